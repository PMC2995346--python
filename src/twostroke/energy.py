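"""Opponent motion-energy sensors and normalised net energy.

Four oriented space-time sensors are built from the quadrature spatial
pair (even SE, odd SO) and the fast/slow biphasic temporal pair (TF, TS):
two sensors tuned to motion toward +x ("rightward") and two toward -x.
Each sensor is cross-correlated with the stimulus, squared and pooled
over all space-time positions and over the quadrature pair, giving
directional energies e_R and e_L.  The model output is motion contrast,

    NE = (e_R - e_L) / (e_R + e_L),

opponent energy divided by flicker energy, bounded in [-1, +1] and
invariant to stimulus contrast.  Pooling happens before the ratio, so a
stimulus yields a single scalar NE; per-sensor divisive normalisation
followed by pooling is algebraically the same after the sums are taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .config import ModelConfig, DEFAULT_CONFIG
from .filters import (
    SpatialFilterSpec,
    TemporalFilterSpec,
    spatial_even,
    spatial_odd,
    temporal_response,
)
from .stimulus import SamplingGrid, StimulusXT, make_two_stroke_xt, make_repeating_xt, spec_for_isi

#: Below this flicker energy a stimulus is treated as blank and NE set to 0.
FLICKER_TOL = 1e-12


@dataclass(frozen=True)
class SensorBank:
    """Four oriented space-time filters (two per direction).

    Each filter is a sum of two outer products of a spatial and a temporal
    vector (rank-2 in space-time).  ``r1``/``r2`` form the quadrature pair
    tuned to +x motion, ``l1``/``l2`` the pair tuned to -x motion.
    """

    r1: np.ndarray
    r2: np.ndarray
    l1: np.ndarray
    l2: np.ndarray
    spatial: SpatialFilterSpec = field(repr=False, default=None)
    fast: TemporalFilterSpec = field(repr=False, default=None)
    slow: TemporalFilterSpec = field(repr=False, default=None)


@dataclass(frozen=True)
class EnergySummary:
    """Pooled directional energies and normalised net energy for one stimulus."""

    e_R: float
    e_L: float
    ne: float

    @property
    def flicker(self) -> float:
        return self.e_R + self.e_L

    @property
    def opponent(self) -> float:
        return self.e_R - self.e_L


@dataclass(frozen=True)
class ModelCurve:
    """Normalised net energy per ISI for one task and one k."""

    isi: tuple[float, ...]
    ne: tuple[float, ...]
    task: str
    k: float

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.isi), np.asarray(self.ne)


def build_sensors(
    spatial: SpatialFilterSpec,
    fast: TemporalFilterSpec,
    slow: TemporalFilterSpec,
) -> SensorBank:
    """Assemble the four oriented sensors from the filter specs.

    The combination signs are a convention fixed by calibration: a grating
    drifting toward +x must yield NE > 0 (asserted in the test suite).
    """
    if fast.dt != slow.dt:
        raise ValueError("fast and slow temporal filters must share dt")
    se = spatial_even(spatial)
    so = spatial_odd(spatial)
    tf = temporal_response(fast)
    ts = temporal_response(slow)
    se_tf = np.outer(se, tf)
    so_ts = np.outer(so, ts)
    so_tf = np.outer(so, tf)
    se_ts = np.outer(se, ts)
    return SensorBank(
        r1=se_tf + so_ts,
        r2=so_tf - se_ts,
        l1=se_tf - so_ts,
        l2=so_tf + se_ts,
        spatial=spatial,
        fast=fast,
        slow=slow,
    )


def _correlate_same(stim: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # cross-correlation == convolution with the doubly flipped kernel
    return fftconvolve(stim, kernel[::-1, ::-1], mode="same")


def energy_summary(stim: StimulusXT, bank: SensorBank) -> EnergySummary:
    """Cross-correlate, square, pool, and normalise.

    Each sensor is correlated with the stimulus at all space-time
    positions ('same' output size, zero boundary), squared, and summed
    over space, time, and the quadrature pair.  A blank stimulus
    (flicker below tolerance) yields NE = 0 with a warning.
    """
    if bank.spatial is not None and not np.isclose(bank.spatial.dx, stim.grid.dx):
        raise ValueError("stimulus and sensor bank sampled at different dx")
    if bank.fast is not None and not np.isclose(bank.fast.dt, stim.grid.dt):
        raise ValueError("stimulus and sensor bank sampled at different dt")
    e_R = sum(
        float(np.sum(_correlate_same(stim.values, kern) ** 2))
        for kern in (bank.r1, bank.r2)
    )
    e_L = sum(
        float(np.sum(_correlate_same(stim.values, kern) ** 2))
        for kern in (bank.l1, bank.l2)
    )
    flicker = e_R + e_L
    if flicker < FLICKER_TOL:
        warnings.warn("flicker energy below tolerance; NE set to 0", stacklevel=2)
        return EnergySummary(e_R=e_R, e_L=e_L, ne=0.0)
    return EnergySummary(e_R=e_R, e_L=e_L, ne=(e_R - e_L) / flicker)


def bank_for_k(k: float, cfg: ModelConfig = DEFAULT_CONFIG) -> SensorBank:
    """Sensor bank with both temporal filters at scale factor k."""
    spatial = SpatialFilterSpec(
        f=cfg.spatial_f, sigma=cfg.spatial_sigma, extent=cfg.spatial_extent, dx=cfg.dx
    )
    fast = TemporalFilterSpec(
        k=k, n=cfg.n_fast, beta=cfg.beta, extent=cfg.temporal_extent, dt=cfg.dt
    )
    slow = TemporalFilterSpec(
        k=k, n=cfg.n_slow, beta=cfg.beta, extent=cfg.temporal_extent, dt=cfg.dt
    )
    return build_sensors(spatial, fast, slow)


def model_curve(
    task: str,
    k: float,
    isi_list: tuple[float, ...] | None = None,
    cfg: ModelConfig = DEFAULT_CONFIG,
    phase_step: float | None = None,
) -> ModelCurve:
    """Normalised net energy per ISI for one task.

    Direction discrimination ('dd') uses the single seven-epoch cycle
    centred in the time window; the after-effect adaptor ('mae') tiles the
    cycle over the whole window.
    """
    if task not in ("dd", "mae"):
        raise ValueError(f"unknown task {task!r}")
    isi_list = tuple(cfg.isi_set if isi_list is None else isi_list)
    phase_step = cfg.phase_step if phase_step is None else phase_step
    grid = SamplingGrid(dx=cfg.dx, dt=cfg.dt, x_extent=cfg.x_extent, t_extent=cfg.t_extent)
    bank = bank_for_k(k, cfg)
    mode = "single_cycle" if task == "dd" else "repeating"
    maker = make_two_stroke_xt if task == "dd" else make_repeating_xt
    ne = []
    for isi in isi_list:
        spec = spec_for_isi(
            isi,
            mode,
            frame_duration=cfg.frame_duration,
            spatial_frequency=cfg.spatial_frequency,
            contrast=cfg.contrast,
            phase_step=phase_step,
        )
        stim = maker(spec, grid)
        ne.append(energy_summary(stim, bank).ne)
    return ModelCurve(isi=isi_list, ne=tuple(ne), task=task, k=k)


__all__ = [
    "SensorBank",
    "EnergySummary",
    "ModelCurve",
    "build_sensors",
    "energy_summary",
    "bank_for_k",
    "model_curve",
    "FLICKER_TOL",
]
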