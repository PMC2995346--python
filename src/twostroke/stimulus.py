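"""Space-time stimulus synthesis for two-stroke apparent motion.

Stimuli are stored as x-t matrices of luminance contrast (0 = mean-grey
background), sampled at 0.05 deg and 5 ms by default.  The annular grating
of the psychophysical display is linearised to a 1-D translation, so a +90
degree phase step corresponds to a quarter-period displacement in +x and
the clockwise/counter-clockwise distinction reduces to +-x.

The two-stroke sequence is seven epochs::

    G1 - ISI - G2 - G1 - ISI - G2 - G1

with five grating frames of ``frame_duration`` each, two blank ISIs, and
grating 2 phase-shifted from grating 1 by ``phase_step``.  Direction
discrimination uses one cycle centred in the time window; the after-effect
adaptor repeats the cycle for the whole window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import ISI_SET


@dataclass(frozen=True)
class SamplingGrid:
    """Sampling of the x-t plane: degrees and seconds per sample."""

    dx: float = 0.05
    dt: float = 0.005
    x_extent: float = 8.0
    t_extent: float = 1.5

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("sampling steps must be positive")
        if self.x_extent <= 0 or self.t_extent <= 0:
            raise ValueError("extents must be positive")

    @property
    def n_x(self) -> int:
        return int(round(self.x_extent / self.dx))

    @property
    def n_t(self) -> int:
        return int(round(self.t_extent / self.dt))

    def x(self) -> np.ndarray:
        """Spatial sample positions in degrees, [0, x_extent)."""
        return np.arange(self.n_x) * self.dx

    def t(self) -> np.ndarray:
        """Temporal sample positions in seconds, [0, t_extent)."""
        return np.arange(self.n_t) * self.dt


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of a two-stroke sequence.

    ``phase_step`` is the spatial phase shift (degrees) between the two
    pattern frames; its sign selects the apparent-motion direction.
    """

    frame_duration: float = 0.040
    isi_duration: float = 0.0
    spatial_frequency: float = 1.6
    contrast: float = 0.5
    phase_step: float = 90.0
    mode: str = "single_cycle"

    def __post_init__(self) -> None:
        if self.isi_duration < 0:
            raise ValueError("isi_duration must be >= 0")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        if abs(self.phase_step) != 90.0:
            raise ValueError("phase_step must be +90 or -90 degrees")
        if self.mode not in ("single_cycle", "repeating"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be positive")


@dataclass(frozen=True)
class StimulusXT:
    """An x-t contrast matrix plus the grid and spec that produced it."""

    values: np.ndarray  # shape (n_x, n_t)
    grid: SamplingGrid
    spec: StimulusSpec | None = None


def make_grating_profile(
    phase_deg: float, spec: StimulusSpec, grid: SamplingGrid
) -> np.ndarray:
    """Spatial contrast profile of a sine grating at the given phase.

    Returns ``contrast * sin(2*pi*sf*x + phase)`` sampled on the grid.
    """
    x = grid.x()
    phase = np.deg2rad(phase_deg)
    return spec.contrast * np.sin(2 * np.pi * spec.spatial_frequency * x + phase)


def _epoch_boundaries(spec: StimulusSpec, grid: SamplingGrid) -> list[tuple[int, int, float]]:
    """Sample-index spans of the 7 epochs, with the phase of each grating.

    Returns (start, stop, phase_deg) per epoch; blank epochs carry nan.
    Boundaries are rounded to the nearest sample; at the default grid
    40 ms / 5 ms = 8 samples exactly, so no rounding drift accumulates.
    """
    f, isi = spec.frame_duration, spec.isi_duration
    durations = [f, isi, f, f, isi, f, f]
    phases = [0.0, np.nan, spec.phase_step, 0.0, np.nan, spec.phase_step, 0.0]
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    idx = np.round(edges / grid.dt).astype(int)
    return [(idx[i], idx[i + 1], phases[i]) for i in range(7)]


def _cycle_matrix(spec: StimulusSpec, grid: SamplingGrid) -> np.ndarray:
    """One seven-epoch cycle as an (n_x, n_cycle) contrast matrix."""
    epochs = _epoch_boundaries(spec, grid)
    n_cycle = epochs[-1][1]
    out = np.zeros((grid.n_x, n_cycle))
    for start, stop, phase in epochs:
        if np.isnan(phase) or stop <= start:
            continue
        out[:, start:stop] = make_grating_profile(phase, spec, grid)[:, None]
    return out


def make_two_stroke_xt(spec: StimulusSpec, grid: SamplingGrid) -> StimulusXT:
    """Single-cycle two-stroke stimulus centred in the time window.

    The active part (5 frames + 2 ISIs) is zero-padded symmetrically;
    an odd number of padding samples puts the extra sample after the
    sequence (onset rounded earlier).
    """
    if spec.mode != "single_cycle":
        raise ValueError("make_two_stroke_xt requires mode='single_cycle'")
    cycle = _cycle_matrix(spec, grid)
    n_active = cycle.shape[1]
    if n_active > grid.n_t:
        raise ValueError(
            f"sequence ({n_active} samples) exceeds time window ({grid.n_t})"
        )
    start = (grid.n_t - n_active) // 2
    values = np.zeros((grid.n_x, grid.n_t))
    values[:, start : start + n_active] = cycle
    return StimulusXT(values=values, grid=grid, spec=spec)


def make_repeating_xt(spec: StimulusSpec, grid: SamplingGrid) -> StimulusXT:
    """Seven-epoch cycle tiled from t=0 until the window is full.

    The final partial cycle is truncated.  This is the adapting stimulus
    used for motion after-effect predictions.
    """
    if spec.mode != "repeating":
        raise ValueError("make_repeating_xt requires mode='repeating'")
    cycle = _cycle_matrix(replace(spec, mode="single_cycle"), grid)
    n_cycle = cycle.shape[1]
    if n_cycle == 0:
        raise ValueError("degenerate cycle of zero duration")
    reps = int(np.ceil(grid.n_t / n_cycle))
    values = np.tile(cycle, reps)[:, : grid.n_t]
    return StimulusXT(values=values, grid=grid, spec=spec)


def make_drifting_grating_xt(
    sf: float,
    tf: float,
    direction: int,
    contrast: float = 0.5,
    grid: SamplingGrid | None = None,
) -> StimulusXT:
    """Uniformly drifting grating, used to calibrate sensor sign labels.

    ``v(x, t) = contrast * sin(2*pi*(sf*x - direction*tf*t))`` so that
    ``direction=+1`` moves the pattern toward +x.
    """
    grid = grid or SamplingGrid()
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    if sf <= 0:
        raise ValueError("spatial frequency must be positive")
    if tf < 0:
        raise ValueError("temporal frequency must be >= 0")
    if sf >= 0.5 / grid.dx:
        raise ValueError("spatial frequency at or above Nyquist limit")
    if tf >= 0.5 / grid.dt:
        raise ValueError("temporal frequency at or above Nyquist limit")
    x = grid.x()[:, None]
    t = grid.t()[None, :]
    values = contrast * np.sin(2 * np.pi * (sf * x - direction * tf * t))
    return StimulusXT(values=values, grid=grid, spec=None)


def spec_for_isi(
    isi: float,
    mode: str,
    frame_duration: float = 0.040,
    spatial_frequency: float = 1.6,
    contrast: float = 0.5,
    phase_step: float = 90.0,
) -> StimulusSpec:
    """Convenience constructor for one member of the ISI set."""
    return StimulusSpec(
        frame_duration=frame_duration,
        isi_duration=isi,
        spatial_frequency=spatial_frequency,
        contrast=contrast,
        phase_step=phase_step,
        mode=mode,
    )


__all__ = [
    "ISI_SET",
    "SamplingGrid",
    "StimulusSpec",
    "StimulusXT",
    "make_grating_profile",
    "make_two_stroke_xt",
    "make_repeating_xt",
    "make_drifting_grating_xt",
    "spec_for_isi",
]
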