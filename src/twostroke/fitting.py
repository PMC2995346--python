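"""Grid-search fitting of the temporal scale factor k to psychophysical data.

Model output and data are rescaled to a common range before comparison:

* direction discrimination — percent correct P maps to (P/100) - 0.5 and
  model NE maps to NE/2, so 50% performance and NE = 0 coincide at zero
  (an affine map, not min-max, because chance must map to chance);
* after-effect durations — each observer's durations are normalised to
  [0, 1] by their own maximum, and the model curve is floored at zero
  (durations cannot be negative) and normalised by its own maximum for
  that k.

Goodness of fit is the RMS error across the nine ISI values; the best k
is the grid minimiser, ties broken toward smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig, DEFAULT_CONFIG
from .energy import ModelCurve, model_curve


@dataclass
class PsychoData:
    """One observer/condition/task series: value per ISI.

    ``value`` is percent in [0, 100] for the direction-discrimination task
    ('dd') and non-negative seconds for after-effect durations ('mae').
    """

    observer: str
    condition: str
    task: str
    isi: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.isi = np.asarray(self.isi, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.condition not in ("photopic", "scotopic"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.task not in ("dd", "mae"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.isi.shape != self.value.shape:
            raise ValueError("isi and value must have equal length")
        if self.task == "dd" and (np.any(self.value < 0) or np.any(self.value > 100)):
            raise ValueError("dd values must lie in [0, 100] percent")
        if self.task == "mae" and np.any(self.value < 0):
            raise ValueError("mae durations must be non-negative")


@dataclass
class FitResult:
    """Best-fitting k with its RMS error and the rescaled curves."""

    observer: str
    condition: str
    task: str
    k_best: float
    rms: float
    curve_model: np.ndarray
    curve_data: np.ndarray
    k_grid: tuple[float, ...]
    rms_grid: np.ndarray = field(repr=False, default=None)


def rescale_dd(data_percent: np.ndarray) -> np.ndarray:
    """Map percent in [0, 100] to [-0.5, +0.5]; 50% maps to 0."""
    p = np.asarray(data_percent, dtype=float)
    if np.any(p < 0) or np.any(p > 100):
        raise ValueError("percent values must lie in [0, 100]")
    return p / 100.0 - 0.5


def rescale_model_dd(ne: np.ndarray) -> np.ndarray:
    """Map NE in [-1, 1] to [-0.5, +0.5]; NE = 0 maps to 0."""
    return np.asarray(ne, dtype=float) / 2.0


def rescale_mae(durations: np.ndarray) -> np.ndarray:
    """Normalise durations to [0, 1] by the observer's own maximum."""
    d = np.asarray(durations, dtype=float)
    if np.any(d < 0):
        raise ValueError("durations must be non-negative")
    m = d.max()
    if m <= 0:
        raise ValueError("all-zero duration vector is uninformative")
    return d / m


def rescale_model_mae(ne_curve: np.ndarray) -> np.ndarray:
    """Floor negative NE at 0, then normalise to [0, 1] by the maximum."""
    ne = np.clip(np.asarray(ne_curve, dtype=float), 0.0, None)
    m = ne.max()
    if m <= 0:
        raise ValueError("model curve has no positive net energy")
    return ne / m


def rms_error(model_rescaled: np.ndarray, data_rescaled: np.ndarray) -> float:
    """Root mean squared difference across ISI values."""
    a = np.asarray(model_rescaled, dtype=float)
    b = np.asarray(data_rescaled, dtype=float)
    if a.shape != b.shape:
        raise ValueError("model and data vectors must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


class CurveLibrary:
    """Memoised model curves per (task, k, ISI set, config).

    Fitting many observers against the same grid re-uses each curve, so
    the expensive energy-model runs happen once per (task, k).
    """

    def __init__(self, cfg: ModelConfig = DEFAULT_CONFIG):
        self.cfg = cfg
        self._cache: dict[tuple, ModelCurve] = {}

    def curve(self, task: str, k: float, isi_list: tuple[float, ...] | None = None) -> ModelCurve:
        isi_list = tuple(self.cfg.isi_set if isi_list is None else isi_list)
        key = (task, float(k), isi_list)
        if key not in self._cache:
            self._cache[key] = model_curve(task, k, isi_list, self.cfg)
        return self._cache[key]


def fit_k(
    data: PsychoData,
    k_grid: tuple[float, ...] | None = None,
    cfg: ModelConfig = DEFAULT_CONFIG,
    curves: CurveLibrary | None = None,
) -> FitResult:
    """Select the grid k minimising RMS error against one observer's data.

    Deterministic: the grid is scanned in ascending order and ties go to
    the smaller k.
    """
    if data.value.size == 0:
        raise ValueError("empty data")
    k_grid = tuple(sorted(cfg.k_grid() if k_grid is None else k_grid))
    if not k_grid:
        raise ValueError("empty k grid")
    curves = curves or CurveLibrary(cfg)
    isi_list = tuple(data.isi)

    if data.task == "dd":
        data_rescaled = rescale_dd(data.value)
        rescale_model = rescale_model_dd
    else:
        data_rescaled = rescale_mae(data.value)
        rescale_model = rescale_model_mae

    rms_grid = np.empty(len(k_grid))
    model_rescaled_grid = []
    for i, k in enumerate(k_grid):
        ne = np.asarray(curves.curve(data.task, k, isi_list).ne)
        mr = rescale_model(ne)
        model_rescaled_grid.append(mr)
        rms_grid[i] = rms_error(mr, data_rescaled)
    best = int(np.argmin(rms_grid))  # first minimum -> smallest k on ties
    return FitResult(
        observer=data.observer,
        condition=data.condition,
        task=data.task,
        k_best=k_grid[best],
        rms=float(rms_grid[best]),
        curve_model=model_rescaled_grid[best],
        curve_data=data_rescaled,
        k_grid=k_grid,
        rms_grid=rms_grid,
    )


def pool_mean(records: list[PsychoData]) -> PsychoData:
    """Average a group of observers into one 'Group' series for fitting.

    All records must share condition, task and ISI set.
    """
    if not records:
        raise ValueError("no records to pool")
    first = records[0]
    for r in records[1:]:
        if r.condition != first.condition or r.task != first.task:
            raise ValueError("pooled records must share condition and task")
        if not np.array_equal(r.isi, first.isi):
            raise ValueError("pooled records must share the ISI set")
    values = np.mean([r.value for r in records], axis=0)
    return PsychoData(
        observer="Group",
        condition=first.condition,
        task=first.task,
        isi=first.isi.copy(),
        value=values,
    )


__all__ = [
    "PsychoData",
    "FitResult",
    "rescale_dd",
    "rescale_model_dd",
    "rescale_mae",
    "rescale_model_mae",
    "rms_error",
    "fit_k",
    "pool_mean",
    "CurveLibrary",
]
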