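"""Shared model configuration.

A single frozen dataclass bundles the sampling grid, filter parameters and
stimulus defaults so that every stage of the pipeline (stimulus synthesis,
sensor construction, curve computation, fitting) sees one consistent set of
values.  Frozen/hashable so model curves can be memoised per configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields
from pathlib import Path

import yaml

#: Blank-interval durations (seconds) used by the model stimuli.
ISI_SET: tuple[float, ...] = (0.0, 0.040, 0.085, 0.125, 0.165, 0.200, 0.240, 0.285, 0.315)


@dataclass(frozen=True)
class ModelConfig:
    """Defaults for the sampling grid, filters, stimulus and k grid.

    Attributes
    ----------
    dx, dt : float
        Spatial (deg/sample) and temporal (s/sample) sampling steps.
    x_extent, t_extent : float
        Stimulus extents: 8 deg of space, 1.5 s of time.
    spatial_f, spatial_sigma, spatial_extent : float
        Gabor carrier frequency (cpd), envelope width (deg) and filter
        support (deg, centred on zero).
    n_fast, n_slow : int
        Order of the biphasic temporal filter: 6 (fast) and 9 (slow).
    beta : float
        Weight of the negative temporal lobe relative to the positive one.
    temporal_extent : float
        Temporal filter support in seconds.
    frame_duration : float
        Grating frame duration in seconds.
    spatial_frequency : float
        Stimulus grating frequency in cycles/degree.
    contrast : float
        Michelson contrast of the grating, in (0, 1].
    phase_step : float
        Spatial phase shift between the two pattern frames, degrees (+-90).
    isi_set : tuple of float
        ISI durations in seconds.
    k_min, k_max, k_step : float
        Grid searched when fitting the temporal scale factor k (1/s).
    """

    dx: float = 0.05
    dt: float = 0.005
    x_extent: float = 8.0
    t_extent: float = 1.5

    spatial_f: float = 1.1
    spatial_sigma: float = 0.5
    spatial_extent: float = 4.0

    n_fast: int = 6
    n_slow: int = 9
    beta: float = 0.9
    temporal_extent: float = 0.5

    frame_duration: float = 0.040
    spatial_frequency: float = 1.6
    contrast: float = 0.5
    phase_step: float = 90.0

    isi_set: tuple[float, ...] = ISI_SET

    k_min: float = 20.0
    k_max: float = 200.0
    k_step: float = 5.0

    def k_grid(self) -> tuple[float, ...]:
        """Ascending grid of candidate k values (inclusive of k_max)."""
        n = int(round((self.k_max - self.k_min) / self.k_step))
        return tuple(self.k_min + i * self.k_step for i in range(n + 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        """Load overrides from a YAML key-value file; unknown keys error."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "isi_set" in raw:
            raw["isi_set"] = tuple(float(v) for v in raw["isi_set"])
        return replace(cls(), **raw)


DEFAULT_CONFIG = ModelConfig()
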