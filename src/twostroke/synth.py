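"""Synthetic psychophysical observers.

Stands in for raw observer data so the full pipeline (simulate - fit -
stats) can be exercised end to end.  Two generative models:

* direction discrimination — per ISI, the probability of reporting the
  two-stroke direction is a lapse-contaminated map of model output,
  ``p = (1 - 2*lapse) * (0.5 + NE/2) + lapse``, and the reported value is
  the percent of successes in ``n_trials`` Bernoulli trials (default 80:
  40 per motion direction, collapsed);
* after-effect duration — per repeat, ``max(0, gain * max(0, NE) +
  Gaussian noise)`` seconds, averaged over ``n_repeats`` (default 4);
  "no after-effect" responses are the zero floor.

All randomness flows through one seeded NumPy generator per observer, so
a dataset is bit-reproducible from its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, DEFAULT_CONFIG
from .fitting import PsychoData, CurveLibrary

#: Typical temporal scale factors per (condition, task), used by the
#: default fixture: photopic observers are fast (large k), scotopic slow.
DEFAULT_K_TRUE = {
    ("photopic", "dd"): 110.0,
    ("photopic", "mae"): 90.0,
    ("scotopic", "dd"): 47.0,
    ("scotopic", "mae"): 56.0,
}


@dataclass(frozen=True)
class ObserverModel:
    """Generative parameters for one synthetic observer.

    ``mae_gain`` converts model net energy into seconds of after-effect;
    ``mae_noise_sd`` is trial-to-trial Gaussian noise in seconds.
    """

    k_true: float
    lapse: float = 0.02
    mae_gain: float = 15.0
    mae_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")
        if self.mae_gain <= 0:
            raise ValueError("mae_gain must be positive")
        if self.mae_noise_sd < 0:
            raise ValueError("mae_noise_sd must be non-negative")


def simulate_dd_observer(
    obs: ObserverModel,
    isi_list: tuple[float, ...] | None = None,
    n_trials: int = 80,
    cfg: ModelConfig = DEFAULT_CONFIG,
    curves: CurveLibrary | None = None,
    observer: str = "S1",
    condition: str = "photopic",
) -> PsychoData:
    """Binomial 2AFC percentages per ISI for one observer."""
    curves = curves or CurveLibrary(cfg)
    isi_list = tuple(cfg.isi_set if isi_list is None else isi_list)
    ne = np.asarray(curves.curve("dd", obs.k_true, isi_list).ne)
    p = (1.0 - 2.0 * obs.lapse) * (0.5 + ne / 2.0) + obs.lapse
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        raise ValueError("trial probability outside [0, 1]; NE out of range")
    p = np.clip(p, 0.0, 1.0)
    rng = np.random.default_rng(obs.seed)
    counts = rng.binomial(n_trials, p)
    return PsychoData(
        observer=observer,
        condition=condition,
        task="dd",
        isi=np.asarray(isi_list),
        value=100.0 * counts / n_trials,
    )


def simulate_mae_observer(
    obs: ObserverModel,
    isi_list: tuple[float, ...] | None = None,
    n_repeats: int = 4,
    cfg: ModelConfig = DEFAULT_CONFIG,
    curves: CurveLibrary | None = None,
    observer: str = "S1",
    condition: str = "photopic",
) -> PsychoData:
    """Mean after-effect duration (s) per ISI over noisy repeats."""
    curves = curves or CurveLibrary(cfg)
    isi_list = tuple(cfg.isi_set if isi_list is None else isi_list)
    ne = np.asarray(curves.curve("mae", obs.k_true, isi_list).ne)
    mean_dur = obs.mae_gain * np.clip(ne, 0.0, None)
    rng = np.random.default_rng(obs.seed)
    reps = mean_dur[None, :] + rng.normal(0.0, obs.mae_noise_sd, size=(n_repeats, len(isi_list)))
    reps = np.clip(reps, 0.0, None)
    return PsychoData(
        observer=observer,
        condition=condition,
        task="mae",
        isi=np.asarray(isi_list),
        value=reps.mean(axis=0),
    )


def make_fixture_dataset(
    n_observers: int = 5,
    seed: int = 0,
    k_true: dict[tuple[str, str], float] | None = None,
    lapse: float = 0.02,
    mae_gain: float = 15.0,
    mae_noise_sd: float = 3.0,
    cfg: ModelConfig = DEFAULT_CONFIG,
    curves: CurveLibrary | None = None,
) -> pd.DataFrame:
    """Full synthetic dataset: both tasks, both luminance conditions.

    Returns a tidy frame with columns observer, condition, task, isi_ms,
    value — the same schema the CSV readers expect.  Observer sub-seeds
    are spawned deterministically from ``seed``.
    """
    k_true = dict(DEFAULT_K_TRUE if k_true is None else k_true)
    curves = curves or CurveLibrary(cfg)
    seeds = np.random.SeedSequence(seed).generate_state(
        4 * n_observers, dtype=np.uint32
    )
    rows = []
    i = 0
    for condition in ("photopic", "scotopic"):
        for task in ("dd", "mae"):
            for j in range(n_observers):
                obs = ObserverModel(
                    k_true=k_true[(condition, task)],
                    lapse=lapse,
                    mae_gain=mae_gain,
                    mae_noise_sd=mae_noise_sd,
                    seed=int(seeds[i]),
                )
                i += 1
                name = f"S{j + 1}"
                sim = simulate_dd_observer if task == "dd" else simulate_mae_observer
                rec = sim(obs, cfg=cfg, curves=curves, observer=name, condition=condition)
                for isi, value in zip(rec.isi, rec.value):
                    rows.append(
                        {
                            "observer": name,
                            "condition": condition,
                            "task": task,
                            "isi_ms": int(round(isi * 1000)),
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)


__all__ = [
    "ObserverModel",
    "DEFAULT_K_TRUE",
    "simulate_dd_observer",
    "simulate_mae_observer",
    "make_fixture_dataset",
]
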