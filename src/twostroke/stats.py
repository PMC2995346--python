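"""Summary statistics and inferential tests on fitted k values."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def summary_stats(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    These are the group rows reported alongside individual fits: the
    average of the individual k values and their spread.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for a sample SD")
    return float(np.mean(v)), float(np.std(v, ddof=1))


def paired_t_test(a, b) -> tuple[float, int, float]:
    """Two-tailed paired-samples t-test.

    Returns (t, df, p).  Computed in closed form from the differences:
    t = mean(d) / (sd(d)/sqrt(n)) with df = n - 1.  All-identical
    differences make the statistic undefined (0/0) and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences; t undefined")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


def luminance_attenuation(luminance: float, log_units: float) -> float:
    """Mean luminance (cd/m^2) after a neutral-density attenuation.

    An ND filter of ``log_units`` log units divides luminance by
    10**log_units.
    """
    if luminance <= 0:
        raise ValueError("luminance must be positive")
    return luminance / 10.0**log_units


def format_p(p: float, floor: float = 0.001) -> str:
    """Report a p-value to 3 decimals, with '< .001' below the floor."""
    if p < floor:
        return f"< {floor:.3f}".replace("0.", ".")
    return f"{p:.3f}".replace("0.", ".", 1) if p < 1 else f"{p:.3f}"


__all__ = ["summary_stats", "paired_t_test", "luminance_attenuation", "format_p"]
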