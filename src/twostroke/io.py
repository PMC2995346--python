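"""Reading and writing the delimited-text formats used by the pipeline.

Psychophysical data travel as tidy CSV with columns
``observer, condition, task, isi_ms, value`` — percent correct for the
direction-discrimination task, seconds for after-effect durations.
Validation reports offending rows by line number (header = line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult, PsychoData

REQUIRED_COLUMNS = ("observer", "condition", "task", "isi_ms", "value")
CONDITIONS = ("photopic", "scotopic")
TASKS = ("dd", "mae")


def _validate_frame(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    # +2: one for the header line, one for 1-based numbering
    lines = df.index.to_numpy() + 2
    problems = []
    bad = ~df["condition"].isin(CONDITIONS)
    problems += [f"line {ln}: unknown condition {v!r}" for ln, v in zip(lines[bad], df.loc[bad, "condition"])]
    bad = ~df["task"].isin(TASKS)
    problems += [f"line {ln}: unknown task {v!r}" for ln, v in zip(lines[bad], df.loc[bad, "task"])]
    value = pd.to_numeric(df["value"], errors="coerce")
    bad = value.isna().to_numpy()
    problems += [f"line {ln}: non-numeric value" for ln in lines[bad]]
    is_dd = (df["task"] == "dd").to_numpy()
    bad = is_dd & ((value < 0) | (value > 100)).to_numpy()
    problems += [f"line {ln}: dd value outside [0, 100]" for ln in lines[bad]]
    is_mae = (df["task"] == "mae").to_numpy()
    bad = is_mae & (value < 0).to_numpy()
    problems += [f"line {ln}: negative mae duration" for ln in lines[bad]]
    if problems:
        raise ValueError("invalid psychophysical data:\n" + "\n".join(problems))


def read_psycho_csv(path: str | Path) -> list[PsychoData]:
    """Load and validate a psychophysical CSV into per-series records.

    Rows are grouped by (observer, condition, task) and sorted by ISI
    within each series.
    """
    df = pd.read_csv(path)
    _validate_frame(df)
    records = []
    for (observer, condition, task), grp in df.groupby(
        ["observer", "condition", "task"], sort=True
    ):
        grp = grp.sort_values("isi_ms")
        records.append(
            PsychoData(
                observer=str(observer),
                condition=str(condition),
                task=str(task),
                isi=grp["isi_ms"].to_numpy(dtype=float) / 1000.0,
                value=grp["value"].to_numpy(dtype=float),
            )
        )
    return records


def write_psycho_csv(path: str | Path, data: pd.DataFrame | list[PsychoData]) -> None:
    """Write records (or a tidy frame) back to the CSV schema."""
    if isinstance(data, pd.DataFrame):
        df = data[list(REQUIRED_COLUMNS)]
    else:
        rows = []
        for rec in data:
            for isi, value in zip(rec.isi, rec.value):
                rows.append(
                    {
                        "observer": rec.observer,
                        "condition": rec.condition,
                        "task": rec.task,
                        "isi_ms": int(round(isi * 1000)),
                        "value": value,
                    }
                )
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_fit_results(
    path: str | Path,
    fits: list[FitResult],
    centre_freqs: dict[float, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Write fit results; optionally annotate filter centre frequencies.

    ``centre_freqs`` maps k to (slow_hz, fast_hz); missing entries are
    left blank.
    """
    centre_freqs = centre_freqs or {}
    rows = []
    for fit in fits:
        slow_hz, fast_hz = centre_freqs.get(fit.k_best, (np.nan, np.nan))
        rows.append(
            {
                "observer": fit.observer,
                "condition": fit.condition,
                "task": fit.task,
                "k_best": fit.k_best,
                "rms": fit.rms,
                "centre_freq_slow_hz": slow_hz,
                "centre_freq_fast_hz": fast_hz,
            }
        )
    df = pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


__all__ = [
    "REQUIRED_COLUMNS",
    "read_psycho_csv",
    "write_psycho_csv",
    "write_fit_results",
]
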