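"""Assembly of the 0.2 Hz feature table.

One row per 5 s window: the EEG sample-entropy index plus the six
vital-sign means (EMG, HR, pulse, SBP, DBP, SQI) as inputs, and the
averaged clinician consciousness score as the target.  Inputs are
min-max normalized to [0, 1] — the operating range of the log-sigmoid
network — with bounds fitted on training rows only and applied (with
clipping) to validation and test rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "INPUT_COLUMNS",
    "TARGET_COLUMN",
    "NormBounds",
    "average_raters",
    "align_and_merge",
    "fit_normalizer",
    "apply_normalizer",
    "denormalize",
]

logger = logging.getLogger(__name__)

INPUT_COLUMNS = ("sampen", "emg", "hr", "pulse", "sbp", "dbp", "sqi")
TARGET_COLUMN = "target"

_TIME_DECIMALS = 6  # merge key rounding; the grid step is 5 s


def average_raters(rater_scores: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of all rater columns per timestamp.

    Any column other than ``time_s`` is treated as a rater.
    """
    rater_cols = [c for c in rater_scores.columns if c != "time_s"]
    if not rater_cols:
        raise ValueError("no rater columns present")
    return pd.DataFrame(
        {
            "time_s": rater_scores["time_s"].to_numpy(),
            TARGET_COLUMN: rater_scores[rater_cols].mean(axis=1).to_numpy(),
        }
    )


def align_and_merge(
    entropy_series: pd.DataFrame,
    vitals: pd.DataFrame,
    rater_scores: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join entropy, vitals and averaged rater score on time.

    Rows with any missing or non-finite value (e.g. an undefined-entropy
    sentinel) are dropped and counted in a log record.  An empty
    timestamp intersection is an error.
    """
    target = average_raters(rater_scores)
    frames = [entropy_series, vitals, target]
    keyed = []
    for f in frames:
        f = f.copy()
        f["_t"] = f["time_s"].round(_TIME_DECIMALS)
        keyed.append(f.drop(columns="time_s"))
    merged = keyed[0]
    for f in keyed[1:]:
        merged = merged.merge(f, on="_t", how="inner")
    if merged.empty:
        raise ValueError("no overlapping timestamps between inputs")
    merged = merged.rename(columns={"_t": "time_s"})
    cols = ["time_s", *INPUT_COLUMNS, TARGET_COLUMN]
    merged = merged[cols].sort_values("time_s", ignore_index=True)
    finite = np.isfinite(merged.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing/undefined values", n_dropped)
    return merged.loc[finite].reset_index(drop=True)


@dataclass(frozen=True)
class NormBounds:
    """Per-column (min, max) fitted on training data."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({k: list(v) for k, v in self.bounds.items()}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "NormBounds":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        raw = json.loads(text)
        return cls(bounds={k: (float(v[0]), float(v[1])) for k, v in raw.items()})


def fit_normalizer(
    table: pd.DataFrame, columns: tuple[str, ...] = INPUT_COLUMNS
) -> NormBounds:
    """Fit min-max bounds per column.  Fit on training rows only."""
    bounds = {}
    for c in columns:
        col = table[c].to_numpy(dtype=float)
        bounds[c] = (float(col.min()), float(col.max()))
    return NormBounds(bounds=bounds)


def apply_normalizer(table: pd.DataFrame, bounds: NormBounds) -> pd.DataFrame:
    """Map each bounded column to [0, 1] via x' = (x - min)/(max - min).

    Values outside the training range clip to [0, 1] (the log-sigmoid
    saturates there anyway); a degenerate column (max == min) maps to
    0.5 with a warning so single-window tables stay usable.
    """
    out = table.copy()
    for c, (lo, hi) in bounds.bounds.items():
        col = out[c].to_numpy(dtype=float)
        if hi > lo:
            out[c] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
        else:
            logger.warning("degenerate (constant) column %r mapped to 0.5", c)
            out[c] = np.full_like(col, 0.5)
    return out


def denormalize(table: pd.DataFrame, bounds: NormBounds) -> pd.DataFrame:
    """Inverse of :func:`apply_normalizer` for non-degenerate columns."""
    out = table.copy()
    for c, (lo, hi) in bounds.bounds.items():
        if hi > lo:
            out[c] = out[c].to_numpy(dtype=float) * (hi - lo) + lo
        else:
            out[c] = np.full(len(out), lo)
    return out
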