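"""Sample entropy (SampEn) of EEG windows.

SampEn(m, r, N) is the negative natural log of the conditional
probability that two subsequences of a series that match for m points
(Chebyshev distance <= r, self-matches excluded) also match for m + 1
points:

    B^m(r) = average over i in [1, N-m] of  #{j != i : d(X_m(i), X_m(j)) <= r} / (N - m - 1)
    A^m(r) = the same with template length m + 1
    SampEn = -ln(A^m(r) / B^m(r))

Higher values mean a less regular, less predictable signal; during
anesthesia the filtered EEG becomes more regular and its entropy falls,
which is what makes SampEn usable as a consciousness feature.  The
defaults m = 2 and r = 0.15 x SD follow the multiscale-entropy
literature; the tolerance is taken relative to each window's own
standard deviation, which makes the value amplitude-invariant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SampEnConfig",
    "SampEnResult",
    "count_matches",
    "sample_entropy",
    "windowed_entropy",
]


@dataclass(frozen=True)
class SampEnConfig:
    """Parameters (m, r, N) of the sample-entropy statistic.

    m: embedding (template) length; r_fraction: match tolerance as a
    fraction of the window SD; n_samples: expected window length N.
    """

    m: int = 2
    r_fraction: float = 0.15
    n_samples: int = 625

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.r_fraction < 1:
            raise ValueError("r_fraction must lie in (0, 1)")
        if self.n_samples <= self.m + 1:
            raise ValueError("window length N must exceed m + 1")


@dataclass(frozen=True)
class SampEnResult:
    """Entropy value with the underlying average match fractions.

    ``value`` is NaN when no template pair matches at length m or m+1
    (the statistic is undefined there, not zero).
    """

    value: float
    b_count: float  # B^m(r)
    a_count: float  # A^m(r)

    @property
    def defined(self) -> bool:
        return math.isfinite(self.value)


def _match_fraction(y: np.ndarray, length: int, nt: int, tolerance: float) -> float:
    """Average pair-match fraction over ``nt`` templates of ``length``."""
    if nt < 2:
        return 0.0
    # Chebyshev distances accumulated coordinate-wise to keep memory at
    # one (nt x nt) buffer
    base = sliding_window_view(y, length)[:nt]
    dist = np.zeros((nt, nt))
    for k in range(length):
        np.maximum(dist, np.abs(base[:, k, None] - base[None, :, k]), out=dist)
    hits = dist <= tolerance
    np.fill_diagonal(hits, False)
    return float(hits.sum(axis=1).mean() / (nt - 1))


def count_matches(series: np.ndarray, m: int, tolerance: float) -> float:
    """Average fraction of template pairs within ``tolerance``.

    Templates X_m(i) = (y_i, ..., y_{i+m-1}) are taken for i in
    [1, N-m]; for each, the fraction of j != i (same range) with
    Chebyshev distance max_k |y_{i+k} - y_{j+k}| <= tolerance is counted,
    and the fractions are averaged.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n <= m:
        raise ValueError("series length must exceed m")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return _match_fraction(y, m, n - m, tolerance)


def sample_entropy(series: np.ndarray, config: SampEnConfig | None = None) -> SampEnResult:
    """Compute SampEn of one window with tolerance r_fraction x SD.

    A constant window (SD = 0) yields 0 by convention; if either match
    count is zero the value is the NaN sentinel.
    """
    cfg = config or SampEnConfig(n_samples=len(series))
    y = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite samples")
    if y.size <= cfg.m + 1:
        raise ValueError("series too short for the requested m")
    sd = float(y.std())
    if sd == 0.0:
        return SampEnResult(0.0, 1.0, 1.0)
    tol = cfg.r_fraction * sd
    # both counts average over the same i in [1, N-m], so A <= B
    # structurally and every m-match of a periodic series extends
    nt = y.size - cfg.m
    b = _match_fraction(y, cfg.m, nt, tol)
    a = _match_fraction(y, cfg.m + 1, nt, tol)
    if a == 0.0 or b == 0.0:
        return SampEnResult(float("nan"), b, a)
    return SampEnResult(-math.log(a / b), b, a)


def windowed_entropy(
    filtered_eeg: np.ndarray,
    fs: float = 125.0,
    window_s: float = 5.0,
    config: SampEnConfig | None = None,
) -> pd.DataFrame:
    """SampEn per non-overlapping window, as a 0.2 Hz series.

    Returns a DataFrame with columns ``time_s`` (window end time) and
    ``sampen``; undefined windows carry NaN and are expected to be
    dropped (and logged) when the feature table is assembled.  A trailing
    partial window is discarded with a warning.
    """
    y = np.asarray(filtered_eeg, dtype=float)
    if y.size == 0:
        raise ValueError("empty signal")
    wlen = int(round(fs * window_s))
    n_win = y.size // wlen
    if n_win == 0:
        raise ValueError("signal shorter than one window")
    if y.size % wlen:
        warnings.warn(
            f"dropping trailing partial window of {y.size % wlen} samples",
            stacklevel=2,
        )
    cfg = config or SampEnConfig(n_samples=wlen)
    times = np.arange(1, n_win + 1) * window_s
    values = np.empty(n_win)
    for w in range(n_win):
        values[w] = sample_entropy(y[w * wlen : (w + 1) * wlen], cfg).value
    return pd.DataFrame({"time_s": times, "sampen": values})
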