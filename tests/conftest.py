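"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from doanet import pipeline, synthdata


def _brute_fraction(y, length, nt, tol):
    total = 0.0
    for i in range(nt):
        count = 0
        for j in range(nt):
            if j == i:
                continue
            if max(abs(y[i + k] - y[j + k]) for k in range(length)) <= tol:
                count += 1
        total += count / (nt - 1)
    return total / nt


def brute_force_match_fraction(y: np.ndarray, m: int, tol: float) -> float:
    """Exhaustive O(N^2) pairwise Chebyshev match count, straight from
    the defining sums — the oracle the optimized implementation is
    checked against.  Templates of length m for i in [1, N-m]."""
    return _brute_fraction(y, m, len(y) - m, tol)


def brute_force_sampen(y: np.ndarray, m: int = 2, r_fraction: float = 0.15) -> float:
    """SampEn via the brute-force counts; NaN when undefined.  Both the
    m and m+1 counts run over the same i in [1, N-m]."""
    sd = float(np.asarray(y).std())
    if sd == 0:
        return 0.0
    tol = r_fraction * sd
    nt = len(y) - m
    b = _brute_fraction(y, m, nt, tol)
    a = _brute_fraction(y, m + 1, nt, tol)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def finite_difference_gradients(model, x, t, eps=1e-6):
    """Central finite differences of E = 1/2 (y - t)^2 on every weight —
    the numeric oracle for the analytic backprop gradients."""
    from doanet.bpnn import forward

    grads = []
    for p in (model.w1, model.b1, model.w2, model.b2):
        g = np.empty_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp = 0.5 * (forward(model, x) - t) ** 2
            p[idx] = orig - eps
            lm = 0.5 * (forward(model, x) - t) ** 2
            p[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        grads.append(g)
    return grads


def concordance_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney pairwise concordance fraction: over all
    (positive, negative) pairs, count score_pos > score_neg as 1 and
    ties as 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


@pytest.fixture(scope="session")
def short_patient() -> synthdata.SyntheticPatient:
    """One small patient (20 windows) for fast unit tests."""
    return synthdata.generate_patient(100.0, seed=42)


@pytest.fixture(scope="session")
def cohort_study() -> pipeline.StudyResult:
    """The full synthetic-cohort experiment under the package's study
    conditions (10 patients, 500 s each, 500-epoch folds, 5 held-out
    test patients).  Session-scoped: it takes a couple of minutes and
    several tests read different aspects of the one run."""
    return pipeline.run_synthetic_study(seed=1)
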