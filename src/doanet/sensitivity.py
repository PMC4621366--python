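"""Perturbation sensitivity analysis of the trained network.

The procedure ranks the seven inputs by how much the network output
moves when one input is swept while the others are held at their means:

1. normalize all inputs and the output to [0, 1];
2. set every input to its column mean and record the output — the
   baseline;
3. sweep each input in turn over 0.0, 0.1, ..., 1.0 (others fixed at
   their means) and score it by the MSE of the 11 outputs against the
   baseline;
4. rank inputs by fold-averaged MSE — the larger the MSE, the more
   sensitive the model is to that input.

Across cross-validation folds the per-input MSEs form paired samples;
adjacent ranks are compared with a paired two-sided Wilcoxon signed-rank
test (alpha = 0.05) by default, or a paired t-test via ``test="ttest"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bpnn import NetworkModel, forward
from .features import INPUT_COLUMNS

__all__ = [
    "SensitivityReport",
    "baseline_output",
    "sweep_input",
    "fold_sensitivity",
    "rank_inputs",
]

SWEEP_GRID = np.round(np.arange(0.0, 1.05, 0.1), 10)  # 0.0 .. 1.0, 11 points


def _input_matrix(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table[list(INPUT_COLUMNS)].to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def baseline_output(model: NetworkModel, table: pd.DataFrame | np.ndarray) -> float:
    """Network output at the vector of normalized column means."""
    X = _input_matrix(table)
    if X.size == 0:
        raise ValueError("empty table")
    return forward(model, X.mean(axis=0))


def sweep_input(
    model: NetworkModel, table: pd.DataFrame | np.ndarray, input_index: int
) -> tuple[np.ndarray, float]:
    """Sweep one input over the 11-point grid; others stay at their means.

    Returns the 11 outputs and the MSE of those outputs against the
    baseline (mean-input) output.
    """
    X = _input_matrix(table)
    n_inputs = X.shape[1]
    if not 0 <= input_index < n_inputs:
        raise IndexError(f"input_index must lie in [0, {n_inputs})")
    means = X.mean(axis=0)
    base = forward(model, means)
    outputs = np.empty(SWEEP_GRID.size)
    probe = means.copy()
    for i, v in enumerate(SWEEP_GRID):
        probe[input_index] = v
        outputs[i] = forward(model, probe)
    mse = float(np.mean((outputs - base) ** 2))
    return outputs, mse


def fold_sensitivity(
    model: NetworkModel, table: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Per-input sweep MSE for one fold model."""
    X = _input_matrix(table)
    return np.array([sweep_input(model, X, j)[1] for j in range(X.shape[1])])


def _paired_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    diff = a - b
    if np.allclose(diff, 0.0):
        return 1.0
    if test == "wilcoxon":
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    if test == "ttest":
        return float(stats.ttest_rel(a, b).pvalue)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class SensitivityReport:
    """Fold-wise sweep MSEs, their average, the ranking and p-values."""

    input_names: tuple[str, ...]
    fold_mse: np.ndarray  # (n_folds, n_inputs)
    mean_mse: np.ndarray  # (n_inputs,)
    ranking: list[str]  # best (most sensitive) first
    adjacent_p_values: list[float]  # between rank i and i+1
    test: str = "wilcoxon"
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        order = [self.input_names.index(nm) for nm in self.ranking]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "input": self.ranking,
                "mean_mse": self.mean_mse[order],
                "p_vs_next": self.adjacent_p_values + [np.nan],
            }
        )


def rank_inputs(
    fold_mse: np.ndarray,
    input_names: tuple[str, ...] = INPUT_COLUMNS,
    test: str = "wilcoxon",
    alpha: float = 0.05,
) -> SensitivityReport:
    """Aggregate per-fold sweep MSEs into a ranking with significance.

    Requires >= 2 folds.  Ties in the fold-averaged MSE break by the
    fixed input order.  Adjacent ranks are compared on their paired
    fold-wise MSE vectors.
    """
    fold_mse = np.asarray(fold_mse, dtype=float)
    if fold_mse.ndim != 2 or fold_mse.shape[1] != len(input_names):
        raise ValueError("fold_mse must be (n_folds, n_inputs)")
    if fold_mse.shape[0] < 2:
        raise ValueError("need >= 2 folds for significance testing")
    mean_mse = fold_mse.mean(axis=0)
    # stable sort on negated means keeps input order on ties
    order = np.argsort(-mean_mse, kind="stable")
    ranking = [input_names[i] for i in order]
    p_values = [
        _paired_p(fold_mse[:, order[i]], fold_mse[:, order[i + 1]], test)
        for i in range(len(order) - 1)
    ]
    return SensitivityReport(
        input_names=tuple(input_names),
        fold_mse=fold_mse,
        mean_mse=mean_mse,
        ranking=ranking,
        adjacent_p_values=p_values,
        test=test,
        alpha=alpha,
    )
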