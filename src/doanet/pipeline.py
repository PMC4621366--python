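"""End-to-end orchestration: featurization, patient-level 10-fold
cross-validation and fold-model ensembling.

Cross-validation is at the patient level — all rows of a patient stay in
the same fold — because consecutive 5 s windows of one case are strongly
autocorrelated and row-level splits would leak.  Each fold trains one
network on the other folds' patients (normalization bounds fitted on
those training patients only) and validates on its own patients.  The
final predictor is the ensemble: the arithmetic mean of the ten fold
models' outputs, with shared normalization bounds fitted on all modeling
patients pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import emd, sampen
from .bpnn import NetworkConfig, NetworkModel, forward_batch, train
from .features import (
    INPUT_COLUMNS,
    TARGET_COLUMN,
    NormBounds,
    align_and_merge,
    apply_normalizer,
    fit_normalizer,
)
from .synthdata import SyntheticPatient

__all__ = [
    "FoldPlan",
    "FoldResult",
    "EnsembleModel",
    "featurize_patient",
    "make_folds",
    "cross_validate",
    "build_ensemble",
    "ensemble_predict",
    "StudyResult",
    "run_synthetic_study",
]


def featurize_patient(
    patient: SyntheticPatient,
    sampen_config: sampen.SampEnConfig | None = None,
    fs: float = 125.0,
    window_s: float = 5.0,
    first_imf: int = 2,
    last_imf: int = 6,
) -> pd.DataFrame:
    """Raw signals -> unnormalized feature table for one patient.

    EMD band-filters the EEG window by window, sample entropy turns each
    625-sample window into one 0.2 Hz value, and the result is merged
    with the vitals and the averaged rater score.
    """
    filtered = emd.filter_signal(patient.eeg, fs, window_s, first_imf, last_imf)
    entropy = sampen.windowed_entropy(filtered, fs, window_s, sampen_config)
    return align_and_merge(entropy, patient.vitals, patient.rater_scores)


@dataclass(frozen=True)
class FoldPlan:
    """Patient-id -> fold (1..k) assignment."""

    assignments: dict[object, int]
    k: int
    seed: int

    def patients_in(self, fold: int) -> list:
        return [p for p, f in self.assignments.items() if f == fold]

    def patients_not_in(self, fold: int) -> list:
        return [p for p, f in self.assignments.items() if f != fold]


def make_folds(patient_ids: list, k: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded shuffle + round-robin assignment; fold sizes differ by <= 1."""
    ids = list(patient_ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignments = {ids[j]: (i % k) + 1 for i, j in enumerate(order)}
    return FoldPlan(assignments=assignments, k=k, seed=seed)


@dataclass
class FoldResult:
    fold: int
    model: NetworkModel
    bounds: NormBounds
    val_mse: float  # on the normalized (0,1) target scale
    train_patients: list
    val_patients: list


def _pool(tables_by_patient: dict, patients: list) -> pd.DataFrame:
    return pd.concat([tables_by_patient[p] for p in patients], ignore_index=True)


def _prepare(table: pd.DataFrame, bounds: NormBounds) -> pd.DataFrame:
    out = apply_normalizer(table, bounds)
    out[TARGET_COLUMN] = np.clip(out[TARGET_COLUMN].to_numpy(dtype=float) / 100.0, 0, 1)
    return out


def cross_validate(
    tables_by_patient: dict,
    plan: FoldPlan,
    config: NetworkConfig,
) -> list[FoldResult]:
    """Train one model per fold on the complementary folds.

    Per-fold normalization bounds come from that fold's training
    patients only, so validation rows are transformed without peeking.
    Fold models get distinct (seed + fold) initializations.
    """
    missing = set(plan.assignments) - set(tables_by_patient)
    if missing:
        raise ValueError(f"no feature table for patients: {sorted(map(str, missing))}")
    results = []
    for fold in range(1, plan.k + 1):
        val_patients = plan.patients_in(fold)
        train_patients = plan.patients_not_in(fold)
        if not val_patients or not train_patients:
            raise ValueError(f"fold {fold} is empty")
        train_table = _pool(tables_by_patient, train_patients)
        bounds = fit_normalizer(train_table)
        fold_config = NetworkConfig(
            **{
                **{k: getattr(config, k) for k in config.__dataclass_fields__},
                "seed": config.seed + fold,
            }
        )
        model = train(_prepare(train_table, bounds), fold_config, bounds)
        val_table = _prepare(_pool(tables_by_patient, val_patients), bounds)
        pred = forward_batch(model, val_table[list(INPUT_COLUMNS)].to_numpy(dtype=float))
        val_mse = float(np.mean((pred - val_table[TARGET_COLUMN].to_numpy()) ** 2))
        results.append(
            FoldResult(
                fold=fold,
                model=model,
                bounds=bounds,
                val_mse=val_mse,
                train_patients=train_patients,
                val_patients=val_patients,
            )
        )
    return results


@dataclass
class EnsembleModel:
    """The fold models plus shared normalization bounds."""

    models: list[NetworkModel]
    bounds: NormBounds

    def __post_init__(self) -> None:
        cfgs = {
            (m.config.n_inputs, m.config.n_hidden, m.config.n_outputs)
            for m in self.models
        }
        if len(cfgs) > 1:
            raise ValueError("ensemble members must share one architecture")


def build_ensemble(
    fold_results: list[FoldResult], tables_by_patient: dict
) -> EnsembleModel:
    """Pool all modeling patients to fit the shared test-time bounds."""
    pooled = _pool(tables_by_patient, list(tables_by_patient))
    return EnsembleModel(
        models=[r.model for r in fold_results], bounds=fit_normalizer(pooled)
    )


def ensemble_predict(ensemble: EnsembleModel, table: pd.DataFrame) -> np.ndarray:
    """Mean of the member indices (0-100 scale) per row of a raw table."""
    normed = apply_normalizer(table, ensemble.bounds)
    X = normed[list(INPUT_COLUMNS)].to_numpy(dtype=float)
    preds = np.stack([forward_batch(m, X) for m in ensemble.models])
    return 100.0 * preds.mean(axis=0)


@dataclass
class StudyResult:
    """Everything a synthetic-cohort experiment produces."""

    plan: FoldPlan
    fold_results: list[FoldResult]
    ensemble: EnsembleModel
    fold_sensitivity_mse: np.ndarray  # (k, 7) per-input sweep MSE per fold
    tables: dict  # modeling patients' feature tables
    test_tables: dict  # held-out patients' feature tables
    test_latent: dict  # held-out patients' latent state (ground truth)
    test_mae: dict  # ensemble MAE vs latent per test patient
    test_r: dict  # ensemble Pearson r vs latent per test patient
    constant_mae: dict  # MAE of predicting the training-target mean
    train_target_mean: float


def run_synthetic_study(
    seed: int,
    n_patients: int = 10,
    n_test_patients: int = 5,
    duration_s: float = 500.0,
    epochs: int = 500,
    k: int = 10,
) -> StudyResult:
    """Full synthetic-cohort experiment: generate, featurize,
    cross-validate, ensemble, probe sensitivity, evaluate on held-out
    patients.

    The defaults are the package's study conditions: 10 modeling
    patients of 500 s (100 windows each) with the EMG-dominant effect
    profile, a reduced 500-epoch training schedule, and 5 held-out test
    patients scored against their latent consciousness trajectories.
    """
    from . import evaluation, sensitivity, synthdata

    patients = {
        f"p{i:02d}": synthdata.generate_patient(duration_s, seed * 1000 + i)
        for i in range(n_patients)
    }
    tables = {pid: featurize_patient(p) for pid, p in patients.items()}
    plan = make_folds(list(tables), k=k, seed=seed)
    config = NetworkConfig(epochs=epochs, seed=seed)
    fold_results = cross_validate(tables, plan, config)

    fold_mse = []
    for r in fold_results:
        train_table = _pool(tables, r.train_patients)
        normed = apply_normalizer(train_table, r.bounds)
        fold_mse.append(sensitivity.fold_sensitivity(r.model, normed))
    ensemble = build_ensemble(fold_results, tables)

    test_patients = {
        f"t{i:02d}": synthdata.generate_patient(
            duration_s, seed * 1000 + n_patients + 100 + i
        )
        for i in range(n_test_patients)
    }
    test_tables = {pid: featurize_patient(p) for pid, p in test_patients.items()}
    train_target_mean = float(
        np.mean(np.concatenate([t[TARGET_COLUMN].to_numpy() for t in tables.values()]))
    )
    test_mae, test_r, constant_mae, test_latent = {}, {}, {}, {}
    for pid, table in test_tables.items():
        latent = test_patients[pid].latent.state[: len(table)]
        pred = ensemble_predict(ensemble, table)
        test_latent[pid] = latent
        test_mae[pid] = evaluation.mae(pred, latent)[0]
        constant_mae[pid] = evaluation.mae(
            np.full(latent.size, train_target_mean), latent
        )[0]
        test_r[pid] = evaluation.per_patient_correlation(pred, latent)
    return StudyResult(
        plan=plan,
        fold_results=fold_results,
        ensemble=ensemble,
        fold_sensitivity_mse=np.asarray(fold_mse),
        tables=tables,
        test_tables=test_tables,
        test_latent=test_latent,
        test_mae=test_mae,
        test_r=test_r,
        constant_mae=constant_mae,
        train_target_mean=train_target_mean,
    )
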