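"""Metrics, train/test splitting and learning-curve machinery.

Evaluation compares model-corrected energies against reference energies
on a held-out test set, alongside the baseline-only metrics (composition
regression applied, no kernel correction) so the with/without-correction
comparison is always available.  Learning curves keep the test set fixed
while resampling ever larger training subsets, retraining the sparse
selection and weights at each size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .deltamodel import (
    DeltaModel,
    KernelConfig,
    delta_target,
    fit_normalization,
    kernel_features,
    _solve_ridge,
)
from .representations import RepresentationConfig, atomic_descriptors, descriptor_matrix
from .selection import fps_per_element, omp_select_features, scale_quotas
from .structures import Ensemble, LabelledStructure, composition_vector

__all__ = ["EvalReport", "split", "evaluate", "learning_curve", "train_pipeline"]


@dataclass
class EvalReport:
    """MAE/RMSE/R^2/slope of corrected energies, with baseline-only twins."""

    mae: float
    rmse: float
    r2: float
    slope: float
    n: int
    baseline_mae: float
    baseline_rmse: float
    baseline_r2: float
    baseline_slope: float
    split_manifest: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "mae", "rmse", "r2", "slope", "n",
            "baseline_mae", "baseline_rmse", "baseline_r2", "baseline_slope",
        )}
        d["split_manifest"] = self.split_manifest
        return json.dumps(d, indent=1)


def split(
    records: Sequence, fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seed-deterministic train/test index split."""
    n = len(records)
    n_train = int(round(fraction * n))
    if not 0 < n_train < n:
        raise ValueError(
            f"fraction {fraction} leaves an empty train or test set for n={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _metrics(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float, float, float]:
    """(MAE, RMSE, R^2, slope of predicted regressed on reference)."""
    err = pred - ref
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    var = float(np.sum((ref - ref.mean()) ** 2))
    slope = (
        float(np.sum((ref - ref.mean()) * (pred - pred.mean())) / var)
        if var > 0
        else float("nan")
    )
    return mae, rmse, r2, slope


def evaluate(
    model: DeltaModel, test_records: Sequence[LabelledStructure]
) -> EvalReport:
    """Score corrected energies against references on labelled records.

    Baseline-only metrics apply the model's composition regressions but a
    zero kernel correction, i.e. the honest "without the ML correction"
    comparison on the same normalized footing.
    """
    if not test_records:
        raise ValueError("test set is empty")
    ref = np.array([r.e_reference for r in test_records], float)
    pred = np.empty(len(test_records))
    base = np.empty(len(test_records))
    for i, rec in enumerate(test_records):
        rec.require_both()
        comp = composition_vector(rec.structure)
        offset = model.norm_reference.baseline_energy(
            comp
        ) - model.norm_baseline.baseline_energy(comp)
        base[i] = rec.e_baseline + offset
        pred[i] = rec.e_baseline + offset + model.predict(rec.structure)[0]
    mae, rmse, r2, slope = _metrics(pred, ref)
    bmae, brmse, br2, bslope = _metrics(base, ref)
    return EvalReport(
        mae, rmse, r2, slope, len(test_records), bmae, brmse, br2, bslope
    )


def train_pipeline(
    records: Sequence[LabelledStructure],
    omp_m: int = 1000,
    pool_total: int = 40000,
    kernel_config: KernelConfig | None = None,
    rep_config: RepresentationConfig | None = None,
    fps_start="max-norm",
    normalize: str = "separate",
) -> DeltaModel:
    """FPS pool -> OMP basis -> sparse LKR fit, in one call.

    Per-element FPS quotas are the full-scale defaults scaled down
    proportionally to ``pool_total`` (and clamped to the available
    environments); OMP then selects ``omp_m`` environments jointly across
    elements as one global budget.
    """
    kernel_config = kernel_config or KernelConfig()
    rep_config = rep_config or RepresentationConfig()
    envs = []
    for i, rec in enumerate(records):
        envs.extend(atomic_descriptors(rec.structure, rep_config, structure_id=i))
    quotas = scale_quotas(min(pool_total, len(envs)))
    fps = fps_per_element(envs, quotas, start=fps_start)
    pool_idx = [i for res in fps.values() for i in res.selected_indices]
    pool = [envs[i] for i in pool_idx]
    from .selection import omp_select
    from .deltamodel import train

    norm_b = fit_normalization(records, "baseline")
    norm_r = fit_normalization(records, "reference")
    m = min(omp_m, len(pool))
    omp = omp_select(
        pool, records, m, kernel_config, rep_config,
        norm_baseline=norm_b, norm_reference=norm_r,
    )
    basis = [pool[i] for i in omp.selected_indices]
    return train(records, basis, kernel_config, rep_config, normalize=normalize)


@dataclass
class LearningCurveRow:
    size: int
    median_mae: float
    spread: float  # interquartile range across seeds
    maes: list


def learning_curve(
    records: Sequence[LabelledStructure],
    sizes: Sequence[int],
    seeds: Sequence[int],
    omp_m: int = 200,
    kernel_config: KernelConfig | None = None,
    rep_config: RepresentationConfig | None = None,
    pool_total: int = 600,
    test_fraction: float = 0.2,
    split_seed: int = 0,
) -> list[LearningCurveRow]:
    """Median test MAE versus training-set size over resampling seeds.

    The test set is fixed once (``split_seed``) across every size and
    seed; candidate environments come from an FPS pool over the full
    training side.  Descriptors and kernel features are computed once and
    reused, so retraining at each (size, seed) costs only the OMP
    selection and the ridge solve.
    """
    kernel_config = kernel_config or KernelConfig()
    rep_config = rep_config or RepresentationConfig()
    train_idx, test_idx = split(records, 1.0 - test_fraction, seed=split_seed)
    train_records = [records[i] for i in train_idx]
    test_records = [records[i] for i in test_idx]
    if max(sizes) > len(train_records):
        raise ValueError("requested size exceeds the training pool")

    # shared precomputation
    desc_train = [descriptor_matrix(r.structure, rep_config) for r in train_records]
    desc_test = [descriptor_matrix(r.structure, rep_config) for r in test_records]
    envs = []
    for i, rec in enumerate(train_records):
        for a, sym in enumerate(rec.structure.elements):
            from .representations import AtomicEnvironment

            envs.append(AtomicEnvironment(sym, desc_train[i][a], (i, a)))
    quotas = scale_quotas(min(pool_total, len(envs)))
    fps = fps_per_element(envs, quotas)
    pool_idx = [i for res in fps.values() for i in res.selected_indices]
    basis_vectors = np.stack([envs[i].vector for i in pool_idx])
    basis_elements = tuple(envs[i].element for i in pool_idx)

    norm_b = fit_normalization(train_records, "baseline")
    norm_r = fit_normalization(train_records, "reference")
    y_train = np.array([delta_target(r, norm_b, norm_r) for r in train_records])
    ref_test = np.array([r.e_reference for r in test_records])
    base_test = np.empty(len(test_records))
    for i, rec in enumerate(test_records):
        comp = composition_vector(rec.structure)
        base_test[i] = rec.e_baseline + (
            norm_r.baseline_energy(comp) - norm_b.baseline_energy(comp)
        )
    K_train = kernel_features(
        [r.structure for r in train_records], basis_vectors, basis_elements,
        kernel_config, rep_config, descriptor_cache=desc_train,
    )
    K_test = kernel_features(
        [r.structure for r in test_records], basis_vectors, basis_elements,
        kernel_config, rep_config, descriptor_cache=desc_test,
    )

    rows = []
    for size in sizes:
        maes = []
        for seed in seeds:
            sub = np.random.default_rng(seed).choice(
                len(train_records), size=size, replace=False
            )
            m = min(omp_m, basis_vectors.shape[0], size)
            omp = omp_select_features(
                K_train[sub], y_train[sub], m, ridge=kernel_config.ridge
            )
            sel = omp.selected_indices
            alphas = _solve_ridge(
                K_train[np.ix_(sub, sel)], y_train[sub], kernel_config.ridge, None
            )
            pred = base_test + K_test[:, sel] @ alphas
            maes.append(float(np.mean(np.abs(pred - ref_test))))
        q1, med, q3 = np.percentile(maes, [25, 50, 75])
        rows.append(LearningCurveRow(int(size), float(med), float(q3 - q1), maes))
    return rows
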