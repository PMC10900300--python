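"""Diversity and sparsity selection: farthest point sampling and OMP.

FPS (greedy max-min selection) builds diverse pools of atomic
environments or conformers; orthogonal matching pursuit then picks the
sparse basis of environments whose structure-level kernel columns best
explain the correction targets, refitting all active weights at every
greedy step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "FPSResult",
    "OMPResult",
    "farthest_point_sampling",
    "fps_per_element",
    "scale_quotas",
    "omp_select_features",
    "omp_select",
    "DEFAULT_QUOTAS",
]

#: Per-element environment-pool quotas (a 40 000-environment budget).
DEFAULT_QUOTAS: dict[str, int] = {
    "H": 5000,
    "C": 12000,
    "N": 8000,
    "O": 8000,
    "F": 2000,
    "S": 5000,
}


@dataclass
class FPSResult:
    """Greedy max-min selection order with the achieved min-distances."""

    selected_indices: list[int]
    min_distances: list[float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_indices": [int(i) for i in self.selected_indices],
                "min_distances": [float(d) for d in self.min_distances],
            }
        )


@dataclass
class OMPResult:
    """Greedy OMP selection order with the residual norm after each step."""

    selected_indices: list[int]
    residual_norms: list[float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_indices": [int(i) for i in self.selected_indices],
                "residual_norms": [float(r) for r in self.residual_norms],
            }
        )


def farthest_point_sampling(points, k: int, start="max-norm") -> FPSResult:
    """Greedy max-min (farthest point) selection of ``k`` points.

    Parameters
    ----------
    points : array-like, shape (n, d)
    k : number of points to select, 1 <= k <= n.
    start : ``"max-norm"`` (deterministic default: the point farthest from
        the centroid) or an integer index.

    Distances are Euclidean; ties break on the lowest index, so the
    selection is fully deterministic.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    if start == "max-norm":
        centroid = pts.mean(axis=0)
        first = int(np.argmax(np.linalg.norm(pts - centroid, axis=1)))
    else:
        first = int(start)
        if not 0 <= first < n:
            raise ValueError(f"start index {first} out of range")
    selected = [first]
    dmin = np.linalg.norm(pts - pts[first], axis=1)
    min_distances = [float("inf")]
    for _ in range(1, k):
        nxt = int(np.argmax(dmin))
        min_distances.append(float(dmin[nxt]))
        selected.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(pts - pts[nxt], axis=1))
    return FPSResult(selected, min_distances)


def scale_quotas(total: int, quotas: dict[str, int] | None = None) -> dict[str, int]:
    """Scale per-element quotas proportionally to a smaller total budget.

    Largest-remainder rounding keeps the counts summing to ``total`` while
    preserving the quota ratios as closely as integers allow.
    """
    quotas = dict(DEFAULT_QUOTAS if quotas is None else quotas)
    full = sum(quotas.values())
    if total >= full:
        return quotas
    raw = {e: q * total / full for e, q in quotas.items()}
    out = {e: int(np.floor(v)) for e, v in raw.items()}
    remainder = total - sum(out.values())
    order = sorted(raw, key=lambda e: raw[e] - np.floor(raw[e]), reverse=True)
    for e in order[:remainder]:
        out[e] += 1
    return out


def fps_per_element(envs, quota: dict[str, int], start="max-norm") -> dict[str, FPSResult]:
    """Run FPS independently within each element's sub-pool.

    ``envs`` is a sequence of :class:`~deltakern.representations.AtomicEnvironment`.
    Returned indices point into the *original* ``envs`` sequence.  A quota
    exceeding its sub-pool size is clamped with a logged warning so that
    full-scale quota configurations still run on small pools.
    """
    results: dict[str, FPSResult] = {}
    for element, want in quota.items():
        if want < 0:
            raise ValueError(f"negative quota for {element}")
        if want == 0:
            continue
        idx = [i for i, e in enumerate(envs) if e.element == element]
        if not idx:
            logger.warning("no %s environments in pool; quota %d skipped", element, want)
            continue
        if want > len(idx):
            logger.warning(
                "quota %d for %s exceeds sub-pool size %d; clamping",
                want, element, len(idx),
            )
            want = len(idx)
        sub = np.stack([envs[i].vector for i in idx])
        res = farthest_point_sampling(sub, want, start=start)
        results[element] = FPSResult(
            [idx[i] for i in res.selected_indices], res.min_distances
        )
    return results


def omp_select_features(
    features: np.ndarray,
    targets: np.ndarray,
    m: int,
    ridge: float = 1e-8,
) -> OMPResult:
    """Classical OMP over precomputed feature columns.

    Each greedy step adds the column most correlated (on unit-normalised
    columns) with the current residual, then refits all active weights by
    ridge-regularised least squares on the targets.  Candidates that are
    numerically linearly dependent on the active set are dropped with a
    logged warning.  Correlation screening runs in Gram-matrix form for
    speed; residual norms are recomputed explicitly.
    """
    K = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    n, p = K.shape
    if y.shape != (n,):
        raise ValueError("targets length must match feature rows")
    if not 1 <= m <= p:
        raise ValueError(f"m={m} must be in [1, {p}]")

    norms = np.linalg.norm(K, axis=0)
    dead = norms <= 1e-300
    safe = np.where(dead, 1.0, norms)
    Kn = K / safe
    G = Kn.T @ Kn
    b = Kn.T @ y

    active: list[int] = []
    residual_norms: list[float] = []
    alpha = np.zeros(0)
    excluded = dead.copy()
    while len(active) < m:
        corr = b - (G[:, active] @ alpha if active else 0.0)
        corr = np.abs(corr)
        corr[excluded] = -np.inf
        if active:
            corr[active] = -np.inf
        j = int(np.argmax(corr))
        if not np.isfinite(corr[j]):
            logger.warning("OMP exhausted usable candidates at %d", len(active))
            break
        trial = active + [j]
        A = G[np.ix_(trial, trial)] + ridge * np.eye(len(trial))
        try:
            c_factor = scipy.linalg.cho_factor(A, check_finite=False)
        except scipy.linalg.LinAlgError:
            logger.warning("OMP: candidate %d makes active set rank-deficient", j)
            excluded[j] = True
            continue
        # last Cholesky pivot = Schur complement of the new (unit-norm) column;
        # a near-zero value means the candidate is linearly dependent
        if len(trial) > 1 and c_factor[0][-1, -1] ** 2 <= max(ridge * 10.0, 1e-12):
            logger.warning("OMP: candidate %d nearly dependent on active set", j)
            excluded[j] = True
            continue
        alpha_trial = scipy.linalg.cho_solve(c_factor, b[trial], check_finite=False)
        active = trial
        alpha = alpha_trial
        resid = y - Kn[:, active] @ alpha
        residual_norms.append(float(np.linalg.norm(resid)))
    return OMPResult(active, residual_norms)


def omp_select(
    candidate_envs,
    training_set,
    m: int,
    kernel_config,
    rep_config,
    norm_baseline=None,
    norm_reference=None,
    ridge: float | None = None,
) -> OMPResult:
    """OMP over a pooled candidate-environment set against Delta targets.

    Builds the structure-level kernel feature matrix (sum over each
    structure's atoms of the same-element Gaussian kernel to every
    candidate environment), forms normalised correction targets, and runs
    :func:`omp_select_features`.  Normalisation models are fitted from the
    training set when not supplied.
    """
    from .deltamodel import delta_target, fit_normalization, kernel_features

    if norm_baseline is None:
        norm_baseline = fit_normalization(training_set, "baseline")
    if norm_reference is None:
        norm_reference = fit_normalization(training_set, "reference")
    y = np.array(
        [delta_target(r, norm_baseline, norm_reference) for r in training_set]
    )
    basis_vectors = np.stack([e.vector for e in candidate_envs])
    basis_elements = tuple(e.element for e in candidate_envs)
    K = kernel_features(
        [r.structure for r in training_set],
        basis_vectors,
        basis_elements,
        kernel_config,
        rep_config,
    )
    return omp_select_features(
        K, y, m, ridge=kernel_config.ridge if ridge is None else ridge
    )
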