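"""Composition normalization, Delta targets, and sparse local kernel regression.

The energy model corrects a cheap baseline towards an expensive reference:
both energy columns are first normalised by a multilinear regression on
element counts (the regression coefficients play the role of per-element
atomic energies, so the residuals are atomization-like energies), and the
correction target is the difference of the two residuals,

    Delta(s) = [E_ref(s) - n_ref(s)] - [E_base(s) - n_base(s)].

The correction is modelled as a sum over the structure's atoms of Gaussian
kernel similarities to a sparse basis of stored atomic environments,

    Delta_hat(s) = sum_{i in atoms(s)} sum_j alpha_j k(x_i, x_j),

with k(x, x') = exp(-||x - x'||^2 / (2 sigma^2)) for same-element pairs and
0 otherwise.  Weights come from ridge-regularised least squares on
structure-level targets; per-atom contributions fall out of the same sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .representations import (
    AtomicEnvironment,
    RepresentationConfig,
    descriptor_matrix,
)
from .structures import (
    ELEMENT_INDEX,
    LabelError,
    LabelledStructure,
    Structure,
    SUPPORTED_ELEMENTS,
    composition_vector,
)

__all__ = [
    "NormalizationModel",
    "KernelConfig",
    "DeltaModel",
    "fit_normalization",
    "delta_target",
    "kernel",
    "kernel_features",
    "train",
    "predict",
    "corrected_energy",
]


class FitError(ValueError):
    """Raised when a regression cannot be fitted from the data given."""


@dataclass
class NormalizationModel:
    """Multilinear regression of energy on element counts.

    ``coeffs`` holds one energy per element (kcal/mol per atom) in the
    canonical H,C,N,O,F,S order; elements absent from the fitting data are
    marked undetermined (coefficient fixed at 0).
    """

    coeffs: np.ndarray
    intercept: float
    determined: np.ndarray = field(
        default_factory=lambda: np.ones(len(SUPPORTED_ELEMENTS), dtype=bool)
    )

    def baseline_energy(self, composition: np.ndarray) -> float:
        return float(np.asarray(composition) @ self.coeffs + self.intercept)

    def normalize(self, energy: float, composition: np.ndarray) -> float:
        """Residual energy after removing the composition regression."""
        return float(energy) - self.baseline_energy(composition)

    @classmethod
    def identity(cls) -> "NormalizationModel":
        return cls(
            np.zeros(len(SUPPORTED_ELEMENTS)),
            0.0,
            np.zeros(len(SUPPORTED_ELEMENTS), dtype=bool),
        )


def fit_normalization(
    records: Sequence[LabelledStructure],
    which: str = "baseline",
    weights: Sequence[float] | None = None,
) -> NormalizationModel:
    """Least-squares fit of E ~ c . composition + b on one energy column.

    Elements never observed in the data get no coefficient and are
    reported as undetermined.  The intercept column guarantees zero-mean
    residuals; collinear designs resolve to the minimum-norm solution.
    """
    if which not in ("baseline", "reference"):
        raise ValueError("which must be 'baseline' or 'reference'")
    attr = "e_baseline" if which == "baseline" else "e_reference"
    comps, energies, kept_w = [], [], []
    for i, rec in enumerate(records):
        e = getattr(rec, attr)
        if e is None:
            continue
        comps.append(composition_vector(rec.structure))
        energies.append(e)
        kept_w.append(1.0 if weights is None else float(weights[i]))
    if not energies:
        raise FitError(f"no records carry an {attr} label")
    X = np.asarray(comps, dtype=float)
    y = np.asarray(energies, dtype=float)
    present = X.sum(axis=0) > 0
    design = np.hstack([X[:, present], np.ones((len(y), 1))])
    if weights is not None:
        sw = np.sqrt(np.asarray(kept_w))
        design = design * sw[:, None]
        y = y * sw
    sol, *_ = np.linalg.lstsq(design, y, rcond=None)
    coeffs = np.zeros(len(SUPPORTED_ELEMENTS))
    coeffs[present] = sol[:-1]
    return NormalizationModel(coeffs, float(sol[-1]), present.copy())


def delta_target(
    record: LabelledStructure,
    norm_baseline: NormalizationModel,
    norm_reference: NormalizationModel,
) -> float:
    """Normalized reference minus normalized baseline energy (kcal/mol)."""
    record.require_both()
    comp = composition_vector(record.structure)
    return norm_reference.normalize(record.e_reference, comp) - norm_baseline.normalize(
        record.e_baseline, comp
    )


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian kernel width (descriptor-space units) and ridge strength."""

    sigma: float = 3.0
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


def kernel(
    x: np.ndarray,
    y: np.ndarray,
    config: KernelConfig,
    element_x: str | None = None,
    element_y: str | None = None,
) -> float:
    """Gaussian kernel between two environments; 0 across element channels."""
    if element_x is not None and element_y is not None and element_x != element_y:
        return 0.0
    d2 = float(np.sum((np.asarray(x, float) - np.asarray(y, float)) ** 2))
    return float(np.exp(-d2 / (2.0 * config.sigma**2)))


from functools import lru_cache


@lru_cache(maxsize=4096)
def _element_mask(elems_x: tuple, elems_b: tuple) -> np.ndarray:
    ex = np.asarray(elems_x)
    eb = np.asarray(elems_b)
    return (ex[:, None] == eb[None, :]).astype(float)


def _kernel_block(
    X: np.ndarray,
    elems_x: Sequence[str],
    B: np.ndarray,
    elems_b: Sequence[str],
    sigma: float,
) -> np.ndarray:
    """Atom-by-basis kernel matrix with the same-element channel rule."""
    d2 = cdist(X, B, "sqeuclidean")
    mask = _element_mask(tuple(elems_x), tuple(elems_b))
    return np.exp(-d2 / (2.0 * sigma**2)) * mask


def kernel_features(
    structures: Sequence[Structure],
    basis_vectors: np.ndarray,
    basis_elements: Sequence[str],
    kernel_config: KernelConfig,
    rep_config: RepresentationConfig,
    descriptor_cache: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Structure-level feature matrix K[s, j] = sum_i k(x_i, basis_j)."""
    basis_vectors = np.asarray(basis_vectors, float)
    K = np.zeros((len(structures), len(basis_elements)))
    for s, structure in enumerate(structures):
        mat = (
            descriptor_cache[s]
            if descriptor_cache is not None
            else descriptor_matrix(structure, rep_config)
        )
        K[s] = _kernel_block(
            mat, structure.elements, basis_vectors, basis_elements,
            kernel_config.sigma,
        ).sum(axis=0)
    return K


@dataclass
class DeltaModel:
    """Trained sparse LKR correction model.

    Holds everything needed to predict: both normalization models, the
    selected basis environments (vectors + element tags), their weights,
    and the kernel/representation configs.
    """

    norm_baseline: NormalizationModel
    norm_reference: NormalizationModel
    basis_vectors: np.ndarray
    basis_elements: tuple[str, ...]
    alphas: np.ndarray
    kernel_config: KernelConfig
    rep_config: RepresentationConfig

    def __post_init__(self) -> None:
        self.basis_vectors = np.asarray(self.basis_vectors, float)
        self.alphas = np.asarray(self.alphas, float)
        if len(self.alphas) != len(self.basis_elements) or (
            self.basis_vectors.shape[0] != len(self.alphas)
        ):
            raise ValueError("alphas, basis vectors and elements must align")

    # -- prediction -----------------------------------------------------
    def predict(self, structure: Structure) -> tuple[float, np.ndarray]:
        """Total correction (kcal/mol) and its per-atom decomposition."""
        mat = descriptor_matrix(structure, self.rep_config)
        k = _kernel_block(
            mat, structure.elements, self.basis_vectors, self.basis_elements,
            self.kernel_config.sigma,
        )
        per_atom = k @ self.alphas
        return float(per_atom.sum()), per_atom

    def corrected_energy(self, structure: Structure, e_baseline: float) -> float:
        """Estimated reference energy: baseline + correction, de-normalised.

        The correction is learned between *normalised* energies, so the
        difference of the two composition regressions is restored
        symmetrically when mapping back to the reference scale.
        """
        comp = composition_vector(structure)
        offset = self.norm_reference.baseline_energy(
            comp
        ) - self.norm_baseline.baseline_energy(comp)
        return float(e_baseline) + self.predict(structure)[0] + offset

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "kernel_config": {"sigma": self.kernel_config.sigma,
                              "ridge": self.kernel_config.ridge},
            "rep_config": self.rep_config.to_dict(),
            "basis_elements": list(self.basis_elements),
        }
        np.savez(
            path,
            meta=json.dumps(meta),
            basis_vectors=self.basis_vectors,
            alphas=self.alphas,
            norm_b_coeffs=self.norm_baseline.coeffs,
            norm_b_intercept=self.norm_baseline.intercept,
            norm_b_determined=self.norm_baseline.determined,
            norm_r_coeffs=self.norm_reference.coeffs,
            norm_r_intercept=self.norm_reference.intercept,
            norm_r_determined=self.norm_reference.determined,
        )

    @classmethod
    def load(cls, path) -> "DeltaModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                NormalizationModel(
                    z["norm_b_coeffs"], float(z["norm_b_intercept"]),
                    z["norm_b_determined"],
                ),
                NormalizationModel(
                    z["norm_r_coeffs"], float(z["norm_r_intercept"]),
                    z["norm_r_determined"],
                ),
                z["basis_vectors"],
                tuple(meta["basis_elements"]),
                z["alphas"],
                KernelConfig(**meta["kernel_config"]),
                RepresentationConfig.from_dict(meta["rep_config"]),
            )


def _solve_ridge(
    K: np.ndarray, y: np.ndarray, ridge: float, weights: np.ndarray | None
) -> np.ndarray:
    """Weighted ridge least squares via a stacked (stable) least-squares solve."""
    if weights is not None:
        w = np.sqrt(np.asarray(weights, float))
        K = K * w[:, None]
        y = y * w
    m = K.shape[1]
    if ridge == 0.0:
        if np.linalg.matrix_rank(K) < m:
            raise np.linalg.LinAlgError(
                "kernel feature matrix is singular at ridge=0; "
                "set KernelConfig.ridge > 0"
            )
        sol, *_ = np.linalg.lstsq(K, y, rcond=None)
        return sol
    A = np.vstack([K, np.sqrt(ridge) * np.eye(m)])
    rhs = np.concatenate([y, np.zeros(m)])
    sol, *_ = scipy.linalg.lstsq(A, rhs, check_finite=False, lapack_driver="gelsd")
    return sol


def train(
    records: Sequence[LabelledStructure],
    basis: Sequence[AtomicEnvironment],
    kernel_config: KernelConfig | None = None,
    rep_config: RepresentationConfig | None = None,
    weights: Sequence[float] | None = None,
    normalize: str = "separate",
    descriptor_cache: Sequence[np.ndarray] | None = None,
) -> DeltaModel:
    """Fit a sparse LKR correction model on labelled structures.

    ``normalize`` selects how the composition regression enters:

    * ``"separate"`` (default): one regression per energy column, fitted
      first; the kernel model targets the difference of residuals.
    * ``"joint"``: a single regression of the raw energy difference on
      composition, subtracted before the kernel fit.
    * ``"coupled"``: composition coefficients and kernel weights solved
      in one least-squares system on the raw energy difference, with the
      ridge acting on the kernel weights only.  Predicted totals are
      nearly identical to the two-stage modes, but only the coupled fit
      makes the per-atom decomposition identifiable: two-stage residual
      targets force the kernel weights to cancel the composition-span
      component of every kernel column, scrambling atomic attribution.
    """
    kernel_config = kernel_config or KernelConfig()
    rep_config = rep_config or RepresentationConfig()
    if not basis:
        raise ValueError("basis must be non-empty")
    for rec in records:
        rec.require_both()
    basis_vectors = np.stack([e.vector for e in basis])
    basis_elements = tuple(e.element for e in basis)
    K = kernel_features(
        [r.structure for r in records],
        basis_vectors,
        basis_elements,
        kernel_config,
        rep_config,
        descriptor_cache=descriptor_cache,
    )
    if normalize == "separate":
        norm_b = fit_normalization(records, "baseline", weights=weights)
        norm_r = fit_normalization(records, "reference", weights=weights)
    elif normalize == "joint":
        diff = [
            LabelledStructure(r.structure, 0.0, r.e_reference - r.e_baseline)
            for r in records
        ]
        norm_b = NormalizationModel.identity()
        norm_r = fit_normalization(diff, "reference", weights=weights)
    elif normalize == "coupled":
        norm_b = NormalizationModel.identity()
        norm_r, alphas = _coupled_fit(records, K, kernel_config.ridge, weights)
        return DeltaModel(
            norm_b, norm_r, basis_vectors, basis_elements, alphas,
            kernel_config, rep_config,
        )
    else:
        raise ValueError("normalize must be 'separate', 'joint' or 'coupled'")
    y = np.array([delta_target(r, norm_b, norm_r) for r in records])
    alphas = _solve_ridge(K, y, kernel_config.ridge, weights)
    return DeltaModel(
        norm_b, norm_r, basis_vectors, basis_elements, alphas,
        kernel_config, rep_config,
    )


def _coupled_fit(
    records: Sequence[LabelledStructure],
    K: np.ndarray,
    ridge: float,
    weights: Sequence[float] | None,
) -> tuple[NormalizationModel, np.ndarray]:
    """Joint solve for kernel weights and composition coefficients."""
    X = np.array(
        [composition_vector(r.structure) for r in records], dtype=float
    )
    present = X.sum(axis=0) > 0
    design = np.hstack([X[:, present], np.ones((len(records), 1))])
    y = np.array([r.e_reference - r.e_baseline for r in records], dtype=float)
    m = K.shape[1]
    A = np.hstack([K, design])
    if weights is not None:
        sw = np.sqrt(np.asarray(weights, float))
        A = A * sw[:, None]
        y = y * sw
    if ridge > 0:
        pad = np.hstack(
            [np.sqrt(ridge) * np.eye(m), np.zeros((m, design.shape[1]))]
        )
        A = np.vstack([A, pad])
        y = np.concatenate([y, np.zeros(m)])
    sol, *_ = scipy.linalg.lstsq(A, y, check_finite=False, lapack_driver="gelsd")
    coeffs = np.zeros(len(SUPPORTED_ELEMENTS))
    coeffs[present] = sol[m:-1]
    norm_r = NormalizationModel(coeffs, float(sol[-1]), present.copy())
    return norm_r, sol[:m]


def predict(model: DeltaModel, structure: Structure) -> tuple[float, np.ndarray]:
    """Functional wrapper around :meth:`DeltaModel.predict`."""
    return model.predict(structure)


def corrected_energy(model: DeltaModel, structure: Structure, e_baseline: float) -> float:
    """Functional wrapper around :meth:`DeltaModel.corrected_energy`."""
    return model.corrected_energy(structure, e_baseline)
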