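"""Synthetic molecules, analytic toy potentials and planted-correction data.

Every stage of the toolkit is testable without electronic-structure
engines:

* random molecular clusters relaxed under a pairwise Morse baseline stand
  in for DFTB-level geometries;
* analytic potentials (1D double well, 2D Gaussian well, harmonic net)
  come with quadrature oracles for populations and moments, so sampler
  and FES output can be checked against closed-form thermodynamics;
* labelled datasets carry a *planted* correction built from Gaussian
  bumps in descriptor space -- exactly the hypothesis class of the sparse
  local kernel model -- so recovery experiments isolate the estimator
  from representation error.  An off-class three-body correction
  exercises graceful degradation.

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np
from scipy.integrate import quad

from .constants import KB_KCAL_MOL_K
from .representations import RepresentationConfig, descriptor_matrix
from .sampler import MCConfig, Potential, run_metropolis
from .structures import (
    ELEMENT_INDEX,
    Ensemble,
    LabelledStructure,
    Structure,
    SUPPORTED_ELEMENTS,
)

__all__ = [
    "ToyPotentialSpec",
    "MorseClusterPotential",
    "HarmonicNetPotential",
    "DoubleWell1DPotential",
    "Gaussian2DPotential",
    "make_potential",
    "generate_molecules",
    "PlantedCorrectionSpec",
    "draw_planted_correction",
    "ThreeBodyCorrection",
    "label_with_planted_delta",
    "make_reservoir",
]

# Covalent-like radii (A) for Morse pair minima and packing heuristics.
_RADII = {"H": 0.40, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "S": 1.05}
# Element-wise well-depth factors for the Morse baseline.
_DEPTH = {"H": 1.0, "C": 1.5, "N": 1.4, "O": 1.3, "F": 1.1, "S": 1.6}

# Per-element atomic energy offsets (kcal/mol) added to the two synthetic
# energy columns; they differ so the composition normalization has real
# work to do before the Delta target is formed.
BASELINE_ATOM_ENERGY = {"H": -310.0, "C": -2190.0, "N": -3410.0,
                        "O": -4690.0, "F": -6230.0, "S": -24860.0}
REFERENCE_ATOM_ENERGY = {"H": -313.7, "C": -2204.2, "N": -3427.9,
                         "O": -4712.4, "F": -6257.1, "S": -24891.8}


@dataclass
class ToyPotentialSpec:
    """Named analytic potential with per-kind constants.

    kinds: ``pairwise-morse``, ``harmonic-net``, ``double-well-1d``,
    ``gaussian-2d``.  Kinds with ``analytic_partition`` ship quadrature
    oracles (:func:`double_well_populations`, Gaussian moments).
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    _KINDS = ("pairwise-morse", "harmonic-net", "double-well-1d", "gaussian-2d")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown toy potential kind {self.kind!r}")

    @property
    def analytic_partition(self) -> bool:
        return self.kind in ("double-well-1d", "gaussian-2d")


class MorseClusterPotential:
    """All-pairs Morse potential: smooth, bounded and cheap.

    V = sum_{i<j} D_ij [ (1 - e^{-a (r_ij - r0_ij)})^2 - 1 ]
    with pair minima at r0_ij = max(rad_i + rad_j, 1.0) A.
    """

    name = "pairwise-morse"

    def __init__(self, depth_scale: float = 40.0, a: float = 1.8):
        self.depth_scale = depth_scale
        self.a = a

    def _pair_tables(self, elements) -> tuple[np.ndarray, np.ndarray]:
        d = np.array([math.sqrt(_DEPTH[e]) for e in elements])
        rad = np.array([_RADII[e] for e in elements])
        D = self.depth_scale * np.outer(d, d)
        r0 = np.maximum(rad[:, None] + rad[None, :], 1.0)
        return D, r0

    def evaluate(self, structure: Structure) -> float:
        coords = structure.coords
        n = len(coords)
        if n < 2:
            return 0.0
        D, r0 = self._pair_tables(structure.elements)
        diff = coords[None, :, :] - coords[:, None, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        iu = np.triu_indices(n, k=1)
        ex = np.exp(-self.a * (r[iu] - r0[iu]))
        return float(np.sum(D[iu] * ((1.0 - ex) ** 2 - 1.0)))

    def gradient(self, structure: Structure) -> np.ndarray:
        coords = structure.coords
        n = len(coords)
        g = np.zeros_like(coords)
        if n < 2:
            return g
        D, r0 = self._pair_tables(structure.elements)
        diff = coords[None, :, :] - coords[:, None, :]  # diff[i,j] = x_j - x_i
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(r, np.inf)
        ex = np.exp(-self.a * (r - r0))
        dvdr = 2.0 * D * self.a * ex * (1.0 - ex)
        coef = dvdr / r
        g = -np.einsum("ij,ijk->ik", coef, diff)
        return g


class HarmonicNetPotential:
    """Harmonic springs between all pairs of a reference geometry."""

    name = "harmonic-net"

    def __init__(self, reference: Structure, k: float = 50.0, cutoff: float = 3.0):
        self.reference = reference.copy()
        self.k = k
        ref = reference.coords
        diff = ref[None, :, :] - ref[:, None, :]
        self._r0 = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        self._mask = np.triu(self._r0 < cutoff, k=1)

    def evaluate(self, structure: Structure) -> float:
        coords = structure.coords
        diff = coords[None, :, :] - coords[:, None, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        d = (r - self._r0)[self._mask]
        return float(0.5 * self.k * np.sum(d * d))


class DoubleWell1DPotential:
    """Quartic double well in x with harmonic confinement in y, z.

    V = h ((x^2 - x0^2)/x0^2)^2 + tilt x + k_perp/2 (y^2 + z^2);
    the tilt makes the two wells inequivalent so population ratios are a
    non-trivial check.  Acts on the first atom of a structure.
    """

    name = "double-well-1d"

    def __init__(self, barrier: float = 2.0, x0: float = 1.0,
                 tilt: float = 0.4, k_perp: float = 20.0):
        self.barrier = barrier
        self.x0 = x0
        self.tilt = tilt
        self.k_perp = k_perp

    def v_x(self, x: float) -> float:
        u = (x * x - self.x0 * self.x0) / (self.x0 * self.x0)
        return self.barrier * u * u + self.tilt * x

    def evaluate(self, structure: Structure) -> float:
        x, y, z = structure.coords[0]
        return self.v_x(x) + 0.5 * self.k_perp * (y * y + z * z)


class Gaussian2DPotential:
    """Quadratic well in (x, y) plus harmonic z: Boltzmann dist is Gaussian.

    V = 1/2 [x, y] H [x, y]^T + k_z/2 z^2; at temperature T the sampled
    (x, y) covariance is k_B T H^{-1}.
    """

    name = "gaussian-2d"

    def __init__(self, hessian=((4.0, 1.0), (1.0, 2.0)), k_z: float = 20.0):
        self.hessian = np.asarray(hessian, float)
        if self.hessian.shape != (2, 2) or not np.allclose(
            self.hessian, self.hessian.T
        ):
            raise ValueError("hessian must be symmetric 2x2")
        if np.linalg.eigvalsh(self.hessian).min() <= 0:
            raise ValueError("hessian must be positive definite")
        self.k_z = k_z

    def covariance(self, temperature: float) -> np.ndarray:
        return KB_KCAL_MOL_K * temperature * np.linalg.inv(self.hessian)

    def evaluate(self, structure: Structure) -> float:
        x, y, z = structure.coords[0]
        v = np.array([x, y])
        return float(0.5 * v @ self.hessian @ v + 0.5 * self.k_z * z * z)


def make_potential(spec: ToyPotentialSpec, **extra) -> Potential:
    """Instantiate the potential a :class:`ToyPotentialSpec` names."""
    p = dict(spec.parameters)
    p.update(extra)
    if spec.kind == "pairwise-morse":
        return MorseClusterPotential(**p)
    if spec.kind == "harmonic-net":
        return HarmonicNetPotential(**p)
    if spec.kind == "double-well-1d":
        return DoubleWell1DPotential(**p)
    return Gaussian2DPotential(**p)


def double_well_populations(
    pot: DoubleWell1DPotential, temperature: float
) -> tuple[float, float]:
    """Quadrature oracle: Boltzmann weight of x<0 vs x>0 (y,z separate off)."""
    beta = 1.0 / (KB_KCAL_MOL_K * temperature)
    f = lambda x: math.exp(-beta * pot.v_x(x))
    lo = quad(f, -6 * pot.x0, 0.0, limit=200)[0]
    hi = quad(f, 0.0, 6 * pot.x0, limit=200)[0]
    total = lo + hi
    return lo / total, hi / total


_DEFAULT_WEIGHTS = {"H": 0.35, "C": 0.35, "N": 0.10, "O": 0.10, "F": 0.05, "S": 0.05}
MIN_DISTANCE = 0.8  # hard floor on any interatomic distance (A)


def _place_cluster(n_atoms, elements, rng) -> np.ndarray | None:
    coords = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        for _ in range(200):
            anchor = coords[rng.integers(i)]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = anchor + direction * rng.uniform(1.05, 1.8)
            if np.min(np.linalg.norm(coords[:i] - pos, axis=1)) >= 0.95:
                coords[i] = pos
                break
        else:
            return None
    return coords


def _min_distance(coords: np.ndarray) -> float:
    n = len(coords)
    if n < 2:
        return np.inf
    diff = coords[None, :, :] - coords[:, None, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return float(r[np.triu_indices(n, k=1)].min())


def generate_molecules(
    n: int,
    size_range: tuple[int, int] = (4, 8),
    element_weights: dict[str, float] | None = None,
    seed: int = 0,
    relax_steps: int = 15,
    baseline: MorseClusterPotential | None = None,
) -> Ensemble:
    """Random molecular clusters relaxed a few steps under the Morse baseline.

    Deterministic given ``seed``; every returned structure satisfies the
    minimum interatomic distance of 0.8 A.
    """
    if size_range[0] < 1 or size_range[1] < size_range[0]:
        raise ValueError("invalid size_range")
    weights = dict(_DEFAULT_WEIGHTS if element_weights is None else element_weights)
    symbols = [s for s in SUPPORTED_ELEMENTS if weights.get(s, 0) > 0]
    probs = np.array([weights[s] for s in symbols], float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    pot = baseline or MorseClusterPotential()
    out = []
    for mol in range(n):
        for attempt in range(25):
            n_atoms = int(rng.integers(size_range[0], size_range[1] + 1))
            elements = tuple(rng.choice(symbols, size=n_atoms, p=probs))
            coords = _place_cluster(n_atoms, elements, rng)
            if coords is None:
                continue
            s = Structure(elements, coords, {"name": f"mol{mol}"})
            for _ in range(relax_steps):
                g = pot.gradient(s)
                gn = np.linalg.norm(g, axis=1).max()
                if gn < 1e-6:
                    break
                step = min(1e-3, 0.05 / gn)
                s = Structure(elements, s.coords - step * g, s.tags)
            if _min_distance(s.coords) >= MIN_DISTANCE:
                out.append(s)
                break
        else:
            raise RuntimeError(
                f"could not pack molecule {mol} after 25 attempts"
            )
    return Ensemble.from_structures(out)


@dataclass
class PlantedCorrectionSpec:
    """Smooth, local, element-tagged correction in descriptor space.

    ``bumps`` is a list of (element, centre vector, amplitude): each
    matching atom contributes A exp(-||x_i - mu||^2 / (2 width^2)) -- the
    exact functional form of the kernel model, so the planted signal lies
    inside the hypothesis class when ``width`` equals the kernel sigma.
    Optional per-element linear weights leave the class (mildly);
    ``noise_sd`` adds iid Gaussian label noise in kcal/mol.
    """

    bumps: list  # (element, np.ndarray centre, float amplitude)
    width: float = 3.0
    linear_weights: dict | None = None
    noise_sd: float = 0.0

    def correction_per_atom(
        self, structure: Structure, rep_config: RepresentationConfig
    ) -> np.ndarray:
        mat = descriptor_matrix(structure, rep_config)
        out = np.zeros(structure.n_atoms)
        for i, sym in enumerate(structure.elements):
            x = mat[i]
            acc = 0.0
            for elem, mu, amp in self.bumps:
                if elem == sym:
                    d2 = float(np.sum((x - mu) ** 2))
                    acc += amp * math.exp(-d2 / (2.0 * self.width**2))
            if self.linear_weights and sym in self.linear_weights:
                acc += float(self.linear_weights[sym] @ x)
            out[i] = acc
        return out

    def correction(
        self, structure: Structure, rep_config: RepresentationConfig
    ) -> float:
        return float(self.correction_per_atom(structure, rep_config).sum())


class ThreeBodyCorrection:
    """Off-class correction: angular three-body sum the pair-kernel model
    cannot represent exactly; used to probe graceful degradation."""

    def __init__(self, amplitude: float = 1.0, cutoff: float = 3.0):
        self.amplitude = amplitude
        self.cutoff = cutoff

    def correction(self, structure: Structure, rep_config=None) -> float:
        coords = structure.coords
        n = len(coords)
        total = 0.0
        diff = coords[None, :, :] - coords[:, None, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(r, np.inf)
        for i in range(n):
            nb = np.nonzero(r[i] < self.cutoff)[0]
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    j, k = nb[a], nb[b]
                    cth = float(diff[i, j] @ diff[i, k] / (r[i, j] * r[i, k]))
                    total += self.amplitude * cth
        return total


def draw_planted_correction(
    ensemble: Ensemble,
    rep_config: RepresentationConfig,
    n_bumps_per_element: int = 3,
    amplitude_sd: float = 3.0,
    width: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PlantedCorrectionSpec:
    """Plant bump centres on environments drawn from the ensemble itself."""
    rng = np.random.default_rng(seed)
    by_element: dict[str, list[np.ndarray]] = {}
    for rec in ensemble:
        mat = descriptor_matrix(rec.structure, rep_config)
        for i, sym in enumerate(rec.structure.elements):
            by_element.setdefault(sym, []).append(mat[i])
    bumps = []
    for sym, vectors in sorted(by_element.items()):
        count = min(n_bumps_per_element, len(vectors))
        idx = rng.choice(len(vectors), size=count, replace=False)
        for k in idx:
            amp = float(rng.normal(0.0, amplitude_sd))
            bumps.append((sym, np.array(vectors[int(k)]), amp))
    return PlantedCorrectionSpec(bumps, width=width, noise_sd=noise_sd)


def label_with_planted_delta(
    ensemble: Ensemble,
    baseline: Potential | ToyPotentialSpec,
    correction,
    seed: int = 0,
    rep_config: RepresentationConfig | None = None,
) -> Ensemble:
    """Label structures with baseline and reference energies.

    e_baseline = V_baseline + per-element atomic offsets;
    e_reference = e_baseline + different offsets + planted correction
    (+ optional noise).  The exact planted correction of each record is
    kept in ``structure.tags['true_delta']`` for recovery scoring.
    """
    rep_config = rep_config or RepresentationConfig()
    if isinstance(baseline, ToyPotentialSpec):
        baseline = make_potential(baseline)
    rng = np.random.default_rng(seed)
    noise_sd = getattr(correction, "noise_sd", 0.0)
    records = []
    for rec in ensemble:
        s = rec.structure.copy()
        v = baseline.evaluate(s)
        e_base = v + sum(BASELINE_ATOM_ENERGY[e] for e in s.elements)
        true_delta = float(correction.correction(s, rep_config))
        noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
        e_ref = (
            v
            + sum(REFERENCE_ATOM_ENERGY[e] for e in s.elements)
            + true_delta
            + noise
        )
        s.tags["true_delta"] = true_delta
        records.append(LabelledStructure(s, e_base, e_ref))
    return Ensemble(records)


def make_reservoir(
    potential: Potential | ToyPotentialSpec,
    n: int,
    temperature: float = 300.0,
    seed: int = 0,
    initial: Structure | None = None,
    step_sigma: float = 0.35,
    stride: int = 50,
    burnin: int = 2000,
) -> Ensemble:
    """Canonical reservoir: long Metropolis chain subsampled at a stride.

    Returns an ensemble of decorrelated samples labelled with their
    potential energy (``e_baseline``).
    """
    if n < 1:
        raise ValueError("reservoir size must be >= 1")
    if isinstance(potential, ToyPotentialSpec):
        potential = make_potential(potential)
    if initial is None:
        initial = Structure(("H",), np.zeros((1, 3)))
    config = MCConfig(
        n_steps=burnin + n * stride,
        step_sigma=step_sigma,
        seed=seed,
        temperature=temperature,
        snapshot_stride=stride,
        exchange_stride=10**9,
    )
    traj = run_metropolis(potential, config, initial)
    keep = [
        (s, c, e)
        for s, c, e in zip(traj.snapshot_steps, traj.snapshots[0], traj.energies[0])
        if s > burnin
    ][-n:]
    if len(keep) < n:
        raise ValueError("chain too short for requested reservoir size")
    structs = [
        Structure(initial.elements, c.copy(), {"step": s}) for s, c, _ in keep
    ]
    return Ensemble.from_structures(structs, e_baseline=[e for _, _, e in keep])
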