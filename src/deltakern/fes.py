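"""Collective variables and 2D free-energy surfaces.

Two geometric collective variables characterise ON/OFF conformational
states of azo-tethered amine photoswitches:

* ``d`` — the shortest distance (Angstrom) between the amine nitrogen
  and any atom of a designated blocking group (steric shielding of the
  catalytic lone pair), and
* ``theta`` — the signed distance (Angstrom) between the nitrogen and
  the plane through the three carbons bonded to it (N-pyramidalization /
  N-inversion coordinate).

The free-energy surface is the Boltzmann inversion of the sampled 2D
histogram, F(d, theta) = -k_B T ln rho(d, theta), gauge-fixed so the
occupied-bin minimum is zero.  Basin comparisons integrate Boltzmann
populations over user-supplied bin masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import KB_KCAL_MOL_K
from .structures import Structure

__all__ = [
    "CVSpec",
    "FESGrid",
    "cv_d",
    "cv_theta",
    "build_fes",
    "fes_from_cvs",
    "basin_delta_g",
]


class GeometryError(ValueError):
    """Raised for degenerate collective-variable geometry."""


class AnalysisError(ValueError):
    """Raised when a basin/region query cannot be answered."""


@dataclass
class CVSpec:
    """Atom indices defining the (d, theta) collective variables.

    orientation_reference : optional atom index fixing the sign of the
    plane normal for theta (the normal points towards this atom).  With
    ``None`` the sign follows the right-hand rule on the plane-atom
    ordering, which flips under mirror reflection.
    """

    n_index: int
    group_indices: tuple[int, ...]
    plane_indices: tuple[int, int, int]
    orientation_reference: int | None = None

    def __post_init__(self) -> None:
        self.group_indices = tuple(int(i) for i in self.group_indices)
        self.plane_indices = tuple(int(i) for i in self.plane_indices)
        if len(self.plane_indices) != 3 or len(set(self.plane_indices)) != 3:
            raise ValueError("plane_indices must be 3 distinct atom indices")
        if self.n_index in self.plane_indices:
            raise ValueError("n_index must not be one of the plane atoms")
        if not self.group_indices:
            raise ValueError("group_indices must be non-empty")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_index": self.n_index,
                "group_indices": list(self.group_indices),
                "plane_indices": list(self.plane_indices),
                "orientation_reference": self.orientation_reference,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CVSpec":
        d = json.loads(text)
        return cls(
            int(d["n_index"]),
            tuple(d["group_indices"]),
            tuple(d["plane_indices"]),
            d.get("orientation_reference"),
        )


def cv_d(structure: Structure, spec: CVSpec) -> float:
    """Shortest N-to-group distance (Angstrom)."""
    coords = structure.coords
    n = coords[spec.n_index]
    group = coords[list(spec.group_indices)]
    return float(np.min(np.linalg.norm(group - n, axis=1)))


def cv_theta(structure: Structure, spec: CVSpec) -> float:
    """Signed N-to-plane distance (Angstrom); see :class:`CVSpec` for sign."""
    coords = structure.coords
    p0, p1, p2 = (coords[i] for i in spec.plane_indices)
    normal = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(normal)
    if area2 / 2.0 <= 1e-6:
        raise GeometryError("plane atoms are (nearly) collinear")
    normal = normal / area2
    centroid = (p0 + p1 + p2) / 3.0
    if spec.orientation_reference is not None:
        ref = coords[spec.orientation_reference]
        side = float(normal @ (ref - centroid))
        if side < 0:
            normal = -normal
    return float(normal @ (coords[spec.n_index] - centroid))


@dataclass
class FESGrid:
    """Binned free energy over (d, theta) with the raw histogram attached.

    ``free_energy`` is +inf on empty bins (flagged, never given a finite
    value); the occupied-bin minimum is gauge-fixed at exactly 0.
    """

    d_edges: np.ndarray
    theta_edges: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def write(self, path) -> None:
        """Whitespace grid table (bin centres + F + count) with JSON header."""
        dc = 0.5 * (self.d_edges[:-1] + self.d_edges[1:])
        tc = 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])
        header = json.dumps(
            {
                "temperature": self.temperature,
                "d_edges": self.d_edges.tolist(),
                "theta_edges": self.theta_edges.tolist(),
            }
        )
        with open(path, "w") as fh:
            fh.write(f"#HEADER {header}\n")
            fh.write("# d theta free_energy count\n")
            for i, d in enumerate(dc):
                for j, t in enumerate(tc):
                    f = self.free_energy[i, j]
                    fh.write(
                        f"{d:.8g} {t:.8g} "
                        f"{'inf' if not np.isfinite(f) else format(f, '.10g')} "
                        f"{int(self.counts[i, j])}\n"
                    )

    @classmethod
    def read(cls, path) -> "FESGrid":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#HEADER "):
                raise ValueError("missing FES grid header")
            meta = json.loads(first[len("#HEADER "):])
            rows = [
                ln.split() for ln in fh if ln.strip() and not ln.startswith("#")
            ]
        d_edges = np.asarray(meta["d_edges"], float)
        theta_edges = np.asarray(meta["theta_edges"], float)
        nd, nt = len(d_edges) - 1, len(theta_edges) - 1
        fe = np.full((nd, nt), np.inf)
        counts = np.zeros((nd, nt), dtype=int)
        for k, row in enumerate(rows):
            i, j = divmod(k, nt)
            fe[i, j] = float(row[2])
            counts[i, j] = int(row[3])
        return cls(d_edges, theta_edges, fe, counts, float(meta["temperature"]))


def fes_from_cvs(
    d_values: Sequence[float],
    theta_values: Sequence[float],
    bins: tuple[int, int] = (60, 60),
    temperature: float = 300.0,
    ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> FESGrid:
    """Histogram collective-variable samples and Boltzmann-invert.

    The default grid spans the data range padded by 5 per cent on each
    side.  Empty bins stay at +inf.
    """
    d = np.asarray(d_values, float)
    t = np.asarray(theta_values, float)
    if d.size < 1 or d.shape != t.shape:
        raise ValueError("need >= 1 (d, theta) sample pairs of equal length")
    if temperature <= 0:
        raise ValueError("temperature must be positive")

    def _padded(x):
        lo, hi = float(np.min(x)), float(np.max(x))
        span = hi - lo
        pad = 0.05 * span if span > 0 else max(0.5, abs(lo) * 0.05, 1e-3)
        return lo - pad, hi + pad

    if ranges is None:
        ranges = (_padded(d), _padded(t))
    counts, d_edges, t_edges = np.histogram2d(d, t, bins=bins, range=ranges)
    kt = KB_KCAL_MOL_K * temperature
    with np.errstate(divide="ignore"):
        free = np.where(counts > 0, -kt * np.log(np.maximum(counts, 1e-300)), np.inf)
    occ = counts > 0
    if occ.sum() == 1:
        import warnings

        warnings.warn("all samples fall in a single bin", stacklevel=2)
    free = free - free[occ].min()
    free[~occ] = np.inf
    return FESGrid(d_edges, t_edges, free, counts.astype(int), temperature)


def build_fes(
    samples,
    spec: CVSpec,
    bins: tuple[int, int] = (60, 60),
    temperature: float = 300.0,
) -> FESGrid:
    """FES from structure samples (e.g. the lambda = 0 snapshot stream)."""
    structures = getattr(samples, "structures", samples)
    d = [cv_d(s, spec) for s in structures]
    t = [cv_theta(s, spec) for s in structures]
    return fes_from_cvs(d, t, bins=bins, temperature=temperature)


def basin_delta_g(
    grid: FESGrid,
    region_a: np.ndarray,
    region_b: np.ndarray,
    mode: str = "population",
) -> float:
    """Free-energy difference of basin A relative to basin B (kcal/mol).

    ``population`` (default): Delta G = k_B T ln(P_A / P_B) from the
    integrated Boltzmann populations, so a positive value means A is the
    more stable (more populated) basin.  ``minimum``: depth difference of
    the basin minima, F_min(B) - F_min(A).  Antisymmetric in both modes.
    """
    a = np.asarray(region_a, bool)
    b = np.asarray(region_b, bool)
    if a.shape != grid.counts.shape or b.shape != grid.counts.shape:
        raise ValueError("region masks must match the grid shape")
    occ = grid.occupied
    if not (a & occ).any() or not (b & occ).any():
        raise AnalysisError("both regions must contain occupied bins")
    kt = KB_KCAL_MOL_K * grid.temperature
    if mode == "population":
        pa = grid.counts[a].sum()
        pb = grid.counts[b].sum()
        return float(kt * np.log(pa / pb))
    if mode == "minimum":
        return float(grid.free_energy[b & occ].min() - grid.free_energy[a & occ].min())
    raise ValueError("mode must be 'population' or 'minimum'")


def basin_delta_g_from_free_energy(
    grid: FESGrid, region_a: np.ndarray, region_b: np.ndarray
) -> float:
    """Population Delta G recomputed from the free-energy grid by log-sum-exp.

    Algebraically identical to the count-based route (F is -kT ln counts
    up to the gauge constant, which cancels in the difference); kept as an
    independent algebraic path for validation.
    """
    a = np.asarray(region_a, bool) & grid.occupied
    b = np.asarray(region_b, bool) & grid.occupied
    if not a.any() or not b.any():
        raise AnalysisError("both regions must contain occupied bins")
    kt = KB_KCAL_MOL_K * grid.temperature
    la = logsumexp(-grid.free_energy[a] / kt)
    lb = logsumexp(-grid.free_energy[b] / kt)
    return float(kt * (la - lb))
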