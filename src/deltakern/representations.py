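"""Per-atom local environment descriptors and per-structure global descriptors.

The descriptor is a contract, not a fixed external implementation: any
element-tagged, fixed-length, rotation/translation-invariant, smoothly
cut-off and local map from a structure to per-atom vectors works with the
selection and kernel machinery.  The default implementation expands each
atom's neighbourhood in

* element-resolved radial Gaussians times a smooth cosine cutoff at
  ``r_cut`` (2-body channels), and
* element-pair-resolved Gaussians over the cosine of the bond angle,
  weighted by cosine cutoffs at the shorter angular cutoff ``a_cut``
  (3-body channels),

mirroring the structure (radial 5 A cutoff, angular 4 A cutoff) of the
atom-centred representations used for kernel potentials in this domain.
An adapter producing the same ``(N, D)`` matrix layout can be dropped in
for exact parity with external descriptor packages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass


import numpy as np

from .structures import ELEMENT_INDEX, SUPPORTED_ELEMENTS, Structure

__all__ = [
    "RepresentationConfig",
    "AtomicEnvironment",
    "GlobalDescriptor",
    "atomic_descriptors",
    "descriptor_matrix",
    "global_descriptor",
    "save_descriptors",
    "load_descriptors",
]


@dataclass(frozen=True)
class RepresentationConfig:
    """Hyperparameters of the default radial+angular descriptor.

    r_cut : radial cutoff in Angstrom (2-body channels).
    a_cut : angular cutoff in Angstrom (3-body channels); a_cut <= r_cut.
    n_radial / n_angular : basis sizes per element (pair) channel.
    """

    r_cut: float = 5.0
    a_cut: float = 4.0
    n_radial: int = 24
    n_angular: int = 12
    elements: tuple[str, ...] = SUPPORTED_ELEMENTS

    def __post_init__(self) -> None:
        if not (self.r_cut > 0 and self.a_cut > 0):
            raise ValueError("cutoffs must be positive")
        if self.a_cut > self.r_cut:
            raise ValueError("a_cut must not exceed r_cut")
        if self.n_radial < 1 or self.n_angular < 1:
            raise ValueError("basis sizes must be >= 1")

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_pairs(self) -> int:
        ne = self.n_elements
        return ne * (ne + 1) // 2

    @property
    def length(self) -> int:
        """Deterministic descriptor length for this config."""
        return self.n_elements * self.n_radial + self.n_pairs * self.n_angular

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "r_cut": self.r_cut,
                "a_cut": self.a_cut,
                "n_radial": self.n_radial,
                "n_angular": self.n_angular,
                "elements": list(self.elements),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "r_cut": self.r_cut,
            "a_cut": self.a_cut,
            "n_radial": self.n_radial,
            "n_angular": self.n_angular,
            "elements": list(self.elements),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RepresentationConfig":
        return cls(
            r_cut=float(d["r_cut"]),
            a_cut=float(d["a_cut"]),
            n_radial=int(d["n_radial"]),
            n_angular=int(d["n_angular"]),
            elements=tuple(d["elements"]),
        )


@dataclass
class AtomicEnvironment:
    """Descriptor vector of one atom, tagged by its central element."""

    element: str
    vector: np.ndarray
    source: tuple = (None, None)  # (structure id, atom index)


@dataclass
class GlobalDescriptor:
    """Whole-structure descriptor (element-resolved sum of atomic vectors)."""

    vector: np.ndarray


_R_MIN = 0.5  # shortest radial basis centre (A); below typical contacts


def _cutoff(r: np.ndarray, rc: float) -> np.ndarray:
    """Smooth cosine cutoff: 1/2 (cos(pi r / rc) + 1) inside, 0 at/beyond rc."""
    out = 0.5 * (np.cos(np.pi * np.minimum(r, rc) / rc) + 1.0)
    return np.where(r < rc, out, 0.0)


def _pair_channel_table(n_elem: int) -> np.ndarray:
    table = np.zeros((n_elem, n_elem), dtype=int)
    ch = 0
    for a in range(n_elem):
        for b in range(a, n_elem):
            table[a, b] = table[b, a] = ch
            ch += 1
    return table


from functools import lru_cache


@lru_cache(maxsize=512)
def _triu_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


@lru_cache(maxsize=32)
def _plan(config: RepresentationConfig):
    """Precomputed basis centres / widths / channel tables for one config."""
    nr, na = config.n_radial, config.n_angular
    if nr > 1:
        mu = np.linspace(_R_MIN, config.r_cut, nr)
        width = (config.r_cut - _R_MIN) / (nr - 1)
    else:
        mu = np.array([0.5 * (config.r_cut + _R_MIN)])
        width = config.r_cut - _R_MIN
    centers = np.linspace(-1.0, 1.0, na) if na > 1 else np.array([0.0])
    aw = 2.0 / na
    ptable = _pair_channel_table(config.n_elements)
    lookup = {s: k for k, s in enumerate(config.elements)}
    return mu, width, centers, aw, ptable, lookup


def descriptor_matrix(structure: Structure, config: RepresentationConfig) -> np.ndarray:
    """Descriptor vectors for every atom, shape ``(n_atoms, config.length)``.

    Fast path used by model prediction inside samplers; see
    :func:`atomic_descriptors` for the tagged-object API.
    """
    n = structure.n_atoms
    ne = config.n_elements
    mu, width, centers, aw, ptable, lookup = _plan(config)
    elem_idx = np.fromiter(
        (lookup[s] for s in structure.elements), dtype=np.intp, count=n
    )
    nr, na = config.n_radial, config.n_angular
    rad = np.zeros((n, ne, nr))
    ang = np.zeros((n, config.n_pairs, na))

    coords = structure.coords
    diff = coords[None, :, :] - coords[:, None, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(r, np.inf)

    # 2-body radial expansion
    ii, jj = np.nonzero(r < config.r_cut)
    if ii.size:
        rij = r[ii, jj]
        fc = _cutoff(rij, config.r_cut)
        vals = np.exp(-((rij[:, None] - mu) ** 2) / (2.0 * width**2)) * fc[:, None]
        np.add.at(rad, (ii, elem_idx[jj]), vals)

    # 3-body angular expansion within a_cut (flattened over all centres)
    amask = r < config.a_cut
    nb_ct = amask.sum(axis=1)
    if (nb_ct >= 2).any():
        ci, cj = np.nonzero(amask)  # row-major: grouped by centre atom
        rnb = r[ci, cj]
        U = diff[ci, cj] / rnb[:, None]
        W = _cutoff(rnb, config.a_cut)
        EJ = elem_idx[cj]
        pa_parts, pb_parts, ctr_parts = [], [], []
        start = 0
        for i in range(n):
            c = int(nb_ct[i])
            if c >= 2:
                a_idx, b_idx = _triu_pairs(c)
                pa_parts.append(a_idx + start)
                pb_parts.append(b_idx + start)
                ctr_parts.append(np.full(a_idx.size, i, dtype=np.intp))
            start += c
        pa = np.concatenate(pa_parts)
        pb = np.concatenate(pb_parts)
        ctr = np.concatenate(ctr_parts)
        cth = np.clip(np.einsum("ij,ij->i", U[pa], U[pb]), -1.0, 1.0)
        wpair = W[pa] * W[pb]
        g = (
            np.exp(-((cth[:, None] - centers) ** 2) / (2.0 * aw**2))
            * wpair[:, None]
        )
        chan = ptable[EJ[pa], EJ[pb]]
        np.add.at(ang, (ctr, chan), g)

    return np.concatenate(
        [rad.reshape(n, ne * nr), ang.reshape(n, config.n_pairs * na)], axis=1
    )


def atomic_descriptors(
    structure: Structure,
    config: RepresentationConfig,
    structure_id=None,
) -> list[AtomicEnvironment]:
    """One :class:`AtomicEnvironment` per atom, in atom order."""
    mat = descriptor_matrix(structure, config)
    return [
        AtomicEnvironment(structure.elements[i], mat[i], (structure_id, i))
        for i in range(structure.n_atoms)
    ]


def global_descriptor(
    structure: Structure, config: RepresentationConfig
) -> GlobalDescriptor:
    """Element-resolved sums of atomic descriptors, concatenated.

    Permutation-invariant over same-element atoms and rigid-motion
    invariant; used for diversity selection over whole conformers.
    """
    mat = descriptor_matrix(structure, config)
    blocks = np.zeros((config.n_elements, config.length))
    for i, sym in enumerate(structure.elements):
        blocks[config.elements.index(sym)] += mat[i]
    return GlobalDescriptor(blocks.reshape(-1))


def save_descriptors(prefix, matrix: np.ndarray, config: RepresentationConfig) -> None:
    """Persist a descriptor matrix with a JSON sidecar recording the config."""
    prefix = str(prefix)
    np.save(prefix + ".npy", np.asarray(matrix))
    with open(prefix + ".json", "w") as fh:
        json.dump(
            {"config": config.to_dict(), "hash": config.config_hash()}, fh, indent=1
        )


def load_descriptors(prefix, config: RepresentationConfig) -> np.ndarray:
    """Load a descriptor matrix, refusing a mismatched config hash."""
    prefix = str(prefix)
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    if meta["hash"] != config.config_hash():
        raise ValueError(
            "descriptor file was computed under a different representation "
            f"config (hash {meta['hash']} != {config.config_hash()})"
        )
    return np.load(prefix + ".npy")
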