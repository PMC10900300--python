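"""Volumetric scalar fields from per-atom corrections, with cube export.

Each atom's correction c_i (kcal/mol) is smeared by a unit-integral 3D
Gaussian of configurable width centred on the atom,

    field(r) = sum_i c_i G(r - r_i; width),

so the grid integral of the field recovers the summed corrections and
amplitudes carry energy per volume.  Fields export to Gaussian cube
(header in Bohr per the format) for isosurface rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import BOHR_PER_ANGSTROM
from .structures import ATOMIC_NUMBERS, Structure, SUPPORTED_ELEMENTS

__all__ = ["FieldConfig", "ScalarField", "build_field", "write_cube", "read_cube"]

_NUMBER_TO_SYMBOL = {z: s for s, z in ATOMIC_NUMBERS.items()}


@dataclass(frozen=True)
class FieldConfig:
    """Gaussian width, grid spacing and padding, all in Angstrom."""

    gaussian_width: float = 1.0
    grid_spacing: float = 0.2
    padding: float = 4.0
    isovalues: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        if min(self.gaussian_width, self.grid_spacing, self.padding) <= 0:
            raise ValueError("width, spacing and padding must be positive")


@dataclass
class ScalarField:
    """Regular grid: origin (A), per-axis spacing (A), 3D value array."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.values.shape[k])
            for k in range(3)
        )

    def integral(self) -> float:
        """Grid integral (value sum times voxel volume)."""
        return float(self.values.sum() * np.prod(self.spacing))


def build_field(
    structure: Structure,
    per_atom: np.ndarray,
    config: FieldConfig | None = None,
) -> ScalarField:
    """Superpose unit-integral atom-centred Gaussians scaled by corrections.

    The Gaussian factorises per axis, so each atom adds an outer product
    of three 1D profiles -- cheap even on fine grids.
    """
    config = config or FieldConfig()
    per_atom = np.asarray(per_atom, float)
    if structure.n_atoms == 0 or per_atom.shape != (structure.n_atoms,):
        raise ValueError("per_atom must hold one correction per atom")
    lo = structure.coords.min(axis=0) - config.padding
    hi = structure.coords.max(axis=0) + config.padding
    npts = np.maximum(np.ceil((hi - lo) / config.grid_spacing).astype(int) + 1, 2)
    spacing = np.full(3, config.grid_spacing)
    axes = [lo[k] + spacing[k] * np.arange(npts[k]) for k in range(3)]
    w = config.gaussian_width
    norm1d = 1.0 / (np.sqrt(2.0 * np.pi) * w)
    values = np.zeros(tuple(npts))
    for c, pos in zip(per_atom, structure.coords):
        if c == 0.0:
            continue
        gx = norm1d * np.exp(-((axes[0] - pos[0]) ** 2) / (2 * w**2))
        gy = norm1d * np.exp(-((axes[1] - pos[1]) ** 2) / (2 * w**2))
        gz = norm1d * np.exp(-((axes[2] - pos[2]) ** 2) / (2 * w**2))
        values += c * np.einsum("i,j,k->ijk", gx, gy, gz)
    return ScalarField(lo, spacing, values)


def write_cube(field: ScalarField, structure: Structure, path) -> None:
    """Write a Gaussian cube file (lengths converted to Bohr)."""
    b = BOHR_PER_ANGSTROM
    nx, ny, nz = field.values.shape
    with open(path, "w") as fh:
        fh.write("deltakern correction field\n")
        fh.write("atomic corrections smeared by normalized Gaussians\n")
        fh.write(
            f"{structure.n_atoms:5d} {field.origin[0]*b:12.6f} "
            f"{field.origin[1]*b:12.6f} {field.origin[2]*b:12.6f}\n"
        )
        fh.write(f"{nx:5d} {field.spacing[0]*b:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {field.spacing[1]*b:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {field.spacing[2]*b:12.6f}\n")
        for sym, pos in zip(structure.elements, structure.coords):
            z = ATOMIC_NUMBERS[sym]
            fh.write(
                f"{z:5d} {0.0:12.6f} {pos[0]*b:12.6f} "
                f"{pos[1]*b:12.6f} {pos[2]*b:12.6f}\n"
            )
        flat = field.values.reshape(nx * ny, nz)
        for row in flat:
            for start in range(0, nz, 6):
                fh.write(
                    " ".join(f"{v: .5E}" for v in row[start : start + 6]) + "\n"
                )


def read_cube(path) -> tuple[ScalarField, Structure]:
    """Read back a cube written by :func:`write_cube` (values as stored)."""
    b = BOHR_PER_ANGSTROM
    with open(path) as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        natoms = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]]) / b
        npts = []
        spacing = []
        for k in range(3):
            parts = fh.readline().split()
            npts.append(int(parts[0]))
            spacing.append(float(parts[1 + k]) / b)
        symbols = []
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            parts = fh.readline().split()
            symbols.append(_NUMBER_TO_SYMBOL[int(parts[0])])
            coords[a] = [float(x) / b for x in parts[2:5]]
        data = np.array(fh.read().split(), dtype=float)
    values = data.reshape(tuple(npts))
    return (
        ScalarField(origin, np.array(spacing), values),
        Structure(tuple(symbols), coords),
    )
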