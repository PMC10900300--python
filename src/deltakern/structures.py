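"""Molecular structures, energy labels and extended-XYZ I/O.

The toolkit targets organic molecules composed of H, C, N, O, F and S
atoms.  Coordinates are Cartesian in Angstrom, energies in kcal/mol.
Multi-frame extended XYZ (atom count line, ``key=value`` comment line,
one ``symbol x y z`` line per atom) is the sole structure format.
"""

from __future__ import annotations

import math
import shlex
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: Canonical element order used by every composition-indexed model.
SUPPORTED_ELEMENTS: tuple[str, ...] = ("H", "C", "N", "O", "F", "S")

ELEMENT_INDEX: dict[str, int] = {e: i for i, e in enumerate(SUPPORTED_ELEMENTS)}

ATOMIC_NUMBERS: dict[str, int] = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "S": 16}

#: Default comment-line keys carrying the two energy labels.
DEFAULT_ENERGY_KEYS: tuple[str, str] = ("e_baseline", "e_reference")


class ElementError(ValueError):
    """Raised when a structure contains an unsupported chemical symbol."""


class ParseError(ValueError):
    """Raised on malformed extended-XYZ input; carries the frame index."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


class LabelError(ValueError):
    """Raised when a required energy label is missing or non-finite."""


@dataclass
class Structure:
    """Elements plus Cartesian coordinates (Angstrom) with free-form tags."""

    elements: tuple[str, ...]
    coords: np.ndarray
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        if len(self.elements) < 1:
            raise ValueError("structure needs at least one atom")
        for sym in self.elements:
            if sym not in ELEMENT_INDEX:
                raise ElementError(f"unsupported element symbol: {sym!r}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "Structure":
        return Structure(self.elements, self.coords.copy(), dict(self.tags))


@dataclass
class LabelledStructure:
    """A structure with optional baseline and reference energies (kcal/mol)."""

    structure: Structure
    e_baseline: float | None = None
    e_reference: float | None = None

    def __post_init__(self) -> None:
        for name in ("e_baseline", "e_reference"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not math.isfinite(v):
                    raise LabelError(f"{name} must be finite, got {v}")
                setattr(self, name, v)

    @property
    def has_both(self) -> bool:
        return self.e_baseline is not None and self.e_reference is not None

    def require_both(self) -> None:
        if not self.has_both:
            raise LabelError(
                "training record requires both e_baseline and e_reference"
            )


@dataclass
class Ensemble:
    """Ordered collection of labelled structures.

    Uniform element sequence (frames of one molecule) is not enforced on
    construction because training sets legitimately mix molecules; call
    :meth:`require_uniform` where a trajectory/reservoir is expected.
    """

    records: list[LabelledStructure] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LabelledStructure]:
        return iter(self.records)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Ensemble(self.records[i])
        return self.records[i]

    @property
    def structures(self) -> list[Structure]:
        return [r.structure for r in self.records]

    def require_uniform(self) -> None:
        """Assert all members share one element sequence."""
        if not self.records:
            return
        first = self.records[0].structure.elements
        for i, rec in enumerate(self.records):
            if rec.structure.elements != first:
                raise ValueError(
                    f"ensemble is not uniform: frame {i} has elements "
                    f"{rec.structure.elements} != {first}"
                )

    @classmethod
    def from_structures(
        cls,
        structures: Sequence[Structure],
        e_baseline: Sequence[float] | None = None,
        e_reference: Sequence[float] | None = None,
    ) -> "Ensemble":
        records = []
        for i, s in enumerate(structures):
            records.append(
                LabelledStructure(
                    s,
                    None if e_baseline is None else e_baseline[i],
                    None if e_reference is None else e_reference[i],
                )
            )
        return cls(records)


def composition_vector(structure: Structure) -> np.ndarray:
    """Integer element counts in the canonical order H, C, N, O, F, S."""
    v = np.zeros(len(SUPPORTED_ELEMENTS), dtype=int)
    for sym in structure.elements:
        v[ELEMENT_INDEX[sym]] += 1
    return v


def _parse_comment(comment: str) -> dict[str, str]:
    """Parse ``key=value`` tokens from an extended-XYZ comment line."""
    out: dict[str, str] = {}
    try:
        tokens = shlex.split(comment)
    except ValueError:
        tokens = comment.split()
    for tok in tokens:
        if "=" in tok:
            key, _, val = tok.partition("=")
            out[key] = val.strip('"')
    return out


def read_extxyz(
    path,
    energy_keys: tuple[str, str] = DEFAULT_ENERGY_KEYS,
) -> Ensemble:
    """Read a multi-frame extended-XYZ file into an :class:`Ensemble`.

    Per-frame ``key=value`` properties on the comment line are kept in
    ``structure.tags``; the two configurable energy keys become
    ``e_baseline`` / ``e_reference`` labels when present.
    """
    base_key, ref_key = energy_keys
    records: list[LabelledStructure] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame = 0
    n_lines = len(lines)
    while pos < n_lines:
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError(
                f"frame {frame}: expected atom count, got {lines[pos]!r}",
                frame=frame,
            )
        if pos + 1 + natoms >= n_lines + 1 or natoms < 1:
            raise ParseError(
                f"frame {frame}: declares {natoms} atoms but file is truncated",
                frame=frame,
            )
        comment = lines[pos + 1] if pos + 1 < n_lines else ""
        props = _parse_comment(comment)
        elements: list[str] = []
        coords = np.empty((natoms, 3), dtype=float)
        for a in range(natoms):
            ln = pos + 2 + a
            if ln >= n_lines:
                raise ParseError(
                    f"frame {frame}: declares {natoms} atoms but only "
                    f"{a} atom lines follow",
                    frame=frame,
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(
                    f"frame {frame}: malformed atom line {lines[ln]!r}",
                    frame=frame,
                )
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"frame {frame}: non-numeric coordinate in {lines[ln]!r}",
                    frame=frame,
                )
            elements.append(parts[0])
            coords[a] = xyz
        tags = {
            k: v
            for k, v in props.items()
            if k not in (base_key, ref_key, "Properties")
        }
        tags["frame"] = frame
        structure = Structure(tuple(elements), coords, tags)

        def _energy(key: str) -> float | None:
            if key not in props:
                return None
            try:
                return float(props[key])
            except ValueError:
                raise ParseError(
                    f"frame {frame}: energy key {key}={props[key]!r} "
                    "is not a number",
                    frame=frame,
                )

        records.append(
            LabelledStructure(structure, _energy(base_key), _energy(ref_key))
        )
        pos += 2 + natoms
        frame += 1
    return Ensemble(records)


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_extxyz(
    ensemble: Ensemble,
    path,
    energy_keys: tuple[str, str] = DEFAULT_ENERGY_KEYS,
) -> None:
    """Write an ensemble as multi-frame extended XYZ (round-trip exact)."""
    base_key, ref_key = energy_keys
    with open(path, "w") as fh:
        for rec in ensemble:
            s = rec.structure
            parts = ["Properties=species:S:1:pos:R:3"]
            if rec.e_baseline is not None:
                parts.append(f"{base_key}={_fmt(rec.e_baseline)}")
            if rec.e_reference is not None:
                parts.append(f"{ref_key}={_fmt(rec.e_reference)}")
            for key, val in s.tags.items():
                if key == "frame":
                    continue
                sval = str(val)
                if " " in sval:
                    sval = f'"{sval}"'
                parts.append(f"{key}={sval}")
            fh.write(f"{s.n_atoms}\n{' '.join(parts)}\n")
            for sym, (x, y, z) in zip(s.elements, s.coords):
                fh.write(f"{sym} {_fmt(x)} {_fmt(y)} {_fmt(z)}\n")
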