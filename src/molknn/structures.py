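"""Molecular structures, labelled datasets and multi-frame XYZ I/O.

Coordinates are Cartesian, in Angstrom, both on disk and in memory;
descriptor code converts to Bohr internally where the descriptor
literature demands it.  Labels ride on the XYZ comment line as
whitespace-separated ``key=value`` tokens (our convention, compatible
with extended-XYZ files in the wild); unknown tokens are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATOMIC_NUMBERS",
    "MolecularStructure",
    "LabeledDataset",
    "read_xyz",
    "write_xyz",
    "parse_composition",
    "format_composition",
]

# fmt: off
_SYMBOLS = [
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn",
]
# fmt: on

#: Map element symbol -> atomic number (H..Rn).
ATOMIC_NUMBERS: dict[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}


def normalize_symbol(symbol: str) -> str:
    """Case-normalize an element symbol ('cl' -> 'Cl'); raise on unknown."""
    sym = symbol.strip().capitalize()
    if sym not in ATOMIC_NUMBERS:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return sym


@dataclass
class MolecularStructure:
    """A molecular structure: element symbols plus Cartesian coordinates (A).

    Parameters
    ----------
    elements
        Element symbols, one per atom.
    coordinates
        ``(n_atoms, 3)`` array of Cartesian coordinates in Angstrom.
    composition
        Optional map from building-unit name to count, e.g. ``{"SA": 4, "W": 5}``.
    id
        Opaque identifier string.
    """

    elements: list[str]
    coordinates: np.ndarray
    composition: dict[str, int] | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if len(self.elements) != self.coordinates.shape[0]:
            raise ValueError(
                f"{len(self.elements)} element symbols but "
                f"{self.coordinates.shape[0]} coordinate rows"
            )
        if len(self.elements) < 1:
            raise ValueError("structure must contain at least one atom")
        self.elements = [normalize_symbol(s) for s in self.elements]

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.elements], dtype=int)


@dataclass
class LabeledDataset:
    """Structures with high-level labels and optional low-level labels.

    ``y_high``/``y_low`` are per-structure scalar labels (kcal/mol by
    convention).  ``y_low`` is present iff delta-learning is intended.
    """

    structures: list[MolecularStructure] = field(default_factory=list)
    y_high: np.ndarray | None = None
    y_low: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("y_high", "y_low"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.ndim != 1 or len(v) != len(self.structures):
                    raise ValueError(
                        f"{name} must be a vector with one entry per structure"
                    )
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.structures)

    def subset(self, indices) -> "LabeledDataset":
        """Return a new dataset restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            structures=[self.structures[i] for i in idx],
            y_high=None if self.y_high is None else self.y_high[idx],
            y_low=None if self.y_low is None else self.y_low[idx],
        )

    @property
    def element_set(self) -> list[str]:
        """Sorted (by atomic number) union of elements over all structures."""
        seen = set()
        for s in self.structures:
            seen.update(s.elements)
        return sorted(seen, key=lambda e: ATOMIC_NUMBERS[e])


_COMP_TOKEN = re.compile(r"\(([A-Za-z][A-Za-z0-9]*)\)(\d+)")


def parse_composition(name: str) -> dict[str, int]:
    """Parse a parenthesized unit-count composition string.

    ``"(SA)4(W)5"`` -> ``{"SA": 4, "W": 5}``.
    """
    name = name.strip()
    if not name:
        raise ValueError("empty composition string")
    out: dict[str, int] = {}
    pos = 0
    for m in _COMP_TOKEN.finditer(name):
        if m.start() != pos:
            raise ValueError(f"malformed composition string: {name!r}")
        unit, count = m.group(1), int(m.group(2))
        if count < 1:
            raise ValueError(f"non-positive count for unit {unit!r} in {name!r}")
        if unit in out:
            raise ValueError(f"repeated unit {unit!r} in {name!r}")
        out[unit] = count
        pos = m.end()
    if pos != len(name) or not out:
        raise ValueError(f"malformed composition string: {name!r}")
    return out


def format_composition(composition: dict[str, int]) -> str:
    """Inverse of :func:`parse_composition`; units sorted alphabetically."""
    return "".join(f"({u}){int(c)}" for u, c in sorted(composition.items()))


def _parse_comment(comment: str) -> dict[str, str]:
    tokens = comment.split()
    out = {}
    for tok in tokens:
        if "=" in tok:
            key, _, value = tok.partition("=")
            if key:
                out[key] = value
    return out


def read_xyz(
    path,
    label_key: str = "E_high",
    low_label_key: str = "E_low",
) -> LabeledDataset:
    """Read a multi-frame XYZ file into a :class:`LabeledDataset`.

    The comment line of each frame may carry ``key=value`` tokens; labels
    are taken from ``label_key`` (and ``low_label_key``) when present in
    every frame, an ``id=`` token names the structure, and a ``comp=``
    token in parenthesized unit-count notation attaches composition
    metadata.  A label key missing from all frames yields an unlabeled
    dataset; present in only some frames it is an error.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    structures: list[MolecularStructure] = []
    highs: list[float | None] = []
    lows: list[float | None] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(
                f"frame {frame}: expected atom count, got {lines[i]!r}"
            ) from exc
        if n_atoms < 1:
            raise ValueError(f"frame {frame}: atom count must be >= 1")
        if i + 1 + n_atoms >= len(lines) + 1 and i + 1 + n_atoms > len(lines):
            raise ValueError(
                f"frame {frame}: declares {n_atoms} atoms but file ends early"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta = _parse_comment(comment)
        elements: list[str] = []
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            row_idx = i + 2 + a
            if row_idx >= len(lines):
                raise ValueError(
                    f"frame {frame}: declares {n_atoms} atoms but file ends early"
                )
            parts = lines[row_idx].split()
            if len(parts) < 4:
                raise ValueError(
                    f"frame {frame}: atom count disagrees with atom lines "
                    f"(bad line {row_idx + 1}: {lines[row_idx]!r})"
                )
            try:
                coords[a] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ValueError(
                    f"frame {frame}: atom count disagrees with atom lines "
                    f"(bad line {row_idx + 1}: {lines[row_idx]!r})"
                ) from exc
            elements.append(normalize_symbol(parts[0]))
        comp = parse_composition(meta["comp"]) if "comp" in meta else None
        structures.append(
            MolecularStructure(
                elements=elements,
                coordinates=coords,
                composition=comp,
                id=meta.get("id", f"frame{frame}"),
            )
        )
        highs.append(float(meta[label_key]) if label_key in meta else None)
        lows.append(float(meta[low_label_key]) if low_label_key in meta else None)
        i += 2 + n_atoms
        frame += 1

    def _collect(values: list, key: str):
        have = [v is not None for v in values]
        if not any(have):
            return None
        if not all(have):
            missing = have.index(False)
            raise ValueError(f"label {key!r} missing from frame {missing}")
        return np.array(values, dtype=float)

    return LabeledDataset(
        structures=structures,
        y_high=_collect(highs, label_key),
        y_low=_collect(lows, low_label_key),
    )


def write_xyz(
    dataset: LabeledDataset,
    path,
    label_key: str = "E_high",
    low_label_key: str = "E_low",
) -> None:
    """Write a dataset as multi-frame XYZ with ``key=value`` comment labels.

    Coordinates are printed with 14 significant digits and labels with 17,
    so a write/read round trip preserves labels bit-for-text.
    """
    with open(path, "w") as fh:
        for i, s in enumerate(dataset.structures):
            tokens = [f"id={s.id}"]
            if dataset.y_high is not None:
                tokens.append(f"{label_key}={float(dataset.y_high[i]):.17g}")
            if dataset.y_low is not None:
                tokens.append(f"{low_label_key}={float(dataset.y_low[i]):.17g}")
            if s.composition:
                tokens.append(f"comp={format_composition(s.composition)}")
            fh.write(f"{s.n_atoms}\n")
            fh.write(" ".join(tokens) + "\n")
            for el, (x, y, z) in zip(s.elements, s.coordinates):
                fh.write(f"{el} {x:.14g} {y:.14g} {z:.14g}\n")
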