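"""Molecular descriptors: Coulomb matrix, Bag of Bonds, local many-body.

The local many-body descriptor is a simplified 2-/3-body atomic
environment vector in the spirit of discretized interatomic-distribution
representations: a Gaussian-smeared radial histogram per neighbour
element (two-body) and a Gaussian-smeared angular histogram per
unordered neighbour-element pair (three-body), both damped by a smooth
cosine cutoff ``f_cut(r) = 0.5 (1 + cos(pi r / r_c))``.  Summing the
atomic rows yields a fixed-length global vector for the whole system.

Coulomb matrix and Bag of Bonds follow the literature convention of
interatomic distances in Bohr (1 A = 1.8897259886 Bohr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

from molknn.structures import (
    ATOMIC_NUMBERS,
    LabeledDataset,
    MolecularStructure,
)

__all__ = [
    "ANGSTROM_TO_BOHR",
    "LocalRepresentation",
    "GlobalRepresentation",
    "ManyBodyParams",
    "coulomb_matrix",
    "bag_of_bonds",
    "bob_bag_sizes",
    "local_manybody",
    "globalize",
    "local_representations",
    "global_matrix",
    "export_representations",
    "import_representations",
]

logger = logging.getLogger(__name__)

ANGSTROM_TO_BOHR = 1.8897259886


@dataclass
class LocalRepresentation:
    """Per-atom descriptor matrix: one environment vector per atom."""

    per_atom: np.ndarray  # (n_atoms, p)
    atom_elements: list[str]
    feature_schema: tuple = ()

    def __post_init__(self) -> None:
        self.per_atom = np.atleast_2d(np.asarray(self.per_atom, dtype=float))
        if self.per_atom.shape[0] != len(self.atom_elements):
            raise ValueError("one descriptor row per atom required")
        if not np.all(np.isfinite(self.per_atom)):
            raise ValueError("non-finite descriptor entries")

    @property
    def n_atoms(self) -> int:
        return self.per_atom.shape[0]

    @property
    def dim(self) -> int:
        return self.per_atom.shape[1]


@dataclass
class GlobalRepresentation:
    """Fixed-length descriptor vector for a whole structure."""

    vector: np.ndarray
    feature_schema: tuple = ()

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("non-finite descriptor entries")

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


def _sorted_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def coulomb_matrix(
    structure: MolecularStructure, max_atoms: int
) -> GlobalRepresentation:
    """Row-norm-sorted Coulomb matrix, flattened upper triangle, zero-padded.

    ``M_ii = 0.5 Z_i^2.4``, ``M_ij = Z_i Z_j / r_ij`` with ``r_ij`` in Bohr.
    Rows and columns are sorted by descending row norm, so the output is
    invariant to the input atom order.
    """
    n = structure.n_atoms
    if n > max_atoms:
        raise ValueError(f"structure has {n} atoms but max_atoms={max_atoms}")
    z = structure.atomic_numbers.astype(float)
    m = np.outer(z, z)
    if n > 1:
        r_bohr = squareform(pdist(structure.coordinates)) * ANGSTROM_TO_BOHR
        with np.errstate(divide="ignore"):
            m = m / r_bohr
    np.fill_diagonal(m, 0.5 * z**2.4)
    order = np.argsort(-np.linalg.norm(m, axis=1), kind="stable")
    m = m[np.ix_(order, order)]
    padded = np.zeros((max_atoms, max_atoms))
    padded[:n, :n] = m
    iu = np.triu_indices(max_atoms)
    schema = ("coulomb_matrix", max_atoms)
    return GlobalRepresentation(vector=padded[iu], feature_schema=schema)


def bob_bag_sizes(dataset: LabeledDataset) -> dict[tuple[str, str], int]:
    """Maximal per-pair bond counts over a dataset (the bag sizes)."""
    sizes: dict[tuple[str, str], int] = {}
    for s in dataset.structures:
        counts: dict[tuple[str, str], int] = {}
        els = s.elements
        for i in range(len(els)):
            for j in range(i + 1, len(els)):
                p = _sorted_pair(els[i], els[j])
                counts[p] = counts.get(p, 0) + 1
        for p, c in counts.items():
            sizes[p] = max(sizes.get(p, 0), c)
    return sizes


def bag_of_bonds(
    structure: MolecularStructure, bag_sizes: dict[tuple[str, str], int]
) -> GlobalRepresentation:
    """Bag of Bonds: per element pair, sorted ``Z_i Z_j / r_ij`` values.

    Each unordered element pair gets a fixed-size bag; the Coulomb terms
    (r in Bohr) of that pair's bonds are sorted descending and zero-padded
    to the bag size.  Bags are concatenated in lexicographic pair order.
    """
    bag_sizes = {_sorted_pair(*k): v for k, v in bag_sizes.items()}
    z = dict(ATOMIC_NUMBERS)
    bags: dict[tuple[str, str], list[float]] = {p: [] for p in bag_sizes}
    els = structure.elements
    coords = structure.coordinates
    for i in range(len(els)):
        for j in range(i + 1, len(els)):
            p = _sorted_pair(els[i], els[j])
            if p not in bags:
                raise ValueError(f"element pair {p} not covered by bag_sizes")
            r = np.linalg.norm(coords[i] - coords[j]) * ANGSTROM_TO_BOHR
            bags[p].append(z[els[i]] * z[els[j]] / r)
    pieces = []
    schema_items = []
    for p in sorted(bag_sizes):
        vals = sorted(bags[p], reverse=True)
        size = bag_sizes[p]
        if len(vals) > size:
            raise ValueError(f"bag {p} overflow: {len(vals)} > {size}")
        pieces.append(np.pad(np.asarray(vals, dtype=float), (0, size - len(vals))))
        schema_items.append((p, size))
    schema = ("bag_of_bonds", tuple(schema_items))
    return GlobalRepresentation(vector=np.concatenate(pieces), feature_schema=schema)


@dataclass(frozen=True)
class ManyBodyParams:
    """Hyperparameters of the local 2-/3-body descriptor.

    cutoff : radial cutoff r_c in Angstrom.
    n_radial : radial bins per neighbour element.
    radial_width : Gaussian width of radial bins (default: bin spacing).
    n_angular : angular bins on [0, pi] per neighbour-element pair.
    element_set : elements defining the channel schema; build it from the
        union over the whole dataset so train and test vectors align.
    """

    cutoff: float = 8.0
    n_radial: int = 24
    radial_width: float | None = None
    n_angular: int = 12
    element_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.n_radial < 1 or self.n_angular < 1:
            raise ValueError("n_radial and n_angular must be >= 1")

    @property
    def radial_centers(self) -> np.ndarray:
        spacing = self.cutoff / self.n_radial
        return spacing * np.arange(1, self.n_radial + 1)

    @property
    def radial_sigma(self) -> float:
        return (
            self.radial_width
            if self.radial_width is not None
            else self.cutoff / self.n_radial
        )

    @property
    def angular_centers(self) -> np.ndarray:
        return np.linspace(0.0, np.pi, self.n_angular)

    @property
    def angular_sigma(self) -> float:
        return np.pi / (self.n_angular - 1) if self.n_angular > 1 else np.pi

    def schema(self) -> tuple:
        els = tuple(self.element_set)
        pairs = tuple(
            (els[i], els[j]) for i in range(len(els)) for j in range(i, len(els))
        )
        return ("local_manybody", els, pairs, self.cutoff, self.n_radial,
                self.radial_sigma, self.n_angular, self.angular_sigma)

    @property
    def dim(self) -> int:
        e = len(self.element_set)
        return e * self.n_radial + (e * (e + 1) // 2) * self.n_angular


def _cutoff_fn(r: np.ndarray, r_c: float) -> np.ndarray:
    return np.where(r < r_c, 0.5 * (1.0 + np.cos(np.pi * r / r_c)), 0.0)


def local_manybody(
    structure: MolecularStructure, params: ManyBodyParams
) -> LocalRepresentation:
    """Local 2-/3-body atomic environment vectors.

    Two-body channel (element e, bin m) of atom a:
    ``sum_{b != a, elem(b)=e} exp(-(r_ab - c_m)^2 / (2 w^2)) f_cut(r_ab)``.
    Three-body channel (pair ee', bin m): sum over unordered neighbour
    pairs (b, c) with elements {e, e'} of
    ``exp(-(theta_bac - phi_m)^2 / (2 w_theta^2)) f_cut(r_ab) f_cut(r_ac)``.
    Channels of absent elements stay zero so the schema is dataset-wide.
    """
    if not params.element_set:
        params = replace(
            params,
            element_set=tuple(
                sorted(set(structure.elements), key=lambda e: ATOMIC_NUMBERS[e])
            ),
        )
    coords = structure.coordinates
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinate")
    els = structure.elements
    for e in els:
        if e not in params.element_set:
            raise ValueError(f"element {e} absent from descriptor element_set")
    n = structure.n_atoms
    e_index = {e: i for i, e in enumerate(params.element_set)}
    n_el = len(params.element_set)
    pair_index = {}
    count = 0
    for i in range(n_el):
        for j in range(i, n_el):
            pair_index[(i, j)] = count
            count += 1
    n_rad, n_ang = params.n_radial, params.n_angular
    dim = n_el * n_rad + count * n_ang
    out = np.zeros((n, dim))

    if n > 1:
        dist = squareform(pdist(coords))
        fcut = _cutoff_fn(dist, params.cutoff)
        rc = params.radial_centers
        rw = params.radial_sigma
        aw = params.angular_sigma
        ac = params.angular_centers
        el_idx = np.array([e_index[e] for e in els])
        for a in range(n):
            neigh = np.where((dist[a] < params.cutoff) & (np.arange(n) != a))[0]
            if neigh.size == 0:
                continue
            r = dist[a, neigh]
            fc = fcut[a, neigh]
            # two-body: Gaussian-smeared radial histogram per element channel
            gauss = np.exp(-((r[:, None] - rc[None, :]) ** 2) / (2 * rw**2))
            contrib = gauss * fc[:, None]
            for b_pos, b in enumerate(neigh):
                ch = el_idx[b] * n_rad
                out[a, ch : ch + n_rad] += contrib[b_pos]
            # three-body: angular histogram per unordered element pair
            if neigh.size >= 2:
                vec = coords[neigh] - coords[a]
                unit = vec / r[:, None]
                cosang = np.clip(unit @ unit.T, -1.0, 1.0)
                theta = np.arccos(cosang)
                bb, cc = np.triu_indices(neigh.size, k=1)
                ag = np.exp(
                    -((theta[bb, cc][:, None] - ac[None, :]) ** 2) / (2 * aw**2)
                )
                weight = fc[bb] * fc[cc]
                ag = ag * weight[:, None]
                for p_pos in range(bb.size):
                    ei, ej = el_idx[neigh[bb[p_pos]]], el_idx[neigh[cc[p_pos]]]
                    key = (ei, ej) if ei <= ej else (ej, ei)
                    ch = n_el * n_rad + pair_index[key] * n_ang
                    out[a, ch : ch + n_ang] += ag[p_pos]

    # flush negligible Gaussian tails to exact zero: they carry no signal
    # but their subnormal magnitudes cripple downstream kernel algebra
    out[np.abs(out) < 1e-12] = 0.0
    return LocalRepresentation(
        per_atom=out, atom_elements=list(els), feature_schema=params.schema()
    )


def globalize(local: LocalRepresentation) -> GlobalRepresentation:
    """Sum the atomic environment rows into one global vector."""
    if local.n_atoms < 1:
        raise ValueError("empty local representation")
    return GlobalRepresentation(
        vector=local.per_atom.sum(axis=0), feature_schema=local.feature_schema
    )


def dataset_manybody_params(dataset: LabeledDataset, **kwargs) -> ManyBodyParams:
    """ManyBodyParams whose element schema covers the whole dataset."""
    return ManyBodyParams(element_set=tuple(dataset.element_set), **kwargs)


def local_representations(
    dataset: LabeledDataset, params: ManyBodyParams | None = None, **kwargs
) -> list[LocalRepresentation]:
    """Local many-body representations with one shared schema."""
    if params is None:
        params = dataset_manybody_params(dataset, **kwargs)
    elif not params.element_set:
        params = replace(params, element_set=tuple(dataset.element_set))
    return [local_manybody(s, params) for s in dataset.structures]


def global_matrix(
    dataset: LabeledDataset,
    params: ManyBodyParams | None = None,
    locals_: list[LocalRepresentation] | None = None,
    **kwargs,
) -> np.ndarray:
    """(n_structures, p) matrix of summed (global) many-body vectors."""
    if locals_ is None:
        locals_ = local_representations(dataset, params, **kwargs)
    return np.vstack([globalize(l).vector for l in locals_])


def export_representations(
    path, dataset: LabeledDataset, reps: list[LocalRepresentation]
) -> None:
    """Write per-atom representations as a delimited text table."""
    import pandas as pd

    rows = []
    for s, rep in zip(dataset.structures, reps):
        for a in range(rep.n_atoms):
            rows.append(
                {"structure_id": s.id, "atom_index": a, "element": rep.atom_elements[a]}
            )
    df = pd.DataFrame(rows)
    feat = np.vstack([rep.per_atom for rep in reps])
    feat_df = pd.DataFrame(
        feat, columns=[f"f{j:04d}" for j in range(feat.shape[1])], index=df.index
    )
    pd.concat([df, feat_df], axis=1).to_csv(path, index=False)


def import_representations(path, dataset: LabeledDataset) -> list[LocalRepresentation]:
    """Read externally computed per-atom representations for a dataset.

    The file must be a delimited table with columns ``structure_id``,
    ``atom_index``, ``element`` and feature columns.  Every dataset
    structure must appear; extra ids are ignored with a logged warning.
    """
    import pandas as pd

    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("f")]
    by_id = dict(tuple(df.groupby("structure_id", sort=False)))
    wanted = {s.id for s in dataset.structures}
    extra = set(by_id) - wanted
    if extra:
        logger.warning("ignoring %d unreferenced structure ids: %s",
                       len(extra), sorted(extra)[:5])
    reps = []
    for s in dataset.structures:
        if s.id not in by_id:
            raise KeyError(f"structure id {s.id!r} missing from {path}")
        g = by_id[s.id].sort_values("atom_index")
        if len(g) != s.n_atoms:
            raise ValueError(
                f"structure {s.id!r}: {len(g)} rows for {s.n_atoms} atoms"
            )
        reps.append(
            LocalRepresentation(
                per_atom=g[feat_cols].to_numpy(dtype=float),
                atom_elements=list(g["element"]),
                feature_schema=("imported", tuple(feat_cols)),
            )
        )
    return reps
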