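"""Synthetic molecular-cluster datasets with two correlated label levels.

Clusters are assembled from a small library of rigid, stylized molecular
units (an S-centred 5-atom "SA" unit, a 3-atom water-like "W" unit, a
4-atom ammonia-like "AM" unit — shapes are deliberately schematic, not
chemically accurate).  Whole units are placed at random positions and
orientations inside a box, subject to a minimum inter-unit atomic
distance, and finally jittered atom-wise.

Labels come from a smooth pairwise Morse potential plus per-element
atomic reference energies ("high level").  A second, "low level" label
re-evaluates the same functional with slightly perturbed Morse
parameters, adds a smooth per-composition offset and Gaussian noise —
so the residual (high - low) is a structured, learnable signal with
much smaller variance than the raw label, which is exactly the premise
of delta-learning between two levels of theory.  All energies are in
kcal/mol, distances in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from molknn._util import substream
from molknn.structures import LabeledDataset, MolecularStructure

__all__ = ["GeneratorConfig", "generate_clusters", "label_energies",
            "DEFAULT_UNIT_LIBRARY", "DEFAULT_MORSE_PARAMS"]

# Rigid local geometries (element, xyz in Angstrom), stylized.
_T = 1.45 / np.sqrt(3.0)
DEFAULT_UNIT_LIBRARY: dict[str, tuple[list[str], np.ndarray]] = {
    "SA": (
        ["S", "O", "O", "O", "O"],
        np.array(
            [
                [0.0, 0.0, 0.0],
                [_T, _T, _T],
                [_T, -_T, -_T],
                [-_T, _T, -_T],
                [-_T, -_T, _T],
            ]
        ),
    ),
    "W": (
        ["O", "H", "H"],
        np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]),
    ),
    "AM": (
        ["N", "H", "H", "H"],
        np.array(
            [
                [0.0, 0.0, 0.0],
                [0.94, 0.0, 0.38],
                [-0.47, 0.81, 0.38],
                [-0.47, -0.81, 0.38],
            ]
        ),
    ),
}

# Morse well parameters per unordered element pair:
# (D_e kcal/mol, alpha 1/Angstrom, r_e Angstrom).
DEFAULT_MORSE_PARAMS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("S", "S"): (2.5, 1.6, 3.0),
    ("O", "S"): (5.0, 1.8, 2.2),
    ("H", "S"): (3.0, 1.8, 2.4),
    ("O", "O"): (4.0, 1.7, 2.6),
    ("H", "O"): (6.0, 2.0, 1.8),
    ("H", "H"): (2.0, 1.5, 2.2),
    ("N", "O"): (4.5, 1.8, 2.4),
    ("H", "N"): (5.0, 2.0, 1.9),
    ("N", "S"): (3.5, 1.7, 2.8),
    ("N", "N"): (3.0, 1.6, 2.7),
}

_DEFAULT_COMPOSITIONS = {
    "(SA)1(W)1": 0.25,
    "(SA)1(W)2": 0.20,
    "(SA)2(W)1": 0.20,
    "(SA)2(W)2": 0.20,
    "(SA)3(W)3": 0.15,
}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cluster generator.

    Defaults: a box of 10 A, minimum inter-unit atomic distance 2.4 A,
    atomic jitter 0.05 A, a composition mix up to (SA)3(W)3, 5% relative
    low-level parameter perturbation and 0.1 kcal/mol low-level noise.
    """

    unit_library: dict = field(
        default_factory=lambda: dict(DEFAULT_UNIT_LIBRARY)
    )
    composition_distribution: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMPOSITIONS)
    )
    n_structures: int = 100
    placement_box: float = 10.0
    min_distance: float = 2.4
    jitter_sd: float = 0.05
    morse_params: dict = field(default_factory=lambda: dict(DEFAULT_MORSE_PARAMS))
    # epsilon(Z) = atomic_energy_per_z * Z (kcal/mol).  Chosen clearly below
    # the per-atom interaction scale so total energies are negative and
    # larger compositions have lower (more negative) mean energy, the way
    # electronic binding energies behave for growing clusters.
    atomic_energy_per_z: float = -25.0
    pair_cutoff: float = 12.0
    low_level_rel_shift: float = 0.05
    low_level_noise_sd: float = 0.1
    seed: int = 0
    max_placement_attempts: int = 1000

    def __post_init__(self) -> None:
        total = sum(self.composition_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"composition probabilities sum to {total}, not 1")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        for pair, (de, _, _) in self.morse_params.items():
            if de <= 0:
                raise ValueError(f"Morse D_e must be positive for pair {pair}")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def generate_clusters(config: GeneratorConfig) -> LabeledDataset:
    """Generate unlabeled clusters by rigid-unit rejection placement.

    Deterministic for a given config seed; regeneration is bitwise
    identical.  Raises if a unit cannot be placed within
    ``max_placement_attempts`` (the box is too small for the composition).
    """
    from molknn.structures import parse_composition

    rng = substream(config.seed, "generate-clusters")
    comp_names = sorted(config.composition_distribution)
    comp_probs = np.array([config.composition_distribution[c] for c in comp_names])
    comp_probs = comp_probs / comp_probs.sum()

    structures = []
    for i in range(config.n_structures):
        name = comp_names[rng.choice(len(comp_names), p=comp_probs)]
        comp = parse_composition(name)
        elements: list[str] = []
        placed: list[np.ndarray] = []
        for unit, count in sorted(comp.items()):
            unit_elements, unit_coords = config.unit_library[unit]
            for _ in range(count):
                for attempt in range(config.max_placement_attempts):
                    rot = Rotation.random(rng=rng).as_matrix()
                    center = rng.uniform(0.0, config.placement_box, size=3)
                    candidate = unit_coords @ rot.T + center
                    if not placed:
                        break
                    existing = np.vstack(placed)
                    if cdist(candidate, existing).min() >= config.min_distance:
                        break
                else:
                    raise RuntimeError(
                        f"could not place unit {unit} after "
                        f"{config.max_placement_attempts} attempts; "
                        "try a larger placement_box"
                    )
                placed.append(candidate)
                elements.extend(unit_elements)
        coords = np.vstack(placed)
        coords = coords + rng.normal(0.0, config.jitter_sd, size=coords.shape)
        structures.append(
            MolecularStructure(
                elements=elements,
                coordinates=coords,
                composition=comp,
                id=f"syn{i:05d}",
            )
        )
    return LabeledDataset(structures=structures)


def _param_tables(params):
    """Dense per-element-pair (D_e, alpha, r_e) lookup tables."""
    els = sorted({e for pair in params for e in pair})
    code = {e: i for i, e in enumerate(els)}
    m = len(els)
    de = np.zeros((m, m))
    al = np.zeros((m, m))
    re = np.zeros((m, m))
    for (a, b), (d, alpha, r0) in params.items():
        ia, ib = code[a], code[b]
        de[ia, ib] = de[ib, ia] = d
        al[ia, ib] = al[ib, ia] = alpha
        re[ia, ib] = re[ib, ia] = r0
    return code, de, al, re


def _morse_energy(structure: MolecularStructure, params, eps_per_z, cutoff) -> float:
    z = structure.atomic_numbers
    e = eps_per_z * float(z.sum())
    n = structure.n_atoms
    if n < 2:
        return e
    code, de_t, al_t, re_t = (
        params if isinstance(params, tuple) else _param_tables(params)
    )
    codes = np.array([code[el] for el in structure.elements])
    r = pdist(structure.coordinates)
    iu, ju = np.triu_indices(n, k=1)
    keep = r <= cutoff
    ci, cj = codes[iu[keep]], codes[ju[keep]]
    de = de_t[ci, cj]
    al = al_t[ci, cj]
    re = re_t[ci, cj]
    if np.any(de == 0):
        raise KeyError("missing Morse parameters for an element pair")
    e += float(np.sum(de * ((1.0 - np.exp(-al * (r[keep] - re))) ** 2 - 1.0)))
    return e


def _perturbed_params(config: GeneratorConfig) -> dict:
    """Low-level Morse parameters: fixed seeded relative shifts per pair."""
    rng = substream(config.seed, "low-level-params")
    out = {}
    for pair in sorted(config.morse_params):
        de, alpha, re = config.morse_params[pair]
        shifts = rng.uniform(-1.0, 1.0, size=3) * config.low_level_rel_shift
        out[pair] = (de * (1 + shifts[0]), alpha * (1 + shifts[1]),
                     re * (1 + shifts[2]))
    return out


def _composition_offset(structure: MolecularStructure) -> float:
    comp = structure.composition or {}
    n_sa = comp.get("SA", 0)
    n_w = comp.get("W", 0)
    n_am = comp.get("AM", 0)
    return 1.0 * n_sa + 0.6 * n_w + 0.8 * n_am + 0.15 * n_sa * n_w


def label_energies(
    dataset: LabeledDataset, config: GeneratorConfig
) -> LabeledDataset:
    """Attach high- and low-level energy labels to a cluster dataset.

    ``y_high`` is the Morse-plus-atomic-reference energy; ``y_low`` uses
    perturbed Morse parameters, a smooth per-composition offset and
    Gaussian noise.  The residual ``y_high - y_low`` is required to have
    smaller variance than ``y_high`` (the delta-learning premise); if a
    noise draw violates this the noise is redrawn with a fresh substream.
    """
    if not dataset.structures:
        raise ValueError("dataset has no structures")
    high_tables = _param_tables(config.morse_params)
    low_tables = _param_tables(_perturbed_params(config))
    y_high = np.array(
        [
            _morse_energy(s, high_tables, config.atomic_energy_per_z,
                          config.pair_cutoff)
            for s in dataset.structures
        ]
    )
    y_low_clean = np.array(
        [
            _morse_energy(s, low_tables, config.atomic_energy_per_z,
                          config.pair_cutoff)
            + _composition_offset(s)
            for s in dataset.structures
        ]
    )
    n = len(dataset)
    for redraw in range(10):
        rng = substream(config.seed, f"low-level-noise-{redraw}")
        y_low = y_low_clean + rng.normal(0.0, config.low_level_noise_sd, size=n)
        if n < 2 or np.var(y_high - y_low) < np.var(y_high):
            break
    else:
        raise RuntimeError(
            "residual variance never fell below label variance; the low "
            "level is not a usable delta-learning baseline for this config"
        )
    return LabeledDataset(structures=dataset.structures, y_high=y_high, y_low=y_low)
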