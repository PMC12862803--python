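import numpy as np
import pytest

from molknn.descriptors import (
    ANGSTROM_TO_BOHR,
    ManyBodyParams,
    bag_of_bonds,
    bob_bag_sizes,
    coulomb_matrix,
    export_representations,
    global_matrix,
    globalize,
    import_representations,
    local_manybody,
    local_representations,
)
from molknn.structures import LabeledDataset, MolecularStructure

H2_BOND = 0.74
H2_TERM = 1.0 / (H2_BOND * ANGSTROM_TO_BOHR)  # Z_i Z_j / r_ij, r in Bohr


def _h2():
    return MolecularStructure(["H", "H"], [[0, 0, 0], [0, 0, H2_BOND]])


def _random_structure(rng, n=6):
    els = rng.choice(["H", "O", "S"], size=n).tolist()
    return MolecularStructure(els, rng.normal(scale=2.0, size=(n, 3)))


def _random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


class TestCoulombMatrix:
    def test_single_hydrogen_diagonal(self):
        rep = coulomb_matrix(MolecularStructure(["H"], [[0, 0, 0]]), max_atoms=3)
        assert rep.vector[0] == pytest.approx(0.5)  # 0.5 * 1**2.4
        assert np.count_nonzero(rep.vector) == 1

    def test_h2_off_diagonal_value(self):
        rep = coulomb_matrix(_h2(), max_atoms=2)
        # entries: [M11, M12, M22] of the sorted matrix
        assert rep.vector[1] == pytest.approx(H2_TERM, rel=1e-10)
        assert rep.vector[1] == pytest.approx(0.71511, abs=1e-5)

    def test_atom_permutation_invariance(self, rng):
        s = _random_structure(rng)
        perm = rng.permutation(s.n_atoms)
        sp = MolecularStructure(
            [s.elements[i] for i in perm], s.coordinates[perm]
        )
        np.testing.assert_allclose(
            coulomb_matrix(s, 8).vector, coulomb_matrix(sp, 8).vector, atol=1e-10
        )

    def test_too_many_atoms_rejected(self):
        with pytest.raises(ValueError, match="max_atoms"):
            coulomb_matrix(_h2(), max_atoms=1)


class TestBagOfBonds:
    def test_h2_bag_value_and_padding(self):
        rep = bag_of_bonds(_h2(), {("H", "H"): 3})
        np.testing.assert_allclose(rep.vector, [H2_TERM, 0.0, 0.0], rtol=1e-10)

    def test_single_atom_all_zero(self):
        rep = bag_of_bonds(
            MolecularStructure(["O"], [[0, 0, 0]]), {("O", "O"): 2, ("H", "O"): 1}
        )
        assert np.all(rep.vector == 0)

    def test_permutation_invariance(self, rng):
        s = _random_structure(rng)
        sizes = bob_bag_sizes(LabeledDataset([s]))
        perm = rng.permutation(s.n_atoms)
        sp = MolecularStructure([s.elements[i] for i in perm], s.coordinates[perm])
        np.testing.assert_allclose(
            bag_of_bonds(s, sizes).vector, bag_of_bonds(sp, sizes).vector,
            atol=1e-10,
        )

    def test_uncovered_pair_and_overflow_rejected(self):
        with pytest.raises(ValueError, match="not covered"):
            bag_of_bonds(_h2(), {("O", "O"): 1})
        three_h = MolecularStructure(["H"] * 3, np.eye(3))
        with pytest.raises(ValueError, match="overflow"):
            bag_of_bonds(three_h, {("H", "H"): 2})


class TestLocalManyBody:
    def test_isolated_atom_zero_row(self):
        params = ManyBodyParams(element_set=("H", "O"))
        rep = local_manybody(MolecularStructure(["O"], [[0, 0, 0]]), params)
        assert rep.per_atom.shape == (1, params.dim)
        assert np.all(rep.per_atom == 0)

    def test_diatomic_at_bin_center_closed_form(self):
        params = ManyBodyParams(cutoff=6.0, n_radial=12, element_set=("H",))
        centers = params.radial_centers
        m = 5
        r = centers[m]
        s = MolecularStructure(["H", "H"], [[0, 0, 0], [r, 0, 0]])
        rep = local_manybody(s, params)
        f_cut = 0.5 * (1 + np.cos(np.pi * r / params.cutoff))
        assert rep.per_atom[0, m] == pytest.approx(f_cut, rel=1e-12)

    def test_rigid_motion_invariance(self, rng):
        params = ManyBodyParams(cutoff=6.0, n_radial=10, n_angular=6,
                                element_set=("H", "O", "S"))
        s = _random_structure(rng, n=8)
        R = _random_rotation(rng)
        t = rng.normal(scale=10.0, size=3)
        moved = MolecularStructure(s.elements, s.coordinates @ R.T + t)
        np.testing.assert_allclose(
            local_manybody(s, params).per_atom,
            local_manybody(moved, params).per_atom,
            atol=1e-10,
        )

    def test_entries_nonnegative_and_bounded_by_neighbor_count(self, rng):
        params = ManyBodyParams(cutoff=6.0, n_radial=8, n_angular=6,
                                element_set=("H", "O", "S"))
        s = _random_structure(rng, n=7)
        rep = local_manybody(s, params)
        assert np.all(rep.per_atom >= 0)
        # two-body channels: each neighbour contributes gauss*f_cut <= 1
        two_body = rep.per_atom[:, : 3 * params.n_radial]
        assert np.all(two_body <= s.n_atoms - 1 + 1e-12)

    def test_nan_coordinate_rejected(self):
        with pytest.raises(ValueError):
            local_manybody(
                MolecularStructure(["H", "H"], [[0, 0, 0], [np.nan, 0, 0]]),
                ManyBodyParams(element_set=("H",)),
            )


class TestGlobalize:
    def test_single_atom_equals_row(self):
        params = ManyBodyParams(element_set=("H", "O"))
        rep = local_manybody(
            MolecularStructure(["H", "H"], [[0, 0, 0], [1, 0, 0]]), params
        )
        np.testing.assert_array_equal(
            globalize(rep).vector, rep.per_atom.sum(axis=0)
        )

    def test_far_separated_copies_additive(self, rng):
        params = ManyBodyParams(cutoff=6.0, n_radial=8, n_angular=6,
                                element_set=("H", "O", "S"))
        s = _random_structure(rng, n=5)
        doubled = MolecularStructure(
            s.elements * 2,
            np.vstack([s.coordinates, s.coordinates + [100.0, 0, 0]]),
        )
        g1 = globalize(local_manybody(s, params)).vector
        g2 = globalize(local_manybody(doubled, params)).vector
        np.testing.assert_allclose(g2, 2 * g1, rtol=1e-8, atol=1e-10)

    def test_row_permutation_invariant(self, rng):
        params = ManyBodyParams(cutoff=6.0, n_radial=8, n_angular=6,
                                element_set=("H", "O", "S"))
        rep = local_manybody(_random_structure(rng), params)
        perm = rng.permutation(rep.n_atoms)
        from molknn.descriptors import LocalRepresentation

        shuffled = LocalRepresentation(
            rep.per_atom[perm],
            [rep.atom_elements[i] for i in perm],
            rep.feature_schema,
        )
        np.testing.assert_allclose(
            globalize(rep).vector, globalize(shuffled).vector, atol=1e-12
        )


def test_dataset_schema_fixed_across_structures(cluster_dataset, light_params):
    reps = local_representations(cluster_dataset, light_params)
    dims = {r.dim for r in reps}
    assert len(dims) == 1
    schemas = {r.feature_schema for r in reps}
    assert len(schemas) == 1
    G = global_matrix(cluster_dataset, locals_=reps)
    assert G.shape == (len(cluster_dataset), dims.pop())


class TestImportExport:
    def test_roundtrip_identity(self, tmp_path, cluster_dataset, light_params):
        ds = cluster_dataset.subset(range(5))
        reps = local_representations(ds, light_params)
        p = tmp_path / "reps.csv"
        export_representations(p, ds, reps)
        back = import_representations(p, ds)
        for a, b in zip(reps, back):
            np.testing.assert_allclose(a.per_atom, b.per_atom, rtol=1e-12)
            assert a.atom_elements == b.atom_elements

    def test_missing_id_raises(self, tmp_path, cluster_dataset, light_params):
        ds = cluster_dataset.subset(range(4))
        reps = local_representations(ds, light_params)
        p = tmp_path / "reps.csv"
        export_representations(p, ds.subset(range(3)), reps[:3])
        with pytest.raises(KeyError, match=ds.structures[3].id):
            import_representations(p, ds)

    def test_extra_ids_ignored_with_warning(
        self, tmp_path, cluster_dataset, light_params, caplog
    ):
        ds = cluster_dataset.subset(range(4))
        reps = local_representations(ds, light_params)
        p = tmp_path / "reps.csv"
        export_representations(p, ds, reps)
        import logging

        with caplog.at_level(logging.WARNING, logger="molknn.descriptors"):
            back = import_representations(p, ds.subset(range(2)))
        assert len(back) == 2
        assert any("unreferenced" in r.message for r in caplog.records)
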