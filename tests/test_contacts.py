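"""Structure parsing, interchain contact maps, pLDDT classification."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import brute_force_contact_map
from slimdock.contacts import (
    Atom,
    Chain,
    Residue,
    StructureModel,
    compare_maps,
    confidence_profile,
    interchain_contact_map,
    read_structure,
    write_mmcif,
    write_pdb,
)
from slimdock.errors import ConfigError, DataError
from slimdock.synth import InterfaceSpec, generate_interface_structure


def two_point_model(distance: float, element_b: str = "C") -> StructureModel:
    a = Chain("A", (Residue(1, "GLY", (Atom("CA", "C", (0.0, 0.0, 0.0)),)),))
    b = Chain(
        "B", (Residue(1, "GLY", (Atom("XB", element_b, (distance, 0.0, 0.0)),)),)
    )
    return StructureModel((a, b))


class TestContactRule:
    @pytest.mark.parametrize("distance, expected", [(3.9, 1.0), (4.0, 1.0), (4.1, 0.0)])
    def test_cutoff_inclusive_at_4(self, distance, expected):
        cmap = interchain_contact_map(two_point_model(distance), "A", "B")
        assert cmap.values[0, 0] == expected

    def test_hydrogen_pairs_do_not_count(self):
        # only sub-4 atom pair involves a hydrogen -> no contact
        a = Chain(
            "A",
            (Residue(1, "GLY", (Atom("CA", "C", (0, 0, 0)), Atom("HA", "H", (5.0, 0, 0)))),),
        )
        b = Chain("B", (Residue(1, "GLY", (Atom("CB", "C", (7.0, 0.0, 0.0)),)),))
        cmap = interchain_contact_map(StructureModel((a, b)), "A", "B")
        assert cmap.values[0, 0] == 0.0

    def test_empty_selection_is_error(self):
        with pytest.raises(ConfigError):
            interchain_contact_map(two_point_model(3.0), "A", "B", subset_a=(99,))

    def test_transpose_symmetry(self, structure_factory):
        model = structure_factory(np.random.default_rng(0))
        ab = interchain_contact_map(model, "A", "B")
        ba = interchain_contact_map(model, "B", "A")
        np.testing.assert_array_equal(ab.values, ba.values.T)

    def test_cutoff_monotonicity(self, structure_factory):
        model = structure_factory(np.random.default_rng(1))
        small = interchain_contact_map(model, "A", "B", cutoff=3.5)
        large = interchain_contact_map(model, "A", "B", cutoff=5.0)
        assert np.all(large.values >= small.values)

    def test_rigid_motion_invariance(self, structure_factory):
        model = structure_factory(np.random.default_rng(2))
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
        shift = np.array([10.0, -4.0, 2.5])

        def transform(m: StructureModel) -> StructureModel:
            chains = []
            for c in m.chains:
                residues = []
                for r in c.residues:
                    atoms = tuple(
                        Atom(a.name, a.element, tuple(rot.apply(a.xyz) + shift), a.bfactor)
                        for a in r.atoms
                    )
                    residues.append(Residue(r.number, r.name, atoms))
                chains.append(Chain(c.chain_id, tuple(residues)))
            return StructureModel(tuple(chains))

        before = interchain_contact_map(model, "A", "B")
        after = interchain_contact_map(transform(model), "A", "B")
        np.testing.assert_array_equal(before.values, after.values)

    def test_matches_brute_force_oracle(self, structure_factory):
        rng = np.random.default_rng(123)
        for _ in range(25):
            model = structure_factory(rng)
            cmap = interchain_contact_map(model, "A", "B", cutoff=4.0)
            oracle = np.array(brute_force_contact_map(model, "A", "B", 4.0), float)
            np.testing.assert_array_equal(cmap.values, oracle)

    def test_subset_order_preserved(self):
        iface = generate_interface_structure(InterfaceSpec(seed=5))
        cmap = interchain_contact_map(
            iface.model, "A", "B", subset_a=(16, 3), subset_b=(81, 114)
        )
        assert cmap.row_residues == (("A", 16), ("A", 3))
        assert cmap.col_residues == (("B", 81), ("B", 114))


class TestStructureIO:
    def test_pdb_roundtrip_preserves_geometry(self, tmp_path):
        iface = generate_interface_structure(InterfaceSpec(seed=11))
        p = tmp_path / "c.pdb"
        write_pdb(iface.model, p)
        model = read_structure(p)
        assert [c.chain_id for c in model.chains] == ["A", "B"]
        cmap = interchain_contact_map(
            model, "A", "B", subset_a=(3, 5, 9, 11, 16),
            subset_b=(15, 81, 114, 119, 159, 162, 318, 321),
        )
        np.testing.assert_array_equal(cmap.values, iface.planted_map.values)

    def test_mmcif_equivalent_to_pdb(self, tmp_path):
        iface = generate_interface_structure(InterfaceSpec(seed=12))
        pp, pc = tmp_path / "c.pdb", tmp_path / "c.cif"
        write_pdb(iface.model, pp)
        write_mmcif(iface.model, pc)
        from_pdb = read_structure(pp)
        from_cif = read_structure(pc)
        for ca, cb in zip(from_pdb.chains, from_cif.chains):
            assert ca.chain_id == cb.chain_id
            for ra, rb in zip(ca.residues, cb.residues):
                assert (ra.number, ra.name) == (rb.number, rb.name)
                np.testing.assert_allclose(
                    ra.heavy_coords(), rb.heavy_coords(), atol=1e-3
                )

    def test_water_only_file_is_error(self, tmp_path):
        p = tmp_path / "w.pdb"
        p.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00"
            "           O\nEND\n"
        )
        with pytest.raises(DataError, match="no polymer residues"):
            read_structure(p)

    def test_missing_file_is_error(self, tmp_path):
        with pytest.raises(DataError):
            read_structure(tmp_path / "absent.pdb")


class TestConfidence:
    @pytest.mark.parametrize(
        "plddt, expected",
        [(45.0, "disordered"), (75.0, "ordered"), (60.0, "intermediate"),
         (50.0, "intermediate"), (70.0, "intermediate")],
    )
    def test_threshold_bands(self, plddt, expected):
        model = StructureModel(
            (Chain("A", (Residue(1, "GLY", (Atom("CA", "C", (0, 0, 0), plddt),)),)),)
        )
        profile = confidence_profile(model, "A")
        assert profile.classes == (expected,)

    def test_ca_representative_with_mean_fallback(self):
        res_with_ca = Residue(
            1, "GLY", (Atom("CA", "C", (0, 0, 0), 80.0), Atom("CB", "C", (1, 0, 0), 20.0))
        )
        res_without = Residue(
            2, "GLY", (Atom("N", "N", (0, 0, 0), 40.0), Atom("C", "C", (1, 0, 0), 60.0))
        )
        model = StructureModel((Chain("A", (res_with_ca, res_without)),))
        profile = confidence_profile(model, "A")
        assert profile.plddt[0] == 80.0  # CA wins over other atoms
        assert profile.plddt[1] == 50.0  # mean fallback

    def test_out_of_range_bfactor_warns(self):
        model = StructureModel(
            (Chain("A", (Residue(1, "GLY", (Atom("CA", "C", (0, 0, 0), 150.0),)),)),)
        )
        with pytest.warns(UserWarning, match="AlphaFold"):
            confidence_profile(model, "A")

    def test_absent_chain_is_error(self):
        model = two_point_model(3.0)
        with pytest.raises(ConfigError):
            confidence_profile(model, "Z")


class TestCompareMaps:
    def _map(self, values, kind="binary"):
        from slimdock.contacts import ContactMap

        values = np.asarray(values, float)
        rows = tuple(("A", i + 1) for i in range(values.shape[0]))
        cols = tuple(("B", j + 1) for j in range(values.shape[1]))
        return ContactMap(rows, cols, values, cutoff=4.0, kind=kind)

    def test_identical_maps_jaccard_one(self):
        m = self._map([[1, 0], [0, 1]])
        occ = self._map([[1.0, 0.0], [0.0, 1.0]], kind="occupancy")
        assert compare_maps(m, occ).jaccard == 1.0

    def test_disjoint_supports_jaccard_zero(self):
        m = self._map([[1, 0], [0, 0]])
        occ = self._map([[0.0, 0.9], [0.0, 0.0]], kind="occupancy")
        comp = compare_maps(m, occ)
        assert comp.jaccard == 0.0
        assert len(comp.prediction_only) == 1
        assert len(comp.trajectory_only) == 1

    def test_occupancy_threshold_applied(self):
        m = self._map([[1]])
        occ = self._map([[0.4]], kind="occupancy")
        assert compare_maps(m, occ, occupancy_threshold=0.5).jaccard == 0.0
        assert compare_maps(m, occ, occupancy_threshold=0.3).jaccard == 1.0

    def test_mismatched_axes_error(self):
        with pytest.raises(DataError):
            compare_maps(self._map([[1]]), self._map([[1, 0]], kind="occupancy"))
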