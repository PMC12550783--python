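"""Trajectory statistics: COM distances, dissociation kinetics, occupancy, RMSD."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from slimdock.contacts import interchain_contact_map
from slimdock.errors import ConfigError, DataError, FormatError
from slimdock.kinetics import (
    ResidueSelection,
    TrajectoryBundle,
    analyze_dissociation,
    center_of_mass,
    com_distance_series,
    contact_occupancy,
    cumulative_fraction,
    dissociation_time,
    indicator,
    read_trajectory,
    subdomain_rmsd,
    write_frames_text,
)
from slimdock.synth import InterfaceSpec, TrajectorySpec, generate_interface_structure, generate_trajectory


def make_bundle(coords, chains, resnums, names=None, elements=None, masses=None, times=None):
    coords = np.asarray(coords, float)
    n = coords.shape[1]
    table = pd.DataFrame(
        {
            "chain": chains,
            "resnum": resnums,
            "name": names or ["CA"] * n,
            "element": elements or ["C"] * n,
            "mass": masses or [1.0] * n,
        }
    )
    times = np.arange(coords.shape[0], dtype=float) if times is None else np.asarray(times, float)
    return TrajectoryBundle(frames=coords, times=times, atom_table=table)


class TestCenterOfMass:
    def test_midpoint_of_unit_masses(self):
        b = make_bundle([[[0, 0, 0], [2, 0, 0]]], ["A", "A"], [1, 1])
        sel = ResidueSelection("A", (1,), "all")
        np.testing.assert_allclose(center_of_mass(b, sel, 0), [1, 0, 0])

    def test_mass_weighting(self):
        b = make_bundle([[[0, 0, 0], [4, 0, 0]]], ["A", "A"], [1, 1], masses=[1.0, 3.0])
        sel = ResidueSelection("A", (1,), "all")
        np.testing.assert_allclose(center_of_mass(b, sel, 0), [3, 0, 0])
        np.testing.assert_allclose(
            center_of_mass(b, sel, 0, weighting="geometric"), [2, 0, 0]
        )

    def test_single_atom_identity(self):
        b = make_bundle([[[1.5, -2.0, 3.0]]], ["A"], [7])
        sel = ResidueSelection("A", (7,), "all")
        np.testing.assert_allclose(center_of_mass(b, sel, 0), [1.5, -2.0, 3.0])

    def test_unresolvable_selection_error(self):
        b = make_bundle([[[0, 0, 0]]], ["A"], [1])
        with pytest.raises(ConfigError):
            ResidueSelection("B", (1,), "all").resolve(b)


class TestComDistance:
    def test_three_four_five(self):
        b = make_bundle([[[0, 0, 0], [3, 4, 0]]], ["A", "B"], [1, 1])
        d = com_distance_series(
            b, ResidueSelection("A", (1,), "all"), ResidueSelection("B", (1,), "all")
        )
        np.testing.assert_allclose(d, [5.0])

    def test_identical_selections_zero(self):
        b = make_bundle([[[1, 2, 3]], [[4, 5, 6]]], ["A"], [1])
        sel = ResidueSelection("A", (1,), "all")
        np.testing.assert_allclose(com_distance_series(b, sel, sel), [0.0, 0.0])

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 10, size=(1, 6, 3))
        shifted = base + np.array([7.0, -3.0, 1.0])
        frames = np.concatenate([base, shifted])
        b = make_bundle(frames, ["A"] * 3 + ["B"] * 3, [1, 1, 1, 2, 2, 2])
        d = com_distance_series(
            b, ResidueSelection("A", (1,), "all"), ResidueSelection("B", (2,), "all")
        )
        assert d[0] == pytest.approx(d[1])


class TestDissociationTime:
    def test_first_strict_crossing(self):
        t = dissociation_time(np.array([6, 9, 16, 12]), np.array([0, 100, 200, 300]))
        assert t == 200.0

    def test_never_exceeded_is_none(self):
        assert dissociation_time(np.array([6.0, 15.0]), np.array([0.0, 1.0])) is None

    def test_first_frame_crossing(self):
        assert dissociation_time(np.array([16.0, 6.0]), np.array([0.0, 1.0])) == 0.0

    def test_length_mismatch_error(self):
        with pytest.raises(DataError):
            dissociation_time(np.array([1.0]), np.array([0.0, 1.0]))


class TestCumulativeFraction:
    def test_direct_count(self):
        grid = np.array([15.0, 25.0])
        f = cumulative_fraction([10.0, 20.0, None], grid)
        np.testing.assert_allclose(f, [1 / 3, 2 / 3])

    def test_all_none_zero(self):
        np.testing.assert_allclose(cumulative_fraction([None, None], np.array([0.0, 5.0])), 0.0)

    def test_all_before_grid_one(self):
        np.testing.assert_allclose(cumulative_fraction([1.0, 2.0], np.array([5.0, 9.0])), 1.0)

    def test_empty_input_error(self):
        with pytest.raises(ConfigError):
            cumulative_fraction([], np.array([0.0]))

    def test_step_function_properties(self):
        """F is non-decreasing, right-continuous at each t_D, with values in
        {k/N}, and equals the scaled empirical CDF of finite t_Ds."""
        t_ds = [10.0, 10.0, 40.0, None, 75.0]
        grid = np.linspace(0, 100, 201)
        f = cumulative_fraction(t_ds, grid)
        assert np.all(np.diff(f) >= 0)
        n = len(t_ds)
        assert set(np.round(f * n).astype(int)) <= set(range(n + 1))
        np.testing.assert_allclose(f * n, np.round(f * n))
        for td in [10.0, 40.0, 75.0]:
            i = np.searchsorted(grid, td)
            assert f[i] == pytest.approx(np.mean([t is not None and t <= td for t in t_ds]))
        finite = sorted(t for t in t_ds if t is not None)
        assert f[-1] == pytest.approx(len(finite) / n)

    def test_indicator_reconstructs_t_d(self):
        grid = np.linspace(0, 100, 101)
        eta = indicator(37.0, grid)
        assert grid[np.argmax(eta)] == 37.0
        assert np.all(eta[grid < 37.0] == 0) and np.all(eta[grid >= 37.0] == 1)


class TestOccupancy:
    def test_fraction_of_frames(self):
        # contact (d=3) in 1 of 4 frames, else d=10
        frames = [[[0, 0, 0], [3, 0, 0]]] + [[[0, 0, 0], [10, 0, 0]]] * 3
        b = make_bundle(frames, ["A", "B"], [1, 1])
        occ = contact_occupancy(
            b, ResidueSelection("A", (1,), "heavy"), ResidueSelection("B", (1,), "heavy")
        )
        assert occ.values[0, 0] == 0.25

    def test_never_in_contact(self):
        b = make_bundle([[[0, 0, 0], [9, 0, 0]]] * 2, ["A", "B"], [1, 1])
        occ = contact_occupancy(
            b, ResidueSelection("A", (1,), "heavy"), ResidueSelection("B", (1,), "heavy")
        )
        assert occ.values[0, 0] == 0.0

    def test_single_frame_equals_binary_map(self):
        """Occupancy of a one-frame trajectory equals the static contact map of
        that frame's structure."""
        iface = generate_interface_structure(InterfaceSpec(seed=21))
        rows = []
        coords = []
        for chain in iface.model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    rows.append((chain.chain_id, res.number, atom.name, atom.element, 12.0))
                    coords.append(atom.xyz)
        table = pd.DataFrame(rows, columns=["chain", "resnum", "name", "element", "mass"])
        b = TrajectoryBundle(
            frames=np.array(coords)[None, :, :],
            times=np.array([0.0]),
            atom_table=table,
        )
        sel_a = ResidueSelection("A", (3, 5, 9, 11, 16), "heavy")
        sel_b = ResidueSelection("B", (15, 81, 114, 119, 159, 162, 318, 321), "heavy")
        occ = contact_occupancy(b, sel_a, sel_b)
        static = interchain_contact_map(
            iface.model, "A", "B", subset_a=sel_a.residues, subset_b=sel_b.residues
        )
        np.testing.assert_array_equal(occ.values, static.values)


class TestRmsd:
    def _translation_bundle(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 10, size=(8, 3))
        frames = np.stack([base, base + np.array([3.0, 4.0, 0.0])])
        return make_bundle(frames, ["A"] * 8, [1] * 8)

    def test_frame_zero_is_zero(self):
        b = self._translation_bundle()
        series = subdomain_rmsd(b, ResidueSelection("A", (1,), "all"))
        assert series.rmsd[0] == 0.0

    def test_pure_translation_no_fit_closed_form(self):
        b = self._translation_bundle()
        series = subdomain_rmsd(b, ResidueSelection("A", (1,), "all"))
        assert series.rmsd[1] == pytest.approx(5.0, abs=1e-12)
        assert series.superposition == "none"

    def test_translation_removed_by_superposition(self):
        b = self._translation_bundle()
        sel = ResidueSelection("A", (1,), "all")
        series = subdomain_rmsd(b, sel, superpose_on=sel)
        assert series.rmsd[1] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_invariance_with_fit(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0, 10, size=(10, 3))
        rot = Rotation.from_euler("zyx", [1.0, -0.4, 2.2])
        moved = rot.apply(base) + np.array([5.0, 5.0, -2.0])
        b = make_bundle(np.stack([base, moved]), ["A"] * 10, [1] * 10)
        sel = ResidueSelection("A", (1,), "all")
        series = subdomain_rmsd(b, sel, superpose_on=sel)
        assert series.rmsd[1] == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_anchor_rejected(self):
        coords = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0]]], float)  # collinear
        b = make_bundle(coords, ["A"] * 3, [1] * 3)
        sel = ResidueSelection("A", (1,), "all")
        with pytest.raises(DataError):
            subdomain_rmsd(b, sel, superpose_on=sel)

    def test_too_few_anchor_atoms_rejected(self):
        b = make_bundle([[[0, 0, 0], [1, 1, 1]]], ["A", "A"], [1, 1])
        sel = ResidueSelection("A", (1,), "all")
        with pytest.raises(ConfigError):
            subdomain_rmsd(b, sel, superpose_on=sel)


class TestTrajectoryIO:
    def _text(self, dt="1.0", frames=3):
        lines = [f"2 {frames} {dt}"]
        for t in range(frames):
            lines.append(f"A 1 CA C 12.0 {float(t)} 0.0 0.0")
            lines.append(f"B 1 CA C 12.0 5.0 0.0 0.0")
        return "\n".join(lines) + "\n"

    def test_three_frame_fixture(self, tmp_path):
        p = tmp_path / "t.xyzt"
        p.write_text(self._text())
        b = read_trajectory(p)
        assert b.n_frames == 3 and b.n_atoms == 2
        np.testing.assert_allclose(b.times, [0.0, 1.0, 2.0])

    def test_stride_metadata_converts(self, tmp_path):
        p = tmp_path / "t.xyzt"
        p.write_text(self._text(dt="0.01"))
        b = read_trajectory(p)
        np.testing.assert_allclose(b.times, [0.0, 0.01, 0.02])

    def test_nan_coordinate_error(self, tmp_path):
        p = tmp_path / "t.xyzt"
        p.write_text("1 1 1.0\nA 1 CA C 12.0 nan 0.0 0.0\n")
        with pytest.raises(DataError):
            read_trajectory(p)

    def test_atom_count_mismatch_error(self, tmp_path):
        p = tmp_path / "t.xyzt"
        p.write_text("2 2 1.0\nA 1 CA C 12.0 0 0 0\n")
        with pytest.raises(DataError):
            read_trajectory(p)

    def test_write_read_roundtrip(self, tmp_path):
        traj = generate_trajectory(TrajectorySpec(seed=3, n_frames=5))
        p = tmp_path / "rt.xyzt"
        write_frames_text(traj.bundle, p)
        b = read_trajectory(p)
        np.testing.assert_allclose(b.frames, traj.bundle.frames, atol=1e-5)
        np.testing.assert_allclose(b.times, traj.bundle.times)

    def test_mdtraj_container_roundtrip(self, tmp_path):
        import mdtraj as md

        traj = generate_trajectory(TrajectorySpec(seed=4, n_frames=4))
        bundle = traj.bundle
        top = md.Topology()
        chain_objs = {}
        residue_objs = {}
        for _, row in bundle.atom_table.iterrows():
            key = row["chain"]
            if key not in chain_objs:
                chain_objs[key] = top.add_chain()
            rkey = (row["chain"], row["resnum"])
            if rkey not in residue_objs:
                residue_objs[rkey] = top.add_residue("GLY", chain_objs[key], resSeq=row["resnum"])
            top.add_atom(row["name"], md.element.get_by_symbol(row["element"].capitalize()), residue_objs[rkey])
        t = md.Trajectory(xyz=bundle.frames / 10.0, topology=top, time=bundle.times * 1000.0)
        path = tmp_path / "t.h5"
        t.save_hdf5(str(path))
        b = read_trajectory(path, format="mdtraj")
        np.testing.assert_allclose(b.frames, bundle.frames, atol=1e-3)
        np.testing.assert_allclose(b.times, bundle.times, atol=1e-6)
        assert list(b.atom_table["resnum"]) == list(bundle.atom_table["resnum"])


class TestAnalyzeDissociation:
    def test_bound_and_escape_contrast(self):
        sel_a = ResidueSelection("MEK", (3, 5, 9, 11, 16))
        sel_b = ResidueSelection("ERK", (15, 81, 114, 119, 159, 162, 318, 321))
        bound = [generate_trajectory(TrajectorySpec(seed=s, mode="bound", n_frames=300)).bundle for s in (1, 2)]
        escape = [
            generate_trajectory(
                TrajectorySpec(seed=s, mode="escape", n_frames=300, escape_time_ns=100.0)
            ).bundle
            for s in (1, 2)
        ]
        rb = analyze_dissociation(bound, sel_a, sel_b)
        re_ = analyze_dissociation(escape, sel_a, sel_b)
        assert rb.fraction[-1] == 0.0
        assert re_.fraction[-1] == 1.0
        assert all(td is None for td in rb.t_ds)
        assert all(td is not None for td in re_.t_ds)
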