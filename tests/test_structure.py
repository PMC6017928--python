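"""SASA, buried interface and CPK volume against closed-form and library oracles."""

import math

import numpy as np
import pytest

from nitroredscope.structure import (
    AtomRecord,
    InterfaceReport,
    StructureModel,
    buried_interface,
    cpk_volume,
    read_structure,
    sasa,
    write_pdb,
)
from nitroredscope.synth_data import SimConfig, gen_toy_dimer

R_C = 1.7
PROBE = 1.4


def _atom(x=0.0, y=0.0, z=0.0, chain="A", element="C", radius=R_C, seq=1):
    return AtomRecord(element, chain, "UNK", seq, element, x, y, z, radius)


def _pair(d):
    return StructureModel([_atom(0.0), _atom(d, seq=2)])


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        _, total = sasa(StructureModel([_atom()]), probe=PROBE)
        assert total == pytest.approx(4 * math.pi * (R_C + PROBE) ** 2, rel=1e-12)

    def test_distant_pair_no_occlusion(self):
        R = R_C + PROBE
        _, total = sasa(_pair(2 * R + 0.5), probe=PROBE)
        assert total == pytest.approx(2 * 4 * math.pi * R * R, rel=1e-12)

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_overlapping_pair_matches_spherical_cap_formula(self, d):
        R = R_C + PROBE
        expected = 2 * (4 * math.pi * R * R - 2 * math.pi * R * (R - d / 2))
        _, total = sasa(_pair(d), probe=PROBE, n_points=3840)
        assert total == pytest.approx(expected, rel=0.01)

    def test_convergence_with_lattice_density(self):
        d = 3.0
        R = R_C + PROBE
        exact = 2 * (4 * math.pi * R * R - 2 * math.pi * R * (R - d / 2))
        errs = [abs(sasa(_pair(d), probe=PROBE, n_points=n)[1] - exact)
                for n in (60, 240, 960)]
        assert errs[2] < errs[0]

    def test_rigid_motion_invariance(self, toy_dimer):
        _, before = sasa(toy_dimer, n_points=240)
        moved = toy_dimer.translated((13.0, -7.0, 4.0))
        _, after = sasa(moved, n_points=240)
        assert after == pytest.approx(before, rel=1e-9)

    def test_agrees_with_biotite_shrake_rupley_within_2pct(self, toy_dimer):
        """Independent SASA oracle on the same radii and probe."""
        struc = pytest.importorskip("biotite.structure")
        coords = toy_dimer.coords()
        arr = struc.AtomArray(len(toy_dimer))
        arr.coord = coords.astype(np.float32)
        arr.chain_id = np.array([a.chain_id for a in toy_dimer.atoms])
        arr.res_id = np.array([a.res_seq for a in toy_dimer.atoms])
        arr.res_name = np.array(["UNK"] * len(toy_dimer))
        arr.atom_name = np.array(["C"] * len(toy_dimer))
        arr.element = np.array(["C"] * len(toy_dimer))
        oracle = float(np.sum(struc.sasa(
            arr, probe_radius=PROBE, point_number=1000,
            vdw_radii=np.full(len(toy_dimer), R_C),
        )))
        _, ours = sasa(toy_dimer, probe=PROBE, n_points=960)
        assert ours == pytest.approx(oracle, rel=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sasa(StructureModel([_atom()]), probe=0.0)
        with pytest.raises(ValueError):
            sasa(StructureModel([_atom()]), n_points=0)
        with pytest.raises(ValueError):
            sasa(StructureModel([]))


class TestBuriedInterface:
    def test_separated_chains_bury_nothing(self):
        model = gen_toy_dimer(SimConfig(seed=5), n_atoms_per_chain=15, separation=60.0)
        rep = buried_interface(model, "A", "B", n_points=240)
        assert rep.buried == pytest.approx(0.0, abs=1e-9)
        assert rep.buried_fraction_A == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_under_chain_swap(self, toy_dimer):
        r1 = buried_interface(toy_dimer, "A", "B", n_points=240)
        r2 = buried_interface(toy_dimer, "B", "A", n_points=240)
        assert r1.buried == pytest.approx(r2.buried, rel=1e-9)
        assert r1.asa_A == pytest.approx(r2.asa_B, rel=1e-9)

    def test_buried_area_decreases_with_separation(self):
        burieds = []
        for sep in (4.0, 8.0, 12.0, 40.0):
            model = gen_toy_dimer(SimConfig(seed=7), n_atoms_per_chain=20, separation=sep)
            burieds.append(buried_interface(model, "A", "B", n_points=240).buried)
        assert burieds == sorted(burieds, reverse=True)
        assert burieds[-1] == pytest.approx(0.0, abs=1e-9)

    def test_buried_nonnegative_and_formula_consistent(self, toy_dimer):
        rep = buried_interface(toy_dimer, "A", "B", n_points=240)
        assert rep.buried >= -1e-9
        assert rep.buried == pytest.approx((rep.asa_A + rep.asa_B - rep.asa_AB) / 2)
        assert rep.buried_fraction_A == pytest.approx(100 * rep.buried / rep.asa_A)

    def test_missing_chain_rejected(self, toy_dimer):
        with pytest.raises(ValueError):
            buried_interface(toy_dimer, "A", "Z")

    def test_from_areas_worked_arithmetic(self):
        rep = InterfaceReport.from_areas(13200.0, 13200.0, 17200.0)
        assert rep.buried == pytest.approx(4600.0)
        assert round(rep.buried_fraction_A) == 35


class TestCpkVolume:
    def test_single_sphere_within_1pct(self):
        v = cpk_volume(StructureModel([_atom()]), grid_spacing=0.15)
        assert v == pytest.approx(4 / 3 * math.pi * R_C**3, rel=0.01)

    def test_disjoint_spheres_add(self):
        v = cpk_volume(_pair(10.0), grid_spacing=0.15)
        assert v == pytest.approx(2 * 4 / 3 * math.pi * R_C**3, rel=0.01)

    def test_overlapping_spheres_match_lens_formula(self):
        d = 2.0
        v_single = 4 / 3 * math.pi * R_C**3
        v_lens = math.pi * (4 * R_C + d) * (2 * R_C - d) ** 2 / 12
        v = cpk_volume(_pair(d), grid_spacing=0.12)
        assert v == pytest.approx(2 * v_single - v_lens, rel=0.01)

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            cpk_volume(StructureModel([_atom()]), grid_spacing=0.0)


class TestReadWrite:
    def test_pdb_round_trip(self, toy_dimer, tmp_path):
        p = tmp_path / "dimer.pdb"
        write_pdb(toy_dimer, p)
        model = read_structure(p)
        assert len(model) == len(toy_dimer)
        assert model.chains == {"A", "B"}
        np.testing.assert_allclose(model.coords(), toy_dimer.coords(), atol=1e-3)

    def test_two_atom_toy_file(self, tmp_path):
        p = tmp_path / "two.pdb"
        write_pdb(StructureModel([_atom(), _atom(3.0, seq=2)]), p)
        model = read_structure(p)
        assert len(model) == 2
        assert model.chains == {"A"}

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError):
            read_structure(p)

    def test_waters_and_hydrogens_excluded(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
            "HETATM    3  O   HOH A   2       5.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        model = read_structure(p)
        assert len(model) == 1
        assert model.atoms[0].element == "C"

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        model = read_structure(p)
        assert len(model) == 1
        assert model.atoms[0].x == pytest.approx(2.0)

    def test_unknown_element_gets_fallback_radius_with_warning(self, tmp_path):
        p = tmp_path / "odd.pdb"
        p.write_text(
            "ATOM      1  U   UNK A   1       0.000   0.000   0.000  1.00  0.00           U\n"
            "END\n"
        )
        with pytest.warns(UserWarning, match="fallback"):
            model = read_structure(p)
        assert model.atoms[0].radius == pytest.approx(1.8)
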