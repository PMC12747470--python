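"""Unit cells, CIF round-trips, minimum-image geometry, bond perception."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mofscreen.elements import ElementError, covalent_radius
from mofscreen.structures import (
    AtomSite,
    CifFormatError,
    DisorderError,
    EmptyStructureError,
    PeriodicStructure,
    SmallMolecule,
    UnitCell,
    build_supercell,
    min_image_distance,
    parse_cif,
    perceive_bonds,
    write_cif,
)
from mofscreen.synth import make_cubic_framework

CIF_P1_TWO_SITES = """data_two
_cell_length_a 10.0
_cell_length_b 10.0
_cell_length_c 10.0
_cell_angle_alpha 90.0
_cell_angle_beta 90.0
_cell_angle_gamma 90.0
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.1 0.1 0.1
O1 O 0.5 0.5 0.5
"""

CIF_SYMMETRY = """data_sym
_cell_length_a 10.0
_cell_length_b 10.0
_cell_length_c 10.0
_cell_angle_alpha 90.0
_cell_angle_beta 90.0
_cell_angle_gamma 90.0
loop_
_symmetry_equiv_pos_as_xyz
'x,y,z'
'-x,-y,z'
'x+1/2,y+1/2,z'
'-x+1/2,-y+1/2,z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.1 0.2 0.0
"""


class TestUnitCell:
    def test_cubic_volume_exact(self):
        assert UnitCell(10, 10, 10).volume == pytest.approx(1000.0, abs=1e-12)

    @given(
        a=st.floats(2, 30), b=st.floats(2, 30), c=st.floats(2, 30),
        alpha=st.floats(50, 130), beta=st.floats(50, 130), gamma=st.floats(50, 130),
    )
    @settings(max_examples=60, deadline=None)
    def test_triclinic_volume_matches_lattice_determinant(self, a, b, c, alpha, beta, gamma):
        try:
            cell = UnitCell(a, b, c, alpha, beta, gamma)
        except ValueError:
            return  # geometrically impossible angle combination
        det = abs(np.linalg.det(cell.matrix))
        assert cell.volume == pytest.approx(det, rel=1e-9)

    @pytest.mark.parametrize("bad", [dict(a=-1), dict(alpha=0.0), dict(gamma=180.0)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(a=10, b=10, c=10)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            UnitCell(**kwargs)


class TestMinImage:
    def test_wraparound(self):
        cell = UnitCell(10, 10, 10)
        assert min_image_distance(cell, (0.1, 0, 0), (0.9, 0, 0)) == pytest.approx(2.0)

    def test_identity_is_zero(self):
        cell = UnitCell(10, 10, 10)
        assert min_image_distance(cell, (0.3, 0.4, 0.5), (0.3, 0.4, 0.5)) == 0.0

    @given(
        p=st.tuples(*[st.floats(0, 1, exclude_max=True)] * 3),
        q=st.tuples(*[st.floats(0, 1, exclude_max=True)] * 3),
    )
    @settings(max_examples=40, deadline=None)
    def test_triclinic_matches_brute_force_and_axioms(self, p, q):
        cell = UnitCell(8, 11, 9, 75, 85, 100)
        d = min_image_distance(cell, p, q)
        # brute force over 5x5x5 images
        shifts = np.array(
            [[i, j, k] for i in range(-2, 3) for j in range(-2, 3) for k in range(-2, 3)]
        )
        vecs = (np.asarray(q) - np.asarray(p) + shifts) @ cell.matrix
        brute = np.sqrt((vecs ** 2).sum(axis=1)).min()
        assert d == pytest.approx(brute, abs=1e-9)
        assert d == pytest.approx(min_image_distance(cell, q, p), abs=1e-12)
        raw = np.linalg.norm((np.asarray(q) - np.asarray(p)) @ cell.matrix)
        assert d <= raw + 1e-12


class TestSupercell:
    @pytest.mark.parametrize(
        "min_width,reps", [(24.0, 27), (20.0, 8), (10.0, 1), (5.0, 1)]
    )
    def test_replication_count(self, min_width, reps):
        s = make_cubic_framework(10.0, "C")
        sc = build_supercell(s, min_width)
        assert sc.n_sites == reps
        assert sc.mass_per_cell == pytest.approx(reps * s.mass_per_cell)

    def test_widths_respected(self):
        s = make_cubic_framework(10.0, "C")
        sc = build_supercell(s, 24.0)
        assert (sc.cell.perpendicular_widths >= 24.0 - 1e-9).all()


class TestCif:
    def test_p1_identity_expansion(self):
        s = parse_cif(CIF_P1_TWO_SITES)
        assert s.n_sites == 2
        assert s.elements == ["C", "O"]

    def test_symmetry_expansion_to_four_distinct_images(self):
        s = parse_cif(CIF_SYMMETRY)
        assert s.n_sites == 4
        # brute-force deduplication oracle: all pairwise distances > merge threshold
        for i in range(4):
            for j in range(i + 1, 4):
                d = min_image_distance(s.cell, s.sites[i].frac, s.sites[j].frac)
                assert d > 0.1

    def test_roundtrip_preserves_sites_and_coordinates(self):
        s = parse_cif(CIF_P1_TWO_SITES)
        s2 = parse_cif(write_cif(s))
        assert s2.n_sites == s.n_sites
        assert np.allclose(s2.frac_coords, s.frac_coords, atol=1e-6)
        assert s2.elements == s.elements

    def test_roundtrip_of_generated_framework(self):
        s = make_cubic_framework(12.5, "Zr")
        s2 = parse_cif(write_cif(s))
        assert s2.n_sites == 1
        assert s2.cell.a == pytest.approx(12.5, abs=1e-6)

    def test_coordinate_perturbation_changes_exactly_one_field(self):
        s = parse_cif(CIF_P1_TWO_SITES)
        sites = list(s.sites)
        f = np.array(sites[0].frac)
        f[0] += 1e-3
        sites[0] = AtomSite(sites[0].element, tuple(f), label=sites[0].label)
        s_mod = PeriodicStructure(s.cell, sites, name=s.name)
        diff = [
            (l1, l2)
            for l1, l2 in zip(write_cif(s).splitlines(), write_cif(s_mod).splitlines())
            if l1 != l2
        ]
        assert len(diff) == 1
        fields_differ = [
            a != b for a, b in zip(diff[0][0].split(), diff[0][1].split())
        ]
        assert sum(fields_differ) == 1

    def test_empty_name_gets_placeholder_block(self):
        s = make_cubic_framework(10.0, "C")
        s.name = ""
        assert write_cif(s).startswith("data_structure")

    def test_missing_cell_is_format_error(self):
        with pytest.raises(CifFormatError):
            parse_cif("data_x\nloop_\n_atom_site_label\nC1\n")

    def test_empty_site_loop_is_empty_structure_error(self):
        doc = CIF_P1_TWO_SITES.split("loop_")[0] + "loop_\n_atom_site_label\n_atom_site_type_symbol\n_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
        with pytest.raises((EmptyStructureError, CifFormatError)):
            parse_cif(doc)

    def test_unknown_element_rejected(self):
        with pytest.raises(ElementError):
            parse_cif(CIF_P1_TWO_SITES.replace("C1 C", "Xx1 Xx"))

    def test_partial_occupancy_rejected(self):
        doc = CIF_P1_TWO_SITES.replace(
            "_atom_site_fract_z", "_atom_site_fract_z\n_atom_site_occupancy"
        ).replace("0.1 0.1 0.1", "0.1 0.1 0.1 0.5").replace("0.5 0.5 0.5", "0.5 0.5 0.5 1.0")
        with pytest.raises(DisorderError):
            parse_cif(doc)

    def test_oxidation_state_suffix_stripped(self):
        s = parse_cif(CIF_P1_TWO_SITES.replace("C1 C", "Zr1 Zr4+"))
        assert s.elements[0] == "Zr"


class TestBondPerception:
    def test_two_carbons_at_bonding_distance(self):
        mol = SmallMolecule(atoms=[("C", (0, 0, 0), 0.0), ("C", (1.5, 0, 0), 0.0)])
        assert perceive_bonds(mol) == [(0, 1)]

    def test_two_distant_carbons_not_bonded(self):
        mol = SmallMolecule(atoms=[("C", (0, 0, 0), 0.0), ("C", (5.0, 0, 0), 0.0)])
        assert perceive_bonds(mol) == []

    def test_bond_across_periodic_boundary(self):
        s = PeriodicStructure(
            UnitCell(10, 10, 10),
            [AtomSite("C", (0.98, 0, 0)), AtomSite("C", (0.02, 0, 0))],
        )
        bonds = perceive_bonds(s)
        assert len(bonds) == 1
        i, j, shift = bonds[0]
        assert (i, j) == (0, 1)
        d = min_image_distance(s.cell, s.sites[0].frac, s.sites[1].frac)
        assert d == pytest.approx(0.4, abs=1e-9)

    def test_agrees_with_brute_force_all_pairs(self):
        rng = np.random.default_rng(5)
        cell = UnitCell(12, 12, 12)
        sites = [
            AtomSite("C", tuple(f)) for f in rng.random((20, 3))
        ]
        s = PeriodicStructure(cell, sites)
        bonds = {(i, j) for i, j, _ in perceive_bonds(s)}
        cut = 2 * covalent_radius("C") + 0.45
        brute = {
            (i, j)
            for i in range(20)
            for j in range(i + 1, 20)
            if min_image_distance(cell, sites[i].frac, sites[j].frac) <= cut
        }
        assert bonds == brute
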