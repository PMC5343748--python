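import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flexgen.constraints import (Constraint, ConstraintSet, InteractionType,
                                 TOLERANCES, build_constraint_set,
                                 build_topology, classify_pairs,
                                 combine_bounds, make_bounds,
                                 subsample_other_pairs)
from flexgen.fixtures import HingeSpec, make_hinge_pair
from flexgen.structure_io import Atom, Structure, assign_secondary_structure

TABLE_TOLERANCES = {1: 0.02, 2: 0.05, 3: 0.1, 4: 0.1, 5: 0.1, 6: 0.2,
                    7: 0.4, 8: 0.3, 9: 0.4, 10: 0.5, 11: 0.75, 12: 0.5,
                    13: 0.5, 14: 1.0, 15: 5.0}


def test_tolerance_table_exact():
    assert TOLERANCES == TABLE_TOLERANCES
    for code, tol in TABLE_TOLERANCES.items():
        assert InteractionType(code).tolerance == tol


@pytest.fixture(scope="module")
def classified(hinge_pair):
    a, _ = hinge_pair
    return a, classify_pairs(a)


class TestClassification:

    def test_backbone_n_ca_is_covalent(self, classified):
        a, pairs = classified
        i = a.atom_index("A", 2, "N")
        j = a.atom_index("A", 2, "CA")
        assert pairs[(min(i, j), max(i, j))].code == 1

    def test_n_c_same_residue_is_bond_angle(self, classified):
        a, pairs = classified
        i = a.atom_index("A", 2, "N")
        j = a.atom_index("A", 2, "C")
        assert pairs[(min(i, j), max(i, j))].code == 2

    def test_distant_pair_is_generic(self, classified):
        a, pairs = classified
        coords = a.coords
        ca = a.ca_indices()
        # find two Calphas > 15 Å apart
        found = None
        for x in range(len(ca)):
            for y in range(x + 1, len(ca)):
                if np.linalg.norm(coords[ca[x]] - coords[ca[y]]) > 15:
                    found = (ca[x], ca[y])
                    break
            if found:
                break
        assert found is not None
        assert pairs[found].code == 15

    def test_salt_bridge_lys_glu(self):
        # hand-built: Lys NZ 3.5 Å from Glu OE1
        def _atom(serial, name, element, res, ri, xyz, seq):
            return Atom(serial=serial, name=name, element=element,
                        residue_name=res, residue_index=ri, chain_id="A",
                        coords=np.array(xyz, float), res_seq=seq)
        atoms = [
            _atom(1, "N", "N", "LYS", 0, [0, 0, 0], 1),
            _atom(2, "CA", "C", "LYS", 0, [1.46, 0, 0], 1),
            _atom(3, "C", "C", "LYS", 0, [2.0, 1.4, 0], 1),
            _atom(4, "O", "O", "LYS", 0, [1.5, 2.5, 0], 1),
            _atom(5, "NZ", "N", "LYS", 0, [5.0, 0, 0], 1),
            _atom(6, "N", "N", "GLU", 1, [30, 0, 0], 2),
            _atom(7, "CA", "C", "GLU", 1, [31.46, 0, 0], 2),
            _atom(8, "C", "C", "GLU", 1, [32, 1.4, 0], 2),
            _atom(9, "O", "O", "GLU", 1, [31.5, 2.5, 0], 2),
            _atom(10, "OE1", "O", "GLU", 1, [8.5, 0, 0], 2),
        ]
        s = Structure(atoms, sec_struct=["C", "C"])
        pairs = classify_pairs(s)
        i, j = 4, 9  # NZ and OE1, 3.5 Å apart
        assert pairs[(i, j)].code == 11

    def test_omega_pair(self, classified):
        # CA(i)...CA(i+1) runs through the peptide bond C(i)-N(i+1)
        a, pairs = classified
        i = a.atom_index("A", 2, "CA")
        j = a.atom_index("A", 3, "CA")
        assert pairs[(min(i, j), max(i, j))].code == 5

    def test_helix_backbone_pair_secondary_structure(self, classified):
        # N(i) and N(i+4) inside one helix: no bonded path, same segment
        a, pairs = classified
        i = a.atom_index("A", 3, "N")
        j = a.atom_index("A", 7, "N")
        assert pairs[(min(i, j), max(i, j))].code == 10

    def test_every_pair_has_exactly_one_type(self, classified):
        a, pairs = classified
        n = len(a)
        assert len(pairs) == n * (n - 1) // 2

    def test_loop_phi_psi_pairs_are_loose(self, classified):
        a, pairs = classified
        # phi 1-4 pair within a loop residue: N(i)...O(i)? use N(loop+1)-C path
        # C(i-1)..C(i) through N(i)-CA(i) with both residues in the loop
        i = a.atom_index("A", 12, "C")
        j = a.atom_index("A", 13, "C")
        assert pairs[(min(i, j), max(i, j))].code in (6, 7)


def test_topology_counts(hinge_pair):
    a, _ = hinge_pair
    bonds = build_topology(a)
    # a linear peptide with no disulfides: atoms-1 intra bonds minimum
    assert len(bonds) >= len(a) - 1
    for i, j in bonds:
        d = np.linalg.norm(a.atoms[i].coords - a.atoms[j].coords)
        assert d < 2.6  # sanity: template bonds are short


class TestMakeBounds:
    def test_worked_covalent_example(self):
        lower, upper = make_bounds(1.54, InteractionType(1), 0.5)
        assert lower == pytest.approx(1.53, abs=1e-12)
        assert upper == pytest.approx(1.55, abs=1e-12)

    def test_zero_weight_collapses(self):
        for code in (1, 8, 15):
            assert make_bounds(3.7, InteractionType(code), 0.0) == (3.7, 3.7)

    def test_full_weight_type14(self):
        assert make_bounds(3.0, InteractionType(14), 1.0) == (2.0, 4.0)

    def test_lower_clamped_positive(self):
        lower, upper = make_bounds(1.0, InteractionType(15), 1.0)
        assert lower == pytest.approx(0.5)
        assert upper == pytest.approx(6.0)

    @given(d=st.floats(0.5, 50), code=st.integers(1, 15),
           wb=st.floats(0, 1))
    def test_bounds_bracket_distance(self, d, code, wb):
        lower, upper = make_bounds(d, InteractionType(code), wb)
        assert 0 < lower <= d <= upper


class TestCombineBounds:
    def test_worked_example(self):
        c1 = Constraint(0, 1, 6.0, 7.0, 15)
        c2 = Constraint(0, 1, 6.5, 7.5, 15)
        assert combine_bounds(c1, c2) == Constraint(0, 1, 6.0, 7.5, 15)

    def test_idempotent(self):
        c = Constraint(2, 5, 3.3, 4.4, 12)
        assert combine_bounds(c, c) == c

    def test_disjoint_intervals_union_hull(self):
        c1 = Constraint(0, 1, 2.0, 3.0, 15)
        c2 = Constraint(0, 1, 5.0, 6.0, 15)
        assert combine_bounds(c1, c2) == Constraint(0, 1, 2.0, 6.0, 15)

    def test_pair_mismatch_raises(self):
        with pytest.raises(ValueError):
            combine_bounds(Constraint(0, 1, 1, 2, 15),
                           Constraint(0, 2, 1, 2, 15))

    @given(lo1=st.floats(0.5, 9), w1=st.floats(0, 3),
           lo2=st.floats(0.5, 9), w2=st.floats(0, 3),
           t1=st.integers(1, 15), t2=st.integers(1, 15))
    def test_superset_property(self, lo1, w1, lo2, w2, t1, t2):
        c1 = Constraint(0, 1, lo1, lo1 + w1, t1)
        c2 = Constraint(0, 1, lo2, lo2 + w2, t2)
        c = combine_bounds(c1, c2)
        assert c.lower <= min(c1.lower, c2.lower)
        assert c.upper >= max(c1.upper, c2.upper)
        assert c.itype == min(t1, t2)


class TestSubsample:
    def test_all_retained_when_few(self):
        pairs = np.array([[0, 1], [0, 2], [1, 2]])
        out = subsample_other_pairs(pairs, n_atoms=10, seed=0)
        np.testing.assert_array_equal(out, pairs)

    def test_expected_count_binomial(self):
        n_atoms = 1000
        m = 200_000
        pairs = np.column_stack([np.arange(m), np.arange(m) + 1])
        out = subsample_other_pairs(pairs, n_atoms, seed=42)
        p = 20 * n_atoms / m  # 0.1
        sigma = np.sqrt(m * p * (1 - p))
        assert abs(len(out) - 20_000) < 4 * sigma

    def test_deterministic(self):
        pairs = np.column_stack([np.arange(5000), np.arange(5000) + 1])
        out1 = subsample_other_pairs(pairs, 100, seed=7)
        out2 = subsample_other_pairs(pairs, 100, seed=7)
        np.testing.assert_array_equal(out1, out2)
        out3 = subsample_other_pairs(pairs, 100, seed=8)
        assert len(out3) == 0 or not np.array_equal(out1[:len(out3)], out3)


class TestBuildConstraintSet:
    def test_wb_zero_bounds_are_min_max(self, hinge_pair):
        a, b = hinge_pair
        cs = build_constraint_set(a, b, 0.0, seed=0)
        xa, xb = a.coords, b.coords
        da = np.linalg.norm(xa[cs.i] - xa[cs.j], axis=1)
        db = np.linalg.norm(xb[cs.i] - xb[cs.j], axis=1)
        np.testing.assert_allclose(cs.lower, np.minimum(da, db), atol=1e-9)
        np.testing.assert_allclose(cs.upper, np.maximum(da, db), atol=1e-9)

    def test_identical_inputs_match_single_structure_bounds(self, hinge_pair):
        a, _ = hinge_pair
        cs = build_constraint_set(a, a, 0.5, seed=3)
        xa = a.coords
        da = np.linalg.norm(xa[cs.i] - xa[cs.j], axis=1)
        for k in range(len(cs)):
            lo, up = make_bounds(da[k], InteractionType(int(cs.itype[k])), 0.5)
            assert cs.lower[k] == pytest.approx(lo, abs=1e-9)
            assert cs.upper[k] == pytest.approx(up, abs=1e-9)

    def test_generic_count_near_20na(self):
        spec = HingeSpec(n_res_per_arm=16)
        a, b = make_hinge_pair(spec)
        a = assign_secondary_structure(a)
        b = assign_secondary_structure(b)
        cs = build_constraint_set(a, b, 0.5, seed=0)
        n = len(a)
        n_generic = int(np.sum(cs.itype == 15))
        total_generic = n * (n - 1) // 2 - int(np.sum(cs.itype != 15))
        p = min(1.0, 20 * n / total_generic)
        sigma = np.sqrt(total_generic * p * (1 - p))
        assert abs(n_generic - min(20 * n, total_generic)) < 4 * sigma + 1

    def test_both_inputs_satisfy_all_constraints(self, hinge_pair):
        a, b = hinge_pair
        for wb in (0.0, 0.5, 1.0):
            cs = build_constraint_set(a, b, wb, seed=1)
            for s in (a, b):
                x = s.coords
                d = np.linalg.norm(x[cs.i] - x[cs.j], axis=1)
                violations = np.sum((d < cs.lower - 1e-9)
                                    | (d > cs.upper + 1e-9))
                assert violations == 0

    def test_specific_counts_scale_linearly(self):
        counts = []
        sizes = []
        for n_arm in (6, 12, 24):
            spec = HingeSpec(n_res_per_arm=n_arm)
            a, b = make_hinge_pair(spec)
            a = assign_secondary_structure(a)
            b = assign_secondary_structure(b)
            cs = build_constraint_set(a, b, 0.5, seed=0)
            counts.append(int(np.sum(cs.itype != 15)))
            sizes.append(len(a))
        ratio1 = counts[1] / counts[0]
        ratio2 = counts[2] / counts[1]
        size1 = sizes[1] / sizes[0]
        size2 = sizes[2] / sizes[1]
        # specific interactions grow ~linearly with atom count
        assert ratio1 == pytest.approx(size1, rel=0.35)
        assert ratio2 == pytest.approx(size2, rel=0.35)

    def test_tsv_round_trip(self, tmp_path, hinge_pair):
        a, b = hinge_pair
        cs = build_constraint_set(a, b, 0.3, seed=9)
        path = tmp_path / "cs.tsv"
        cs.to_tsv(path)
        back = ConstraintSet.from_tsv(path)
        assert back.n_atoms == cs.n_atoms
        assert back.wb == cs.wb
        assert back.seed == cs.seed
        np.testing.assert_array_equal(back.i, cs.i)
        np.testing.assert_allclose(back.lower, cs.lower, atol=1e-6)
        np.testing.assert_array_equal(back.itype, cs.itype)
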