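"""Geometry measures, perception and Kabsch superposition.

The superposition r.m.s.d. is cross-checked against two independent oracles:
scipy's rotation alignment and a coarse Euler-grid brute force with local
polish, neither of which touches the Kabsch code path.
"""

import gemmi
import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ligrest.geometry import (
    DegenerateGeometryError,
    bond_angle,
    bond_length,
    dihedral,
    perceive_internal_coordinates,
    superpose_rmsd,
)

finite = st.floats(-10, 10, allow_nan=False)
vec = st.tuples(finite, finite, finite).map(np.array)


class TestMeasures:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((0, 0, 0), (0, 0, 1.52), 1.52), ((0, 0, 0), (0, 0, 0), 0.0),
         ((1, 1, 1), (2, 2, 2), np.sqrt(3))],
    )
    def test_bond_length(self, a, b, expected):
        assert bond_length(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a,b,c,expected",
        [((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
         ((1, 0, 0), (0, 0, 0), (-1, 0, 0), 180.0),
         ((1, 0, 0), (0, 0, 0), (1, 0, 0), 0.0)],
    )
    def test_bond_angle(self, a, b, c, expected):
        assert bond_angle(a, b, c) == pytest.approx(expected)

    def test_zero_arm_raises(self):
        with pytest.raises(DegenerateGeometryError):
            bond_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    @pytest.mark.parametrize(
        "d,expected",
        [((1, 0, 1), 0.0),  # cis: a and d on the same side of the b–c axis
         ((-1, 0, 1), 180.0)],  # trans
    )
    def test_dihedral_planar(self, d, expected):
        a, b, c = (1, 0, 0), (0, 0, 0), (0, 0, 1)
        assert dihedral(a, b, c, d) == pytest.approx(expected, abs=1e-9)

    def test_dihedral_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 0, 0), (0, 0, 1), (0, 0, 2), (1, 0, 3))

    def test_dihedral_matches_gemmi(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            try:
                mine = dihedral(*pts)
            except DegenerateGeometryError:
                continue
            ref = np.degrees(gemmi.calculate_dihedral(*(gemmi.Position(*p) for p in pts)))
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_dihedral_reversal_invariance(self):
        # the torsion viewed from either end of the central bond is the same
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.normal(size=(4, 3))
            assert dihedral(a, b, c, d) == pytest.approx(dihedral(d, c, b, a), abs=1e-9)

    def test_dihedral_mirror_negates(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(4, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        fwd = dihedral(*pts)
        assert dihedral(*mirrored) == pytest.approx(-fwd, abs=1e-9)


class TestPerception:
    def test_ethane_single_central_bond(self, ethane):
        ics = perceive_internal_coordinates(ethane)
        centrals = {tuple(sorted(q[1:3])) for q in ics.torsion_quads}
        assert centrals == {("C1", "C2")}

    def test_benzene_planar_group_of_twelve(self, benzene):
        ics = perceive_internal_coordinates(benzene)
        assert len(ics.planar_groups) == 1
        assert len(ics.planar_groups[0]) == 12

    def test_acetate_no_chiral_centres(self, acetate):
        assert perceive_internal_coordinates(acetate).chiral_centres == []

    def test_dipeptide_chiral_centre_at_ca(self, dipeptide_like):
        centres = perceive_internal_coordinates(dipeptide_like).chiral_centres
        assert [c.centre for c in centres] == ["CA"]
        assert centres[0].signed_volume != 0

    def test_angle_apex_bonded_to_flanks(self, any_component):
        bonded = {b.key for b in any_component.bonds}
        ics = perceive_internal_coordinates(any_component)
        for a1, apex, a3 in ics.angle_triples:
            assert frozenset((a1, apex)) in bonded
            assert frozenset((a3, apex)) in bonded
            assert a1 < a3

    def test_every_hydrogen_in_torsion_when_path_exists(self, any_component):
        ics = perceive_internal_coordinates(any_component)
        in_tor = {a for q in ics.torsion_quads for a in q}
        hydrogens = {a.name for a in any_component.atoms if a.is_hydrogen}
        # all fixtures have ≥4 atoms on every hydrogen's branch
        assert hydrogens <= in_tor


class TestSuperposition:
    def test_identical_sets_zero(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        assert superpose_rmsd(x, x)["rmsd"] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = x @ rot.T + np.array([1.0, -2.0, 3.0])
        out = superpose_rmsd(x, moved)
        assert out["rmsd"] == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(out["rotation"]) == pytest.approx(1.0)

    def test_symmetry_of_arguments(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(7, 3))
        y = x + rng.normal(scale=0.1, size=x.shape)
        assert superpose_rmsd(x, y)["rmsd"] == pytest.approx(
            superpose_rmsd(y, x)["rmsd"], abs=1e-9
        )

    def test_mismatched_counts_raise(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_against_scipy_alignment_oracle(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(4, 3))
        mov = ref + rng.normal(scale=0.2, size=ref.shape)
        mine = superpose_rmsd(ref, mov)["rmsd"]
        rot, rssd = Rotation.align_vectors(
            ref - ref.mean(0), mov - mov.mean(0)
        )
        oracle = rssd / np.sqrt(ref.shape[0])
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_against_rotation_grid_brute_force(self):
        """Brute-force search over Euler angles (coarse grid + local polish)
        must agree with the closed-form result to 1e-6."""
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(4, 3))
        mov = ref + rng.normal(scale=0.15, size=ref.shape)
        mine = superpose_rmsd(ref, mov)["rmsd"]

        p = ref - ref.mean(0)
        q = mov - mov.mean(0)

        def rmsd_for(angles):
            rot = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
            return np.sqrt(np.mean(np.sum((q @ rot.T - p) ** 2, axis=1)))

        grid = np.arange(-180.0, 180.0, 30.0)
        best, best_angles = np.inf, None
        for az in grid:
            for ay in grid:
                for ax in grid:
                    v = rmsd_for((az, ay, ax))
                    if v < best:
                        best, best_angles = v, (az, ay, ax)
        res = scipy.optimize.minimize(rmsd_for, best_angles, method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-14})
        assert mine == pytest.approx(res.fun, abs=1e-6)
        assert mine <= res.fun + 1e-9  # closed form is at least as good

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rigid_motion_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(5, 3))
        rot = Rotation.random(random_state=np.random.RandomState(seed % 2 ** 16)).as_matrix()
        t = rng.normal(size=3)
        assert superpose_rmsd(x, x @ rot.T + t)["rmsd"] < 1e-8
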