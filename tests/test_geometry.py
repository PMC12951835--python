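"""Unit tests for the attack-parameter definitions, against independent oracles."""

import math

import numpy as np
import pytest

from burgidunitz.errors import DegenerateGeometryError
from burgidunitz.geometry import (
    INDETERMINATE,
    Plane,
    bd_angle,
    chirality,
    compute_attack,
    dihedral_deg,
    fl_angle,
    lw_angle,
    phi_attack,
    project_onto_plane,
    pyramidalization,
    substituent_plane,
    tau_dihedral,
)
from burgidunitz.fixtures import (
    FixtureSpec,
    build_site,
    oracle_angle,
    oracle_dihedral,
    oracle_signed_volume,
)

from conftest import CANONICAL, make_nucleophile, make_site


class TestSubstituentPlane:
    def test_planar_substituents_give_z_normal(self, canonical_site):
        plane = substituent_plane(canonical_site)
        assert abs(abs(plane.normal[2]) - 1.0) < 1e-12
        assert abs(plane.signed_distance(CANONICAL["OD1"])) < 1e-12

    def test_plane_through_substituents_not_through_pyramidalized_center(self):
        site = make_site(c_el=[0.0, 0.0, 0.15])
        plane = substituent_plane(site)
        for name in ("OD1", "ND2", "CB"):
            assert abs(plane.signed_distance(CANONICAL[name])) < 1e-12
        assert abs(plane.signed_distance(site.c_el.position)) == pytest.approx(0.15)

    def test_matches_brute_force_cross_product(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            o, n, c = rng.normal(size=(3, 3))
            site = make_site(o_c=o, n_a=n, c_c=c)
            plane = substituent_plane(site)
            brute = np.cross(n - o, c - o)
            brute = brute / np.linalg.norm(brute)
            assert min(
                np.linalg.norm(plane.normal - brute),
                np.linalg.norm(plane.normal + brute),
            ) < 1e-12

    def test_collinear_substituents_raise(self):
        with pytest.raises(DegenerateGeometryError):
            substituent_plane(
                make_site(o_c=[1, 0, 0], n_a=[2, 0, 0], c_c=[3, 0, 0])
            )


class TestProjection:
    def test_point_in_plane_is_fixed(self):
        plane = Plane(anchor=np.zeros(3), normal=np.array([0.0, 0.0, 2.0]))
        p = np.array([1.3, -0.2, 0.0])
        np.testing.assert_allclose(project_onto_plane(p, plane), p, atol=1e-15)

    def test_foot_at_height_h(self):
        plane = Plane(anchor=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]))
        foot = project_onto_plane(np.array([2.0, 1.0, 3.7]), plane)
        np.testing.assert_allclose(foot, [2.0, 1.0, 0.0], atol=1e-15)

    def test_agrees_with_distance_minimization(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(11)
        anchor, raw_normal, point = rng.normal(size=(3, 3))
        plane = Plane(anchor=anchor, normal=raw_normal)
        # parametrize the plane by two in-plane axes and minimize the distance
        u = np.cross(plane.normal, [1.0, 0.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(plane.normal, u)

        def dist(ab):
            return np.linalg.norm(anchor + ab[0] * u + ab[1] * v - point)

        best = minimize(dist, x0=[0.0, 0.0], method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-14})
        brute_foot = anchor + best.x[0] * u + best.x[1] * v
        np.testing.assert_allclose(
            project_onto_plane(point, plane), brute_foot, atol=1e-6
        )


class TestPyramidalization:
    def test_planar_site_has_zero_delta(self, canonical_site):
        assert pyramidalization(canonical_site, [0, 0, 2.8]) == 0.0

    def test_displacement_toward_nucleophile_is_positive(self):
        site = make_site(c_el=[0.0, 0.0, 0.15])
        assert pyramidalization(site, [0, 0, 2.8]) == pytest.approx(0.15, abs=1e-12)

    def test_displacement_away_is_negative(self):
        site = make_site(c_el=[0.0, 0.0, -0.05])
        assert pyramidalization(site, [0, 0, 2.8]) == pytest.approx(-0.05, abs=1e-12)


class TestBdAngle:
    def test_perpendicular_approach_is_90(self):
        assert bd_angle([0, 0, 2.8], [0, 0, 0], [1.23, 0, 0]) == pytest.approx(90.0)

    def test_collinear_extension_is_180(self):
        assert bd_angle([-2.8, 0, 0], [0, 0, 0], [1.23, 0, 0]) == pytest.approx(180.0)

    def test_matches_oracle_on_random_triples(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 3))
            assert bd_angle(a, b, c) == pytest.approx(oracle_angle(a, b, c), abs=1e-9)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            bd_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])


class TestFlAngle:
    def test_nucleophile_beyond_carbonyl_extension_gives_zero(self, canonical_site):
        # P falls on the extension of the O=C' line beyond C'
        alpha, dp = fl_angle(canonical_site, [-3.0, 0.0, 1.0])
        assert alpha == pytest.approx(0.0, abs=1e-9)
        assert dp == pytest.approx(3.0)

    def test_perpendicular_attack_is_indeterminate(self, canonical_site):
        alpha, dp = fl_angle(canonical_site, [0.0, 0.0, 2.8])
        assert alpha is None
        assert dp < 1e-12

    def test_sign_positive_on_amide_side(self, canonical_site):
        plus, _ = fl_angle(canonical_site, [-0.5, 2.0, 1.0])   # P on the N (+y) side
        minus, _ = fl_angle(canonical_site, [-0.5, -2.0, 1.0])
        assert plus > 0 and minus < 0
        assert plus == pytest.approx(-minus, abs=1e-9)

    def test_degeneracy_tolerance_is_respected(self, canonical_site):
        # P sits 0.03 Å from C': indeterminate at tol 0.05, determinate at 0.01
        o_nuc = [0.03, 0.0, 2.8]
        assert fl_angle(canonical_site, o_nuc, degeneracy_tol=0.05)[0] is None
        assert fl_angle(canonical_site, o_nuc, degeneracy_tol=0.01)[0] is not None


class TestLwAngle:
    def test_in_omega_plane_gives_zero(self, canonical_site):
        # the Omega plane of the canonical frame is the xz plane
        assert lw_angle(canonical_site, [0.5, 0.0, 2.7]) == pytest.approx(0.0, abs=1e-9)

    def test_sign_positive_away_from_amide_nitrogen(self, canonical_site):
        # amide N sits at +y; the convention is positive on the opposite side
        assert lw_angle(canonical_site, [0.0, -1.0, 2.6]) > 0
        assert lw_angle(canonical_site, [0.0, 1.0, 2.6]) < 0

    def test_mirror_through_electrophile_plane_negates(self, canonical_site):
        o_nuc = np.array([0.3, -0.9, 2.5])
        up = lw_angle(canonical_site, o_nuc)
        down = lw_angle(canonical_site, o_nuc * [1, 1, -1])
        assert up == pytest.approx(down, abs=1e-9)  # reflection keeps the Omega side
        mirrored_y = lw_angle(canonical_site, o_nuc * [1, -1, 1])
        assert mirrored_y == pytest.approx(-up, abs=1e-9)


class TestPhiAttack:
    def test_positive_normal_approach_gives_plus_90(self, canonical_site):
        assert phi_attack(canonical_site, [0, 0, 2.8]) == pytest.approx(90.0, abs=1e-9)

    def test_mirror_negates_preserving_magnitude(self, canonical_site):
        o_nuc = np.array([0.4, 0.7, 2.4])
        phi = phi_attack(canonical_site, o_nuc)
        assert phi_attack(canonical_site, o_nuc * [1, 1, -1]) == pytest.approx(
            -phi, abs=1e-9
        )

    def test_matches_oracle_dihedral(self, canonical_site):
        rng = np.random.default_rng(5)
        c_prime = np.zeros(3)
        for _ in range(50):
            o_nuc = rng.normal(scale=2.0, size=3) + [0, 0, 3.0]
            expected = oracle_dihedral(
                o_nuc, CANONICAL["OD1"], c_prime, CANONICAL["CB"]
            )
            assert phi_attack(canonical_site, o_nuc) == pytest.approx(
                expected, abs=1e-9
            )

    def test_result_in_half_open_interval(self, canonical_site):
        # an anti-periplanar in-plane approach maps to +180, never -180
        phi = phi_attack(canonical_site, [-1.0, -2.254, 0.0])
        assert -180.0 < phi <= 180.0


class TestTau:
    def test_in_plane_nucleophile_gives_zero(self, canonical_site):
        assert tau_dihedral(canonical_site, [-1.0, 2.0, 0.0]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_in_omega_plane_gives_90(self, canonical_site):
        assert tau_dihedral(canonical_site, [0.4, 0.0, 2.8]) == pytest.approx(
            90.0, abs=1e-9
        )

    def test_collinear_with_co_raises(self, canonical_site):
        with pytest.raises(DegenerateGeometryError):
            tau_dihedral(canonical_site, [3.0, 0.0, 0.0])


class TestChirality:
    def test_plus_90_attack_is_S(self, canonical_site):
        letter, vol = chirality(canonical_site, [0, 0, 2.8])
        assert letter == "S" and vol > 0

    def test_mirrored_attack_is_R(self, canonical_site):
        letter, vol = chirality(canonical_site, [0, 0, -2.8])
        assert letter == "R" and vol < 0

    def test_volume_matches_oracle_determinant(self, canonical_site):
        rng = np.random.default_rng(13)
        for _ in range(30):
            o_nuc = rng.normal(scale=2.0, size=3)
            _, vol = chirality(canonical_site, o_nuc, volume_tol=0.0)
            expected = oracle_signed_volume(
                o_nuc, CANONICAL["OD1"], CANONICAL["ND2"], CANONICAL["CB"]
            )
            assert vol == pytest.approx(expected, abs=1e-9)

    def test_coplanar_nucleophile_is_indeterminate(self, canonical_site):
        letter, vol = chirality(canonical_site, [-1.0, 1.5, 0.0])
        assert letter == INDETERMINATE and abs(vol) < 0.01


class TestComputeAttack:
    def test_recovers_construction_parameters(self):
        site, nuc, _ = build_site(FixtureSpec(d=2.8, alpha_bd=100.0, phi_attack=85.0))
        g = compute_attack(site, nuc)
        assert g.d == pytest.approx(2.8, abs=1e-6)
        assert g.alpha_bd == pytest.approx(100.0, abs=1e-6)
        assert g.phi_attack == pytest.approx(85.0, abs=1e-6)
        assert g.delta == pytest.approx(0.0, abs=1e-9)
        assert g.chirality == "S"

    def test_perpendicular_attack_all_defined_except_fl(self):
        site, nuc, _ = build_site(FixtureSpec(d=2.8, alpha_bd=90.0, phi_attack=90.0))
        g = compute_attack(site, nuc)
        assert g.alpha_fl is None and g.dp < 1e-9
        for value in (g.d, g.alpha_bd, g.alpha_lw, g.phi_attack, g.tau, g.delta):
            assert math.isfinite(value)
        assert g.tau == pytest.approx(90.0, abs=1e-9)

    def test_coincident_nucleophile_raises(self, canonical_site):
        nuc = make_nucleophile([0.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            compute_attack(canonical_site, nuc)


def test_dihedral_convention_cis_zero_trans_180():
    cis = dihedral_deg([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
    trans = dihedral_deg([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])
    assert cis == pytest.approx(0.0, abs=1e-12)
    assert abs(trans) == pytest.approx(180.0, abs=1e-12)
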