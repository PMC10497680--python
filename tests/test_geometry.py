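"""Six-coordinate placement, vdW separation, and the translation solver."""

import math

import numpy as np
import pytest

from splinterkit import geometry as G
from splinterkit.geometry import (
    DimerConfiguration,
    GeometryError,
    InfeasibleSeparationError,
    InternalCoords,
    cartesian_from_internal,
    internal_from_cartesian,
    map_site_points,
    solve_translation,
    vdw_separation,
)

from .conftest import find_monomer, sites_of


def random_ic(rng):
    return InternalCoords(
        r_PL=float(rng.uniform(2.0, 9.0)),
        theta_P=float(rng.uniform(5.0, 175.0)),
        tau_P=float(rng.uniform(-179.0, 179.0)),
        theta_L=float(rng.uniform(5.0, 175.0)),
        tau_L=float(rng.uniform(-179.0, 179.0)),
        tau_PL=float(rng.uniform(-179.0, 179.0)),
    )


def angdiff(a, b):
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def ic_distance(a, b):
    return max(
        abs(a.r_PL - b.r_PL),
        abs(a.theta_P - b.theta_P),
        abs(a.theta_L - b.theta_L),
        angdiff(a.tau_P, b.tau_P),
        angdiff(a.tau_L, b.tau_L),
        angdiff(a.tau_PL, b.tau_PL),
    )


@pytest.fixture(scope="module")
def pair(fixture_set):
    mono_P = find_monomer(fixture_set, "pwater")
    mono_L = find_monomer(fixture_set, "lmethanol")
    site_P = sites_of(fixture_set, "pwater", "general")[0]
    site_L = sites_of(fixture_set, "lmethanol", "general")[0]
    return mono_P, mono_L, site_P, site_L


class TestRoundTrip:
    def test_round_trip_identity(self, pair, rng):
        mono_P, mono_L, site_P, site_L = pair
        worst = 0.0
        for _ in range(300):
            ic = random_ic(rng)
            config = cartesian_from_internal(mono_P, mono_L, site_P, site_L, ic)
            back = internal_from_cartesian(config, site_P, site_L)
            worst = max(worst, ic_distance(ic, back))
        assert worst < 1e-8

    def test_rigid_ligand_distances_preserved(self, pair, rng):
        mono_P, mono_L, site_P, site_L = pair
        ref = np.linalg.norm(
            mono_L.coords[:, None, :] - mono_L.coords[None, :, :], axis=-1
        )
        for _ in range(20):
            config = cartesian_from_internal(
                mono_P, mono_L, site_P, site_L, random_ic(rng)
            )
            new = np.linalg.norm(
                config.ligand_coords[:, None, :] - config.ligand_coords[None, :, :],
                axis=-1,
            )
            np.testing.assert_allclose(new, ref, atol=1e-10)

    def test_tau_pl_rotation_symmetry(self, pair):
        """tau_PL=0 vs 180 differ by a rotation about the A_P-A_L axis, so
        the ligand A point (on the axis construction origin side) stays put
        while B moves."""
        mono_P, mono_L, site_P, site_L = pair
        base = dict(r_PL=5.0, theta_P=90.0, tau_P=0.0, theta_L=90.0, tau_L=0.0)
        c0 = cartesian_from_internal(
            mono_P, mono_L, site_P, site_L, InternalCoords(tau_PL=0.0, **base)
        )
        c180 = cartesian_from_internal(
            mono_P, mono_L, site_P, site_L, InternalCoords(tau_PL=180.0, **base)
        )
        A0 = map_site_points(mono_L, site_L, c0.ligand_coords)[0]
        A180 = map_site_points(mono_L, site_L, c180.ligand_coords)[0]
        np.testing.assert_allclose(A0, A180, atol=1e-8)
        assert not np.allclose(c0.ligand_coords, c180.ligand_coords, atol=1e-3)

    def test_measurement_against_vector_algebra_oracle(self, pair, rng):
        """Internal coordinates agree with a direct cross/dot recomputation."""
        mono_P, mono_L, site_P, site_L = pair

        def oracle(ap, bp, cp, al, bl, cl):
            def ang(u, v):
                return math.degrees(
                    math.acos(
                        np.clip(
                            np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1
                        )
                    )
                )

            def dih(p0, p1, p2, p3):
                # praxeolitic formulation (IUPAC sign, matches RDKit)
                b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
                b1 = b1 / np.linalg.norm(b1)
                v = b0 - np.dot(b0, b1) * b1
                w = b2 - np.dot(b2, b1) * b1
                return math.degrees(
                    math.atan2(np.dot(np.cross(b1, v), w), np.dot(v, w))
                )

            return (
                np.linalg.norm(ap - al),
                ang(bp - ap, al - ap),
                dih(cp, bp, ap, al),
                ang(bl - al, ap - al),
                dih(cl, bl, al, ap),
                dih(bp, ap, al, bl),
            )

        for _ in range(100):
            ic = random_ic(rng)
            config = cartesian_from_internal(mono_P, mono_L, site_P, site_L, ic)
            got = internal_from_cartesian(config, site_P, site_L)
            al, bl, cl = map_site_points(mono_L, site_L, config.ligand_coords)
            r, tp, taup, tl, taul, taupl = oracle(
                site_P.point_A, site_P.point_B, site_P.point_C, al, bl, cl
            )
            assert got.r_PL == pytest.approx(r, abs=1e-9)
            assert got.theta_P == pytest.approx(tp, abs=1e-7)
            assert angdiff(got.tau_P, taup) < 1e-7
            assert got.theta_L == pytest.approx(tl, abs=1e-7)
            assert angdiff(got.tau_L, taul) < 1e-7
            assert angdiff(got.tau_PL, taupl) < 1e-7


class TestVdwSeparation:
    def test_single_pair_arithmetic(self, radii):
        # two Na (override radius 1.50 each) 4 Å apart -> separation 1.0
        sep = vdw_separation(["Na"], [[0, 0, 0]], ["Na"], [[4.0, 0, 0]], radii)
        assert sep == pytest.approx(1.0)

    def test_tangent_surfaces_zero(self, radii):
        sep = vdw_separation(["Na"], [[0, 0, 0]], ["Na"], [[3.0, 0, 0]], radii)
        assert sep == pytest.approx(0.0)

    def test_clash_is_negative(self, radii):
        assert vdw_separation(["C"], [[0, 0, 0]], ["C"], [[2.0, 0, 0]], radii) < 0

    def test_matches_exhaustive_pair_oracle(self, radii, rng):
        els_p, els_l = ["C", "N", "O", "H", "S"], ["C", "O", "Cl", "H"]
        for _ in range(50):
            cp = rng.uniform(-3, 3, size=(5, 3))
            cl = rng.uniform(4, 9, size=(4, 3))
            expected = min(
                np.linalg.norm(cp[i] - cl[j])
                - radii.radius(els_p[i])
                - radii.radius(els_l[j])
                for i in range(5)
                for j in range(4)
            )
            assert vdw_separation(els_p, cp, els_l, cl, radii) == pytest.approx(
                expected, abs=1e-12
            )

    def test_symmetric_and_rigid_motion_invariant(self, radii, rng):
        els_p, els_l = ["C", "O"], ["N", "H", "S"]
        cp = rng.uniform(-2, 2, size=(2, 3))
        cl = rng.uniform(3, 6, size=(3, 3))
        s1 = vdw_separation(els_p, cp, els_l, cl, radii)
        assert vdw_separation(els_l, cl, els_p, cp, radii) == pytest.approx(s1)
        # joint rigid motion
        theta = 0.77
        R = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        t = np.array([1.0, -2.0, 0.5])
        s2 = vdw_separation(els_p, cp @ R.T + t, els_l, cl @ R.T + t, radii)
        assert s2 == pytest.approx(s1, abs=1e-12)

    def test_missing_element_raises(self, radii):
        with pytest.raises(Exception, match="Zz"):
            vdw_separation(["Zz"], [[0, 0, 0]], ["C"], [[3, 0, 0]], radii)


ANGLES = dict(theta_P=90.0, tau_P=10.0, theta_L=90.0, tau_L=20.0, tau_PL=30.0)


class TestSolveTranslation:
    def test_single_atom_closed_form(self, fixture_set, radii):
        na = find_monomer(fixture_set, "psodium")
        s_na = sites_of(fixture_set, "psodium", "general")[0]
        l_na = find_monomer(fixture_set, "lsodium")
        s_lna = sites_of(fixture_set, "lsodium", "general")[0]
        # r_PL = target + r_vdW(Na) + r_vdW(Na) = target + 3.0
        assert solve_translation(
            na, l_na, s_na, s_lna, ANGLES, 1.0, radii
        ) == pytest.approx(4.0, abs=1e-6)
        assert solve_translation(
            na, l_na, s_na, s_lna, ANGLES, 0.0, radii
        ) == pytest.approx(3.0, abs=1e-6)

    def test_achieved_separation_matches_target(self, fixture_set, radii, rng):
        mono_P = find_monomer(fixture_set, "pwater")
        mono_L = find_monomer(fixture_set, "lformaldehyde")
        site_P = sites_of(fixture_set, "pwater", "general")[0]
        site_L = sites_of(fixture_set, "lformaldehyde", "general")[0]
        for _ in range(20):
            target = float(rng.uniform(-0.5, 3.0))
            angles = dict(
                theta_P=float(rng.uniform(20, 160)),
                tau_P=float(rng.uniform(-170, 170)),
                theta_L=float(rng.uniform(20, 160)),
                tau_L=float(rng.uniform(-170, 170)),
                tau_PL=float(rng.uniform(-170, 170)),
            )
            r_pl = solve_translation(mono_P, mono_L, site_P, site_L, angles, target, radii)
            config = cartesian_from_internal(
                mono_P, mono_L, site_P, site_L, InternalCoords(r_PL=r_pl, **angles)
            )
            achieved = vdw_separation(
                mono_P.elements,
                config.protein_coords,
                mono_L.elements,
                config.ligand_coords,
                radii,
            )
            assert achieved == pytest.approx(target, abs=1e-6)

    def test_matches_grid_scan_oracle(self, fixture_set, radii, rng):
        """Brute-force 0.001 Å scan of the translation, interpolated."""
        mono_P = find_monomer(fixture_set, "pwater")
        mono_L = find_monomer(fixture_set, "lmethanol")
        site_P = sites_of(fixture_set, "pwater", "general")[0]
        site_L = sites_of(fixture_set, "lmethanol", "general")[0]
        for _ in range(10):
            target = float(rng.uniform(-0.5, 2.0))
            angles = dict(
                theta_P=float(rng.uniform(30, 150)),
                tau_P=float(rng.uniform(-170, 170)),
                theta_L=float(rng.uniform(30, 150)),
                tau_L=float(rng.uniform(-170, 170)),
                tau_PL=float(rng.uniform(-170, 170)),
            )
            got = solve_translation(mono_P, mono_L, site_P, site_L, angles, target, radii)

            def sep_at(r_pl):
                c = cartesian_from_internal(
                    mono_P, mono_L, site_P, site_L, InternalCoords(r_PL=r_pl, **angles)
                )
                return vdw_separation(
                    mono_P.elements,
                    c.protein_coords,
                    mono_L.elements,
                    c.ligand_coords,
                    radii,
                )

            grid = np.arange(12.0, 0.5, -0.001)
            vals = None
            oracle = None
            prev_r, prev_s = grid[0], sep_at(grid[0])
            for r_pl in grid[1:]:
                s = sep_at(r_pl)
                if (prev_s - target) * (s - target) <= 0:
                    frac = (prev_s - target) / (prev_s - s)
                    oracle = prev_r + frac * (r_pl - prev_r)
                    break
                prev_r, prev_s = r_pl, s
            assert oracle is not None
            assert got == pytest.approx(oracle, abs=2e-3)

    def test_monotone_in_target(self, fixture_set, radii):
        mono_P = find_monomer(fixture_set, "pwater")
        mono_L = find_monomer(fixture_set, "lmethanol")
        site_P = sites_of(fixture_set, "pwater", "general")[0]
        site_L = sites_of(fixture_set, "lmethanol", "general")[0]
        targets = [-0.8, -0.3, 0.0, 0.5, 1.5, 3.0]
        roots = [
            solve_translation(mono_P, mono_L, site_P, site_L, ANGLES, t, radii)
            for t in targets
        ]
        assert all(a < b for a, b in zip(roots, roots[1:]))

    def test_infeasible_separation_raises(self, fixture_set, radii):
        na = find_monomer(fixture_set, "psodium")
        s_na = sites_of(fixture_set, "psodium", "general")[0]
        l_na = find_monomer(fixture_set, "lsodium")
        s_lna = sites_of(fixture_set, "lsodium", "general")[0]
        with pytest.raises(InfeasibleSeparationError):
            solve_translation(na, l_na, s_na, s_lna, ANGLES, -3.5, radii)


class TestMapSitePoints:
    def test_identity(self, fixture_set):
        m = find_monomer(fixture_set, "lmethanol")
        s = sites_of(fixture_set, "lmethanol", "general")[0]
        np.testing.assert_allclose(
            map_site_points(m, s, m.coords), s.points, atol=1e-9
        )

    def test_equivariance_under_known_rigid_motion(self, fixture_set):
        m = find_monomer(fixture_set, "lmethanol")
        s = sites_of(fixture_set, "lmethanol", "general")[0]
        theta = 1.1
        R = np.array(
            [
                [1, 0, 0],
                [0, math.cos(theta), -math.sin(theta)],
                [0, math.sin(theta), math.cos(theta)],
            ]
        )
        t = np.array([0.3, -1.2, 2.0])
        moved = map_site_points(m, s, m.coords @ R.T + t)
        np.testing.assert_allclose(moved, s.points @ R.T + t, atol=1e-8)

    def test_perturbation_tracking_bound(self, fixture_set, rng):
        m = find_monomer(fixture_set, "lmethanol")
        s = sites_of(fixture_set, "lmethanol", "general")[0]
        for _ in range(20):
            disp = rng.normal(size=m.coords.shape)
            disp *= 0.1 / np.maximum(np.linalg.norm(disp, axis=1, keepdims=True), 1e-12)
            fitted = map_site_points(m, s, m.coords + disp)
            assert np.linalg.norm(fitted - s.points, axis=1).max() < 0.2

    def test_atom_count_mismatch(self, fixture_set):
        m = find_monomer(fixture_set, "lmethanol")
        s = sites_of(fixture_set, "lmethanol", "general")[0]
        with pytest.raises(GeometryError):
            map_site_points(m, s, np.zeros((2, 3)))


class TestValidation:
    def test_nonpositive_r_pl_rejected(self):
        with pytest.raises(GeometryError):
            InternalCoords(
                r_PL=0.0, theta_P=90, tau_P=0, theta_L=90, tau_L=0, tau_PL=0
            )

    def test_tau_normalized_to_principal_branch(self):
        ic = InternalCoords(
            r_PL=3.0, theta_P=90, tau_P=270.0, theta_L=90, tau_L=-200.0, tau_PL=540.0
        )
        assert ic.tau_P == pytest.approx(-90.0)
        assert ic.tau_L == pytest.approx(160.0)
        assert ic.tau_PL == pytest.approx(180.0)

    def test_config_atom_count_checked(self, fixture_set):
        m = find_monomer(fixture_set, "pwater")
        l = find_monomer(fixture_set, "lmethane")
        with pytest.raises(GeometryError):
            DimerConfiguration(
                protein=m,
                ligand=l,
                protein_coords=np.zeros((2, 3)),
                ligand_coords=l.coords,
            )
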