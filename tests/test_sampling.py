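"""Radial/angular sampling, perturbation, and the rejection-retry loop."""

import numpy as np
import pytest
from scipy import stats

from splinterkit.energy import ConstantBackend, RejectionPolicy, ScriptedBackend
from splinterkit.geometry import internal_from_cartesian
from splinterkit.sampling import (
    RadialSpec,
    SamplingError,
    generate_batch,
    perturb_coordinates,
    radial_pdf,
    radial_spec_for,
    rng_for_site_dimer,
    sample_angles,
    sample_r,
)

from .conftest import sites_of

NEUTRAL_GENERAL = RadialSpec(-1.0, 1.0, 3.0)


class TestRadialSpec:
    def test_ordering_enforced(self):
        with pytest.raises(SamplingError):
            RadialSpec(1.0, 0.5, 3.0)

    def test_table_lookup_by_charge_and_class(self, site_dimers):
        for sd in site_dimers:
            spec = radial_spec_for(sd)
            if sd.charge_class == "like-charged":
                assert spec == RadialSpec(0.0, 2.5, 5.0)
            elif sd.charge_class == "opposite-charged":
                assert spec == RadialSpec(-1.8, 1.5, 5.0)
            elif sd.charge_class == "neutral/neutral":
                expected = (
                    RadialSpec(-1.0, 1.0, 3.0)
                    if sd.pair_class == "general/general"
                    else RadialSpec(-1.3, 1.0, 3.0)
                )
                assert spec == expected
            else:
                expected = (
                    RadialSpec(-1.0, 1.5, 5.0)
                    if sd.pair_class == "general/general"
                    else RadialSpec(-1.6, 1.5, 5.0)
                )
                assert spec == expected


class TestSampleR:
    def test_support(self, rng):
        draws = np.array([sample_r(NEUTRAL_GENERAL, rng) for _ in range(5000)])
        assert draws.min() >= NEUTRAL_GENERAL.r_min
        assert draws.max() <= NEUTRAL_GENERAL.r_max

    def test_flat_region_mass_two_thirds(self, rng):
        """P(r <= r_switch) = w1 / (w1 + w2/2) = 2/3 for (-1, 1, 3)."""
        n = 100_000
        draws = np.array([sample_r(NEUTRAL_GENERAL, rng) for _ in range(n)])
        frac = float(np.mean(draws <= NEUTRAL_GENERAL.r_switch))
        p = 2.0 / 3.0
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * sigma

    def test_uniform_when_switch_equals_max(self, rng):
        spec = RadialSpec(-1.0, 3.0, 3.0)
        draws = np.array([sample_r(spec, rng) for _ in range(100_000)])
        ref = rng.uniform(-1.0, 3.0, size=100_000)
        assert stats.ks_2samp(draws, ref).pvalue > 0.01

    def test_piecewise_density_chi2(self, rng):
        n = 100_000
        draws = np.array([sample_r(NEUTRAL_GENERAL, rng) for _ in range(n)])
        edges = np.linspace(-1.0, 3.0, 41)
        observed, _ = np.histogram(draws, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        probs = radial_pdf(NEUTRAL_GENERAL, centers)
        probs = probs / probs.sum()
        res = stats.chisquare(observed, f_exp=probs * n)
        assert res.pvalue > 0.01

    def test_truncation_below_switch_is_uniform(self, rng):
        draws = np.array(
            [sample_r(NEUTRAL_GENERAL, rng, upper_override=0.5) for _ in range(20_000)]
        )
        assert draws.max() <= 0.5
        ref = rng.uniform(-1.0, 0.5, size=20_000)
        assert stats.ks_2samp(draws, ref).pvalue > 0.01

    def test_degenerate_spec_returns_rmin(self, rng):
        spec = RadialSpec(1.0, 1.0, 1.0)
        assert sample_r(spec, rng) == 1.0

    def test_override_outside_bounds_rejected(self, rng):
        with pytest.raises(SamplingError):
            sample_r(NEUTRAL_GENERAL, rng, upper_override=4.0)


class TestSampleAngles:
    def test_hbd_theta_within_90_180(self, fixture_set, rng):
        hbd = sites_of(fixture_set, "pwater", "hbd")[0]
        general = sites_of(fixture_set, "lmethane", "general")[0]
        for _ in range(2000):
            a = sample_angles(hbd, general, rng)
            assert 90.0 <= a["theta_P"] <= 180.0

    def test_split_tau_union_equal_halves(self, fixture_set, rng):
        lb = sites_of(fixture_set, "lformaldehyde", "lb")[0]
        general = sites_of(fixture_set, "pwater", "general")[0]
        n = 100_000
        taus = np.array([sample_angles(general, lb, rng)["tau_L"] for _ in range(n)])
        in_planeA = np.mean((taus >= -45) & (taus <= 45))
        p = 0.5
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(in_planeA - p) < 3 * sigma
        assert all(lb.tau_range.contains(t) for t in taus[:1000])

    def test_tau_pl_uniform_on_circle(self, fixture_set, rng):
        gp = sites_of(fixture_set, "pwater", "general")[0]
        gl = sites_of(fixture_set, "lmethane", "general")[0]
        n = 100_000
        taus = np.array([sample_angles(gp, gl, rng)["tau_PL"] for _ in range(n)])
        observed, _ = np.histogram(taus, bins=np.linspace(-180, 180, 37))
        res = stats.chisquare(observed)
        assert res.pvalue > 0.01


class TestPerturbation:
    def _config(self, fixture_set, site_dimers):
        from splinterkit.geometry import InternalCoords, cartesian_from_internal

        sd = site_dimers[0]
        ic = InternalCoords(
            r_PL=6.0, theta_P=90, tau_P=0, theta_L=90, tau_L=0, tau_PL=0
        )
        return cartesian_from_internal(
            sd.protein, sd.ligand, sd.protein_site, sd.ligand_site, ic
        )

    def test_zero_budget_is_identity(self, fixture_set, site_dimers, rng):
        c = self._config(fixture_set, site_dimers)
        before = c.all_coords.copy()
        perturb_coordinates(c, rng, max_disp=0.0)
        np.testing.assert_array_equal(c.all_coords, before)

    def test_displacement_norm_bounded(self, fixture_set, site_dimers, rng):
        for _ in range(50):
            c = self._config(fixture_set, site_dimers)
            before = c.all_coords.copy()
            perturb_coordinates(c, rng, max_disp=0.1)
            disp = np.linalg.norm(c.all_coords - before, axis=1)
            assert disp.max() <= 0.1 + 1e-12

    def test_directions_spherically_uniform(self, fixture_set, site_dimers, rng):
        """Mean resultant length of displacement directions decays ~ n^-1/2."""
        dirs = []
        for _ in range(400):
            c = self._config(fixture_set, site_dimers)
            before = c.all_coords.copy()
            perturb_coordinates(c, rng, max_disp=0.1)
            d = c.all_coords - before
            dirs.append(d / np.linalg.norm(d, axis=1, keepdims=True))
        dirs = np.vstack(dirs)
        n = dirs.shape[0]
        assert n >= 5000
        resultant = np.linalg.norm(dirs.mean(axis=0))
        # Rayleigh-style bound: E[R] ~ sqrt(3/n) under uniformity
        assert resultant < 4.0 * np.sqrt(1.0 / n)

    def test_originals_retained(self, fixture_set, site_dimers, rng):
        c = self._config(fixture_set, site_dimers)
        before = c.all_coords.copy()
        perturb_coordinates(c, rng)
        kept = np.vstack(c.unperturbed)
        np.testing.assert_array_equal(kept, before)


def neutral_general_dimer(site_dimers):
    return next(
        sd
        for sd in site_dimers
        if sd.charge_class == "neutral/neutral" and sd.pair_class == "general/general"
    )


class TestGenerateBatch:
    def test_accepting_stub_yields_n_in_range(self, site_dimers, radii):
        sd = neutral_general_dimer(site_dimers)
        configs, logs = generate_batch(
            sd, ConstantBackend(-1.0), radii, n=20, rng=rng_for_site_dimer(3, 0)
        )
        assert len(configs) == 20
        assert all(log.attempts == 1 for log in logs)
        spec = radial_spec_for(sd)
        for c in configs:
            ic = c.target_internal
            assert sd.protein_site.theta_range.contains(ic.theta_P)
            assert sd.ligand_site.theta_range.contains(ic.theta_L)
            assert spec.r_min <= ic.r <= spec.r_max

    def test_pre_perturbation_targets_achieved(self, site_dimers, radii):
        sd = neutral_general_dimer(site_dimers)
        configs, _ = generate_batch(
            sd,
            ConstantBackend(-1.0),
            radii,
            n=10,
            rng=rng_for_site_dimer(3, 1),
            max_disp=0.0,
        )
        for c in configs:
            measured = internal_from_cartesian(
                c, sd.protein_site, sd.ligand_site, radii=radii
            )
            assert measured.r_PL == pytest.approx(c.target_internal.r_PL, abs=1e-6)
            assert measured.r == pytest.approx(c.target_internal.r, abs=1e-6)

    def test_post_perturbation_r_drift_bounded(self, site_dimers, radii):
        sd = neutral_general_dimer(site_dimers)
        configs, _ = generate_batch(
            sd, ConstantBackend(-1.0), radii, n=10, rng=rng_for_site_dimer(3, 2)
        )
        for c in configs:
            measured = internal_from_cartesian(
                c, sd.protein_site, sd.ligand_site, radii=radii
            )
            assert abs(measured.r - c.target_internal.r) <= 0.2

    def test_retry_bounds_expand_from_first_rejection(self, site_dimers, radii):
        """k-th consecutive failure shrinks the radial cap to r0 + 0.1k."""
        sd = neutral_general_dimer(site_dimers)
        backend = ScriptedBackend([100.0, 100.0, 100.0], fallback=-1.0)
        configs, logs = generate_batch(
            sd, backend, radii, n=2, rng=rng_for_site_dimer(3, 3)
        )
        assert len(configs) == 2
        log = logs[0]
        assert log.attempts == 4
        r0 = log.rejected_r[0]
        assert log.upper_bounds[0] is None
        assert log.upper_bounds[1] == pytest.approx(r0 + 0.1)
        assert log.upper_bounds[2] == pytest.approx(r0 + 0.2)
        assert log.upper_bounds[3] == pytest.approx(r0 + 0.3)
        # and the chain resets after acceptance
        assert logs[1].upper_bounds == [None]

    def test_accepted_satisfy_threshold(self, site_dimers, radii, surrogate):
        sd = neutral_general_dimer(site_dimers)
        policy = RejectionPolicy()
        configs, _ = generate_batch(
            sd, surrogate, radii, n=30, policy=policy, rng=rng_for_site_dimer(5, 0)
        )
        for c in configs:
            again = surrogate(c)
            assert again.total <= policy.threshold
            assert again.total == pytest.approx(c.energies[0].total)

    def test_like_charged_uses_200_threshold(self, site_dimers, radii, surrogate):
        sd = next(s for s in site_dimers if s.like_charged)
        configs, logs = generate_batch(
            sd, surrogate, radii, n=5, rng=rng_for_site_dimer(5, 1)
        )
        assert all(log.threshold == 200.0 for log in logs)
        assert all(c.energies[0].total <= 200.0 for c in configs)

    def test_bitwise_determinism(self, site_dimers, radii, surrogate):
        sd = neutral_general_dimer(site_dimers)
        a, _ = generate_batch(sd, surrogate, radii, n=8, rng=rng_for_site_dimer(7, 4))
        b, _ = generate_batch(sd, surrogate, radii, n=8, rng=rng_for_site_dimer(7, 4))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.all_coords, cb.all_coords)
            assert ca.energies[0].total == cb.energies[0].total

    def test_radial_density_preserved_with_accepting_backend(
        self, site_dimers, radii
    ):
        """With no rejections the sampled r follows the piecewise density."""
        sd = neutral_general_dimer(site_dimers)
        configs, _ = generate_batch(
            sd, ConstantBackend(-1.0), radii, n=400, rng=rng_for_site_dimer(11, 0)
        )
        rs = np.array([c.target_internal.r for c in configs])
        spec = radial_spec_for(sd)
        edges = np.linspace(spec.r_min, spec.r_max, 9)
        observed, _ = np.histogram(rs, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        probs = radial_pdf(spec, centers)
        probs = probs / probs.sum()
        res = stats.chisquare(observed, f_exp=probs * len(rs))
        assert res.pvalue > 0.01
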