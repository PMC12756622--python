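"""Retention/conductivity model values, fitting behaviour and water points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilstruct.hydraulics import (
    FitConfig,
    KosugiBimodalParams,
    RetentionDataset,
    fit_kosugi_bimodal,
    K_of_h,
    rmse,
    theta_of_h,
    water_points,
)
from soilstruct.synthetic import simulate_retention_dataset

# frozen from a 50-digit mpmath evaluation of the closed forms
THETA_AT_50 = 0.34235746527088628
K_AT_200 = 0.017516258608269772


class TestThetaOfH:
    def test_high_precision_oracle(self, ref_params):
        assert theta_of_h(50.0, ref_params) == pytest.approx(THETA_AT_50, abs=1e-14)

    def test_saturation_limit(self, ref_params):
        assert theta_of_h(1e-10, ref_params) == pytest.approx(ref_params.theta_s, abs=1e-12)

    def test_median_symmetry_unimodal(self):
        """At h = hm1 with a single domain, exactly half the pore space is drained."""
        p = KosugiBimodalParams(
            theta_r=0.05, theta_s=0.45, w=1.0, hm1=100.0, sigma1=1.0,
            hm2=100.0, sigma2=1.0,
        )
        expected = 0.05 + (0.45 - 0.05) / 2
        assert theta_of_h(100.0, p) == pytest.approx(expected, abs=1e-14)

    def test_rejects_nonpositive_head(self, ref_params):
        with pytest.raises(ValueError):
            theta_of_h(0.0, ref_params)
        with pytest.raises(ValueError):
            theta_of_h(-5.0, ref_params)

    def test_monotone_and_bounded_over_pool(self, random_params_pool):
        h = np.logspace(-2, 6, 400)
        for p in random_params_pool:
            th = theta_of_h(h, p)
            assert np.all(np.diff(th) <= 1e-15)
            assert np.all(th >= p.theta_r - 1e-12)
            assert np.all(th <= p.theta_s + 1e-12)


class TestKOfH:
    def test_high_precision_oracle(self, ref_params):
        assert K_of_h(200.0, ref_params) == pytest.approx(K_AT_200, rel=1e-11)

    def test_saturated_limit_is_Ks(self, ref_params):
        assert K_of_h(1e-9, ref_params) == pytest.approx(ref_params.Ks, rel=1e-9)

    def test_dry_limit_vanishes(self, ref_params):
        assert K_of_h(1e8, ref_params) == pytest.approx(0.0, abs=1e-20)

    def test_monotone_nonincreasing(self, random_params_pool):
        h = np.logspace(-1, 5, 200)
        for p in random_params_pool[:15]:
            k = K_of_h(h, p)
            assert np.all(np.diff(k) <= 1e-12 * max(p.Ks, 1.0))
            assert np.all(k >= 0.0)
            assert np.all(k <= p.Ks * (1 + 1e-9))


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"theta_r": 0.5, "theta_s": 0.4},
            {"theta_r": -0.1},
            {"w": 0.0},
            {"w": 1.2},
            {"hm1": -10.0},
            {"sigma1": 0.0},
            {"Ks": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        base = dict(theta_r=0.05, theta_s=0.5, w=0.5, hm1=50.0, sigma1=0.8,
                    hm2=2000.0, sigma2=1.2, Ks=100.0, tau=0.5)
        base.update(kw)
        with pytest.raises(ValueError):
            KosugiBimodalParams(**base)

    def test_domain_sorting_preserves_curve(self, ref_params):
        swapped = KosugiBimodalParams(
            theta_r=0.05, theta_s=0.50, w=0.3, hm1=2000.0, sigma1=1.2,
            hm2=50.0, sigma2=0.8, Ks=100.0, tau=0.5,
        )
        sorted_p = swapped.sorted_domains()
        assert sorted_p.hm1 <= sorted_p.hm2
        h = np.logspace(0, 4, 50)
        np.testing.assert_allclose(theta_of_h(h, swapped), theta_of_h(h, sorted_p), atol=1e-15)


class TestRmse:
    def test_identity_and_hand_values(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([0.11, 0.19], [0.10, 0.20]) == pytest.approx(0.01)
        assert rmse([0.52], [0.50]) == pytest.approx(0.02)

    def test_input_errors(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([], [])


class TestFit:
    def test_noiseless_recovery(self, ref_params):
        """Noiseless data from well-separated modes returns the generating curve."""
        ret = simulate_retention_dataset(
            ref_params, n_points=60, noise_sd=0.0, seed=5, pf_range=(0.0, 4.2), n_dry=0
        )
        fr = fit_kosugi_bimodal(ret)
        assert fr.converged
        pred = theta_of_h(ret.h, fr.params)
        assert np.max(np.abs(pred - ret.theta)) < 1e-6
        for name in ("theta_r", "theta_s", "w", "hm1", "sigma1", "hm2", "sigma2"):
            got, true = getattr(fr.params, name), getattr(ref_params, name)
            assert got == pytest.approx(true, rel=1e-4), name

    def test_unimodal_degenerate_mode(self):
        """Data generated with a single pore domain is matched curve-for-curve."""
        uni = KosugiBimodalParams(
            theta_r=0.06, theta_s=0.48, w=1.0, hm1=300.0, sigma1=1.1,
            hm2=300.0, sigma2=1.1,
        )
        ret = simulate_retention_dataset(
            uni, n_points=60, noise_sd=0.0, seed=3, pf_range=(0.0, 4.2), n_dry=0
        )
        fr = fit_kosugi_bimodal(ret)
        pred = theta_of_h(ret.h, fr.params)
        assert np.max(np.abs(pred - ret.theta)) < 1e-6

    def test_noisy_fit_meets_reported_quality(self, ref_params):
        ret = simulate_retention_dataset(
            ref_params, n_points=100, noise_sd=0.003, seed=42,
            pf_range=(0.0, 4.2), n_dry=0,
        )
        fr = fit_kosugi_bimodal(ret)
        assert fr.rmse_theta <= 0.01

    def test_local_optimality_spot_check(self, ref_params):
        """Perturbing the fitted parameters never lowers the theta RMSE."""
        ret = simulate_retention_dataset(
            ref_params, n_points=80, noise_sd=0.002, seed=9, pf_range=(0.0, 4.2), n_dry=0
        )
        fr = fit_kosugi_bimodal(ret)
        base = rmse(ret.theta, theta_of_h(ret.h, fr.params))
        rng = np.random.default_rng(1)
        import dataclasses

        for _ in range(20):
            factors = 1.0 + rng.uniform(-0.02, 0.02, size=7)
            try:
                perturbed = dataclasses.replace(
                    fr.params,
                    theta_r=fr.params.theta_r * factors[0],
                    theta_s=fr.params.theta_s * factors[1],
                    w=min(fr.params.w * factors[2], 0.999),
                    hm1=fr.params.hm1 * factors[3],
                    sigma1=fr.params.sigma1 * factors[4],
                    hm2=fr.params.hm2 * factors[5],
                    sigma2=fr.params.sigma2 * factors[6],
                )
            except ValueError:
                continue
            assert rmse(ret.theta, theta_of_h(ret.h, perturbed)) >= base - 1e-12

    def test_too_few_points_rejected(self, ref_params):
        ret = RetentionDataset(h=np.logspace(0, 4, 5), theta=np.full(5, 0.3))
        with pytest.raises(ValueError, match="at least 9"):
            fit_kosugi_bimodal(ret)

    def test_narrow_head_span_rejected(self):
        ret = RetentionDataset(h=np.linspace(10, 90, 12), theta=np.linspace(0.4, 0.3, 12))
        with pytest.raises(ValueError, match="decades"):
            fit_kosugi_bimodal(ret)

    def test_deterministic_given_seed(self, ref_params):
        ret = simulate_retention_dataset(ref_params, n_points=40, noise_sd=0.005, seed=2)
        a = fit_kosugi_bimodal(ret, config=FitConfig(n_starts=6, seed=7))
        b = fit_kosugi_bimodal(ret, config=FitConfig(n_starts=6, seed=7))
        assert a.params == b.params
        assert a.cost == b.cost


class TestWaterPoints:
    def test_identity_wa(self, ref_params):
        wp = water_points(ref_params, bulk_density=1.4)
        assert wp.Wa == pytest.approx(wp.Fc - wp.PWP, abs=1e-12)
        assert wp.PWP <= wp.Fc

    def test_porosity_table_pairs(self):
        """phi = 1 - BD/2.65 reproduces the printed (BD, phi) pairs.

        Tolerance is the printed precision of both numbers propagated
        (phi printed to 2 dp, BD to 2 dp scaled by 1/2.65).
        """
        pairs = [(1.32, 0.50), (1.33, 0.50), (1.28, 0.52),
                 (1.47, 0.44), (1.42, 0.46), (1.38, 0.48)]
        tol = 0.005 + 0.005 / 2.65
        p = KosugiBimodalParams(theta_r=0.05, theta_s=0.5, w=0.5, hm1=50.0,
                                sigma1=0.8, hm2=2000.0, sigma2=1.2)
        for bd, phi_printed in pairs:
            wp = water_points(p, bulk_density=bd, particle_density=2.65)
            assert abs(wp.phi - phi_printed) <= tol, (bd, phi_printed, wp.phi)

    def test_bd_must_be_below_particle_density(self, ref_params):
        with pytest.raises(ValueError):
            water_points(ref_params, bulk_density=2.7, particle_density=2.65)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    theta_r=st.floats(0.0, 0.2),
    dts=st.floats(0.1, 0.45),
    w=st.floats(0.05, 0.95),
    log_hm1=st.floats(0.5, 3.0),
    sigma1=st.floats(0.2, 3.0),
    log_hm2=st.floats(0.5, 4.5),
    sigma2=st.floats(0.2, 3.0),
    log_h=st.floats(-2.0, 6.0),
)
def test_theta_within_bounds_property(theta_r, dts, w, log_hm1, sigma1, log_hm2, sigma2, log_h):
    """theta(h) always lies in [theta_r, theta_s] for valid parameters."""
    p = KosugiBimodalParams(
        theta_r=theta_r, theta_s=theta_r + dts, w=w,
        hm1=10**log_hm1, sigma1=sigma1, hm2=10**log_hm2, sigma2=sigma2,
    )
    th = theta_of_h(10**log_h, p)
    assert p.theta_r - 1e-12 <= th <= p.theta_s + 1e-12
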