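"""Pore-size distributions, Young-Laplace transform and the KL structure index."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import lognorm

from soilstruct.structure import (
    DEFAULT_R_MAX_UM,
    DEFAULT_R_MIN_UM,
    PoreSizeDistribution,
    ReferenceSoilSpec,
    head_from_radius,
    kl_divergence,
    psd_from_retention,
    radius_from_head,
    reference_psd,
)


class TestRadiusFromHead:
    def test_paper_bounds(self):
        assert radius_from_head(1.0) == pytest.approx(1490.0)
        assert radius_from_head(14900.0) == pytest.approx(0.1)
        assert radius_from_head(149.0) == pytest.approx(10.0)

    def test_roundtrip_identity(self):
        h = np.logspace(-2, 6, 200)
        np.testing.assert_allclose(head_from_radius(radius_from_head(h)), h, rtol=1e-12)

    def test_strictly_decreasing(self):
        h = np.logspace(0, 4, 50)
        assert np.all(np.diff(radius_from_head(h)) < 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            radius_from_head(0.0)
        with pytest.raises(ValueError):
            head_from_radius(-1.0)


def _integral(psd, lo=None, hi=None):
    lo = lo if lo is not None else psd.r_min
    hi = hi if hi is not None else psd.r_max
    val, _ = integrate.quad(lambda u: psd.pdf(math.exp(u)) * math.exp(u),
                            math.log(lo), math.log(hi), limit=300)
    return val


class TestPsdFromRetention:
    def test_normalization_contract(self, ref_params, random_params_pool):
        for p in [ref_params] + random_params_pool[:8]:
            psd = psd_from_retention(p)
            assert _integral(psd) == pytest.approx(1.0, abs=1e-6)

    def test_unimodal_median(self):
        """A single domain with hm = 149 cm gives a lognormal with median 10 um."""
        from soilstruct.hydraulics import KosugiBimodalParams

        p = KosugiBimodalParams(theta_r=0.05, theta_s=0.5, w=1.0, hm1=149.0,
                                sigma1=0.8, hm2=149.0, sigma2=0.8)
        psd = psd_from_retention(p, r_min=1e-6, r_max=1e9)
        # median: half the mass lies below 10 um
        val = _integral(psd, psd.r_min, 10.0)
        assert val == pytest.approx(0.5, abs=1e-6)

    def test_quantiles_match_monte_carlo(self, ref_params):
        """Mixture quantiles agree with empirical quantiles of 1e6 draws."""
        psd = psd_from_retention(ref_params, r_min=1e-8, r_max=1e12)
        rng = np.random.default_rng(123)
        n = 10**6
        comp = rng.random(n) < ref_params.w
        draws = np.where(
            comp,
            lognorm.rvs(s=ref_params.sigma1, scale=radius_from_head(ref_params.hm1),
                        size=n, random_state=np.random.default_rng(1)),
            lognorm.rvs(s=ref_params.sigma2, scale=radius_from_head(ref_params.hm2),
                        size=n, random_state=np.random.default_rng(2)),
        )
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            emp = np.quantile(draws, q)
            # invert the mixture CDF numerically via mass integrals
            lo, hi = 1e-6, 1e10
            for _ in range(80):
                mid = math.sqrt(lo * hi)
                if _integral(psd, psd.r_min, mid) < q:
                    lo = mid
                else:
                    hi = mid
            assert math.sqrt(lo * hi) == pytest.approx(emp, rel=0.01)

    def test_water_content_convention_scales_density(self, ref_params):
        norm = psd_from_retention(ref_params)
        wc = psd_from_retention(ref_params, convention="water_content")
        r = np.geomspace(0.2, 1000.0, 20)
        np.testing.assert_allclose(
            np.asarray(wc.pdf(r)),
            (ref_params.theta_s - ref_params.theta_r) * np.asarray(norm.pdf(r)),
            rtol=1e-12,
        )
        with pytest.raises(ValueError, match="convention"):
            psd_from_retention(ref_params, convention="nope")

    def test_degenerate_truncation_raises(self, ref_params):
        with pytest.raises(ValueError, match="degenerate"):
            psd_from_retention(ref_params, r_min=1e8, r_max=1e9)


class TestKlDivergence:
    def _lognormal_psd(self, median, sigma, r_min=1e-8, r_max=1e10, kind="structured"):
        return PoreSizeDistribution(
            weights=(1.0,), medians_um=(median,), sigmas=(sigma,),
            r_min=r_min, r_max=r_max, kind=kind,
        )

    def test_identity_is_zero(self):
        p = self._lognormal_psd(10.0, 0.8)
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-8)

    def test_closed_form_lognormal(self):
        """Numeric KL matches the closed form for two wide-bounded lognormals."""
        p = self._lognormal_psd(10.0, 0.8)
        q = self._lognormal_psd(5.0, 1.2)
        mu1, mu2, s1, s2 = math.log(10), math.log(5), 0.8, 1.2
        closed = math.log(s2 / s1) + (s1**2 + (mu1 - mu2) ** 2) / (2 * s2**2) - 0.5
        assert closed == pytest.approx(0.2945112934964289, abs=1e-12)
        assert kl_divergence(p, q) == pytest.approx(closed, abs=1e-4)

    def test_positive_when_different(self, random_params_pool):
        """Gibbs inequality over random mixture pairs on the standard bounds."""
        for pa, pb in zip(random_params_pool[:6], random_params_pool[6:12]):
            p = psd_from_retention(pa)
            q = psd_from_retention(pb)
            val = kl_divergence(p, q)
            assert val >= 0.0
            if (pa.hm1, pa.sigma1, pa.hm2, pa.sigma2, pa.w) != (
                    pb.hm1, pb.sigma1, pb.hm2, pb.sigma2, pb.w):
                assert val > 0.0

    def test_quadrature_convergence(self, ref_params, random_params_pool):
        """Tightening the quadrature tolerance tenfold moves the result < 1e-5."""
        p = psd_from_retention(ref_params)
        q = psd_from_retention(random_params_pool[0])
        a = kl_divergence(p, q, epsabs=1e-8)
        b = kl_divergence(p, q, epsabs=1e-9)
        assert abs(a - b) < 1e-5

    def test_support_mismatch_raises(self):
        p = self._lognormal_psd(1000.0, 0.2, r_min=0.1, r_max=1490.0)
        q = self._lognormal_psd(0.5, 0.2, r_min=0.1, r_max=1490.0)
        with pytest.raises(ValueError, match="underflow|diverge"):
            kl_divergence(p, q)


def _texture_spec(sizes, cmf, theta_r=0.05):
    return ReferenceSoilSpec(
        size_um=np.asarray(sizes, dtype=float),
        cum_mass_fraction=np.asarray(cmf, dtype=float),
        theta_r_fixed=theta_r,
    )


class TestReferencePsd:
    def test_deterministic(self):
        spec = _texture_spec([2.0, 20.0, 63.0, 200.0, 2000.0],
                             [0.11, 0.40, 0.76, 0.90, 1.0])
        a, _ = reference_psd(spec)
        b, _ = reference_psd(spec)
        assert a.medians_um == b.medians_um
        assert a.sigmas == b.sigmas

    def test_sand_coarser_than_clay(self):
        """A sandy texture implies larger reference pores than a clayey one."""
        sand = _texture_spec([63.0, 200.0, 600.0, 2000.0], [0.05, 0.35, 0.75, 1.0])
        clay = _texture_spec([0.2, 0.6, 1.2, 2.0], [0.2, 0.5, 0.8, 1.0])
        psd_sand, _ = reference_psd(sand, r_min=1e-4, r_max=1e6)
        psd_clay, _ = reference_psd(clay, r_min=1e-4, r_max=1e6)

        def median(psd):
            lo, hi = 1e-5, 1e7
            for _ in range(60):
                mid = math.sqrt(lo * hi)
                if _integral(psd, psd.r_min, mid) < 0.5:
                    lo = mid
                else:
                    hi = mid
            return math.sqrt(lo * hi)

        assert median(psd_sand) > median(psd_clay)

    def test_fit_quality_on_smooth_texture(self):
        """The fitted reference curve passes through the constructed pairs."""
        spec = _texture_spec([0.5, 2.0, 10.0, 30.0, 63.0, 200.0, 2000.0],
                             [0.03, 0.11, 0.35, 0.60, 0.76, 0.90, 1.0])
        _, fit = reference_psd(spec)
        assert fit.rmse_theta <= 0.01

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            _texture_spec([2.0, 2000.0], [0.3, 1.0])


class TestStructureSignal:
    def test_added_coarse_mode_raises_index(self, ref_params):
        """Adding a coarse structural pore mode increases KL vs the same reference."""
        spec = _texture_spec([2.0, 20.0, 63.0, 200.0, 2000.0],
                             [0.11, 0.40, 0.76, 0.90, 1.0],
                             theta_r=ref_params.theta_r)
        q, _ = reference_psd(spec)
        structured = dataclasses.replace(ref_params, w=0.7)  # strong coarse mode
        weak = dataclasses.replace(ref_params, w=0.35)
        kld_structured = kl_divergence(psd_from_retention(structured), q)
        kld_weak = kl_divergence(psd_from_retention(weak), q)
        assert kld_structured > kld_weak
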