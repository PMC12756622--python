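"""Pore-size distributions and the Kullback-Leibler soil-structure index.

A fitted bimodal lognormal retention curve implies, through the simplified
Young-Laplace capillary relation r = 0.149/h (r in cm, h in cm of water),
a pore-radius density that is itself a two-component lognormal mixture.
The structure index is the KL divergence between the pore-size density of
the structured soil and that of a hypothetical reference soil of the same
texture but without structural pores, integrated over pore radii between
0.1 um (the equivalent radius at the wilting point) and 1490 um (h = 1 cm).
A larger divergence means the in-situ pore system departs more from the
texture-only packing, i.e. greater structural development.

Note on the capillary constant: with surface tension of water at roughly
20 C the capillary-rise relation gives r [cm] = 0.149 / h [cm]; the bounds
0.1 um (wilting point, h ~ 14900 cm) and 1490 um (h = 1 cm) follow.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.stats import lognorm

from .hydraulics import FitConfig, KosugiBimodalParams, RetentionDataset, fit_kosugi_bimodal

__all__ = [
    "CAPILLARY_CONSTANT_CM2",
    "DEFAULT_R_MIN_UM",
    "DEFAULT_R_MAX_UM",
    "PoreSizeDistribution",
    "ReferenceSoilSpec",
    "radius_from_head",
    "head_from_radius",
    "psd_from_retention",
    "reference_psd",
    "kl_divergence",
]

#: Young-Laplace capillary constant: r [cm] * h [cm] = 0.149 (water, ~20 C).
CAPILLARY_CONSTANT_CM2 = 0.149

#: Default pore-radius bounds of the structure index, um.
DEFAULT_R_MIN_UM = 0.1
DEFAULT_R_MAX_UM = 1490.0


def radius_from_head(h):
    """Equivalent capillary pore radius (um) at pressure head ``h`` (cm).

    r [cm] = 0.149 / h [cm], returned in micrometres.  Strictly decreasing
    in h: h = 1 cm maps to 1490 um, h = 14900 cm to 0.1 um.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0.0):
        raise ValueError("pressure head must be positive")
    r = CAPILLARY_CONSTANT_CM2 / h * 1e4
    return r if r.ndim else float(r)


def head_from_radius(r_um):
    """Pressure head (cm) whose capillary radius is ``r_um`` (um); inverse of radius_from_head."""
    r_um = np.asarray(r_um, dtype=float)
    if np.any(r_um <= 0.0):
        raise ValueError("pore radius must be positive")
    h = CAPILLARY_CONSTANT_CM2 / (r_um * 1e-4)
    return h if h.ndim else float(h)


@dataclass(frozen=True)
class PoreSizeDistribution:
    """A (truncated, renormalized) lognormal-mixture density over pore radius.

    The density is d(Se)/dr of the generating retention model expressed in
    pore radius via Young-Laplace, truncated to [r_min, r_max] um and
    renormalized to integrate to one.  ``weights``, ``medians_um`` and
    ``sigmas`` describe the untruncated mixture components.  ``scale``
    multiplies the normalized density (1.0 for the probability-density
    convention; theta_s - theta_r for the water-content-weighted dtheta/dr
    convention).
    """

    weights: tuple
    medians_um: tuple
    sigmas: tuple
    r_min: float = DEFAULT_R_MIN_UM
    r_max: float = DEFAULT_R_MAX_UM
    kind: str = "structured"
    scale: float = 1.0
    source_params: KosugiBimodalParams | None = None
    #: untruncated mixture mass inside [r_min, r_max]; set in __post_init__
    _mass: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.r_min < self.r_max):
            raise ValueError("need 0 < r_min < r_max")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        mass = 0.0
        for w, m, s in zip(self.weights, self.medians_um, self.sigmas):
            comp = lognorm(s=s, scale=m)
            mass += w * (comp.cdf(self.r_max) - comp.cdf(self.r_min))
        if mass < 1e-6:
            raise ValueError(
                f"mixture mass inside [{self.r_min}, {self.r_max}] um is {mass:.2e}; "
                "truncation is degenerate"
            )
        object.__setattr__(self, "_mass", mass)

    def pdf(self, r_um):
        """Normalized density p(r) in um^-1 on [r_min, r_max]; zero outside."""
        r = np.asarray(r_um, dtype=float)
        out = np.zeros_like(r, dtype=float)
        inside = (r >= self.r_min) & (r <= self.r_max)
        if np.any(inside):
            dens = np.zeros(np.count_nonzero(inside))
            for w, m, s in zip(self.weights, self.medians_um, self.sigmas):
                dens += w * lognorm.pdf(r[inside], s=s, scale=m)
            out[inside] = self.scale * dens / self._mass
        return out if out.ndim else float(out)


def psd_from_retention(
    params: KosugiBimodalParams,
    r_min: float = DEFAULT_R_MIN_UM,
    r_max: float = DEFAULT_R_MAX_UM,
    kind: str = "structured",
    convention: str = "normalized",
) -> PoreSizeDistribution:
    """Pore-size density implied by a fitted bimodal Kosugi retention curve.

    Under r = 0.149/h a lognormal pore domain with median head hm and
    spread sigma maps to a lognormal radius component with median
    radius_from_head(hm) and the same sigma; the domain weights carry over.

    ``convention`` selects ``"normalized"`` (d(Se)/dr renormalized on the
    bounds, a proper probability density — the default) or
    ``"water_content"`` (dtheta/dr: the normalized density scaled by
    theta_s - theta_r).
    """
    if convention not in ("normalized", "water_content"):
        raise ValueError(f"unknown PSD convention {convention!r}")
    scale = 1.0 if convention == "normalized" else params.theta_s - params.theta_r
    return PoreSizeDistribution(
        weights=(params.w, 1.0 - params.w),
        medians_um=(radius_from_head(params.hm1), radius_from_head(params.hm2)),
        sigmas=(params.sigma1, params.sigma2),
        r_min=r_min,
        r_max=r_max,
        kind=kind,
        scale=scale,
        source_params=params,
    )


@dataclass(frozen=True)
class ReferenceSoilSpec:
    """Specification of the structureless (texture-only) reference soil.

    ``particle_size``: cumulative particle-size distribution as parallel
    arrays of particle diameter (um, ascending) and cumulative mass
    fraction (non-decreasing, ending at 1).  ``theta_r_fixed`` is taken
    from the structured soil's fit; ``theta_s_ref`` is the reference
    soil's saturated water content.  ``packing_factor`` scales particle
    radius to equivalent pore radius.
    """

    size_um: np.ndarray
    cum_mass_fraction: np.ndarray
    theta_r_fixed: float
    theta_s_ref: float = 0.30
    packing_factor: float = 0.3

    def __post_init__(self) -> None:
        size = np.asarray(self.size_um, dtype=float)
        cmf = np.asarray(self.cum_mass_fraction, dtype=float)
        if size.shape != cmf.shape or size.ndim != 1:
            raise ValueError("size_um and cum_mass_fraction must be 1-d and equal length")
        if np.unique(size).size < 3:
            raise ValueError("need at least 3 distinct particle-size classes")
        if np.any(np.diff(size) <= 0):
            raise ValueError("particle sizes must be strictly ascending")
        if np.any(np.diff(cmf) < 0) or abs(cmf[-1] - 1.0) > 1e-6:
            raise ValueError("cumulative mass fractions must be non-decreasing and end at 1")
        if not (0.0 <= self.theta_r_fixed < self.theta_s_ref <= 1.0):
            raise ValueError("need 0 <= theta_r_fixed < theta_s_ref <= 1")
        if self.packing_factor <= 0.0:
            raise ValueError("packing factor must be positive")
        object.__setattr__(self, "size_um", size)
        object.__setattr__(self, "cum_mass_fraction", cmf)


def reference_psd(
    spec: ReferenceSoilSpec,
    fit_config: FitConfig | None = None,
    r_min: float = DEFAULT_R_MIN_UM,
    r_max: float = DEFAULT_R_MAX_UM,
    convention: str = "normalized",
) -> tuple[PoreSizeDistribution, "object"]:
    """Pore-size density of the texture-only reference soil.

    The cumulative particle-size distribution is mapped to (pore radius,
    water content) pairs: equivalent pore radius = packing_factor x particle
    radius (radius = diameter/2), and cumulative mass fraction F maps to
    water content theta_r + F (theta_s_ref - theta_r) — coarser particles
    bound larger pores that drain earlier.  The same bimodal lognormal
    retention form is then fitted to those pairs with theta_r and theta_s
    held fixed, and the implied pore-size density is returned together
    with the FitResult.
    """
    r_pore = spec.packing_factor * spec.size_um / 2.0
    theta_pairs = spec.theta_r_fixed + spec.cum_mass_fraction * (
        spec.theta_s_ref - spec.theta_r_fixed
    )

    # densify by monotone interpolation in log r, extending one decade past
    # each end where the cumulative distribution is flat (F = 0 / F = 1),
    # so the fitter always sees the full drainage range
    r_dense = np.geomspace(r_pore.min() / 10.0, r_pore.max() * 10.0, 60)
    theta = np.interp(np.log(r_dense), np.log(r_pore), theta_pairs)
    h = head_from_radius(r_dense)

    order = np.argsort(h)
    ret = RetentionDataset(h=h[order], theta=np.clip(theta[order], 0.0, 1.0))
    base = fit_config or FitConfig()
    fixed = dict(base.fixed)
    fixed.setdefault("theta_r", spec.theta_r_fixed)
    fixed.setdefault("theta_s", spec.theta_s_ref)
    config = dataclasses.replace(base, fixed=fixed, bounds=dict(base.bounds))
    # median heads implied by the texture can fall below 1 cm for coarse sand
    config.bounds["log_hm1"] = (min(0.0, np.log10(h.min())), 5.0)
    config.bounds["log_hm2"] = config.bounds["log_hm1"]
    fit = fit_kosugi_bimodal(ret, None, config)
    psd = psd_from_retention(
        fit.params, r_min=r_min, r_max=r_max, kind="reference", convention=convention
    )
    return psd, fit


def kl_divergence(
    p: PoreSizeDistribution,
    q: PoreSizeDistribution,
    r_min: float | None = None,
    r_max: float | None = None,
    epsabs: float = 1e-8,
) -> float:
    """KL divergence  integral of p(r) ln[p(r)/q(r)] dr  on [r_min, r_max].

    Computed by adaptive quadrature on the ln r axis.  Non-negative up to
    quadrature noise; tiny negative results (> -1e-8) are clamped to zero.

    Raises
    ------
    ValueError
        If q underflows to zero somewhere p carries mass (the divergence
        is then infinite, not a number to floor silently).
    """
    r_min = r_min if r_min is not None else max(p.r_min, q.r_min)
    r_max = r_max if r_max is not None else min(p.r_max, q.r_max)
    if not (0.0 < r_min < r_max):
        raise ValueError("need 0 < r_min < r_max on a shared support")

    # support check on a log grid before integrating
    grid = np.geomspace(r_min, r_max, 512)
    p_g = np.asarray(p.pdf(grid))
    q_g = np.asarray(q.pdf(grid))
    bad = (p_g > 1e-12) & (q_g <= 0.0)
    if np.any(bad):
        raise ValueError(
            "reference density underflows to zero on part of the structured "
            "soil's support; KL divergence diverges"
        )

    def integrand(u: float) -> float:
        r = np.exp(u)
        pr = p.pdf(r)
        if pr <= 0.0:
            return 0.0
        qr = q.pdf(r)
        if qr <= 0.0:
            return 0.0  # excluded region already screened above
        return pr * np.log(pr / qr) * r  # extra r is the Jacobian dr = r du

    val, _ = integrate.quad(
        integrand, np.log(r_min), np.log(r_max), epsabs=epsabs, limit=400
    )
    if val < -1e-8:
        raise ValueError(f"quadrature returned {val}, more negative than tolerance")
    return max(val, 0.0)
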