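"""Bimodal Kosugi soil-hydraulic model: retention, conductivity, fitting.

The retention model represents the pore system as a mixture of two
lognormal pore domains.  Volumetric water content at pressure-head
magnitude ``h`` (cm of water, positive suction) is

    theta(h) = theta_r
             + w       * (theta_s - theta_r) * 1/2 erfc[ln(h/hm1) / (sigma1 sqrt(2))]
             + (1 - w) * (theta_s - theta_r) * 1/2 erfc[ln(h/hm2) / (sigma2 sqrt(2))]

with domain weight ``w``, median heads ``hm1``/``hm2`` and lognormal
spreads ``sigma1``/``sigma2``.  The matching Mualem-type conductivity
curve is

    K(h) = Ks * Se^tau * [a erfc(x1) + b erfc(x2)]^2 / (4 (a + b)^2)

where ``x_i = sigma_i/sqrt(2) + erfc^-1(2 Se_i)``, ``Se_i`` is the
per-domain effective saturation, ``a = w/hm1 * exp(sigma1^2/2)`` and
``b = (1-w)/hm2 * exp(sigma2^2/2)``.

Fitting is bounded nonlinear least squares with a seeded Latin-hypercube
multistart, jointly over theta residuals and (optionally) log10 K
residuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import erfc, erfcinv
from scipy.stats import qmc

logger = logging.getLogger(__name__)

__all__ = [
    "KosugiBimodalParams",
    "RetentionDataset",
    "ConductivityDataset",
    "FitConfig",
    "FitResult",
    "WaterPoints",
    "theta_of_h",
    "K_of_h",
    "effective_saturation",
    "fit_kosugi_bimodal",
    "rmse",
    "water_points",
    "DEFAULT_PARTICLE_DENSITY",
]

#: Standard mineral-soil particle density, g cm^-3.
DEFAULT_PARTICLE_DENSITY = 2.65

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class KosugiBimodalParams:
    """The nine parameters of the bimodal Kosugi retention/conductivity model.

    Parameters
    ----------
    theta_r, theta_s : float
        Residual and saturated volumetric water content, cm^3 cm^-3.
    w : float
        Weight of the first pore domain, in (0, 1).
    hm1, hm2 : float
        Median pressure heads of the two pore domains, cm (positive).
    sigma1, sigma2 : float
        Lognormal spreads of the two domains (dimensionless, > 0).
    Ks : float
        Saturated hydraulic conductivity, cm d^-1.
    tau : float
        Tortuosity/connectivity exponent of the conductivity model.
    """

    theta_r: float
    theta_s: float
    w: float
    hm1: float
    sigma1: float
    hm2: float
    sigma2: float
    Ks: float = 100.0
    tau: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ValueError(
                f"require 0 <= theta_r < theta_s <= 1, got "
                f"theta_r={self.theta_r}, theta_s={self.theta_s}"
            )
        if not (0.0 < self.w < 1.0) and self.w != 1.0:
            raise ValueError(f"pore-domain weight w must be in (0, 1]: {self.w}")
        for name in ("hm1", "hm2", "sigma1", "sigma2", "Ks"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def sorted_domains(self) -> "KosugiBimodalParams":
        """Return an equivalent parameter set with hm1 <= hm2.

        The two pore domains are exchangeable (label switching); sorting by
        median head makes reported parameters comparable across fits.
        """
        if self.hm1 <= self.hm2:
            return self
        return replace(
            self,
            w=1.0 - self.w,
            hm1=self.hm2,
            sigma1=self.sigma2,
            hm2=self.hm1,
            sigma2=self.sigma1,
        )


@dataclass(frozen=True)
class RetentionDataset:
    """Measured (h, theta) points for one soil core; h in cm, positive suction."""

    h: np.ndarray
    theta: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        if h.shape != theta.shape or h.ndim != 1:
            raise ValueError("h and theta must be 1-d arrays of equal length")
        if np.any(h <= 0.0):
            raise ValueError("pressure-head magnitudes must be positive")
        if np.any((theta < 0.0) | (theta > 1.0)):
            raise ValueError("volumetric water contents must lie in [0, 1]")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "theta", theta)

    def __len__(self) -> int:
        return self.h.size


@dataclass(frozen=True)
class ConductivityDataset:
    """Measured (h, K) points; h in cm, K in cm d^-1."""

    h: np.ndarray
    K: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        K = np.asarray(self.K, dtype=float)
        if h.shape != K.shape or h.ndim != 1:
            raise ValueError("h and K must be 1-d arrays of equal length")
        if np.any(h <= 0.0):
            raise ValueError("pressure-head magnitudes must be positive")
        if np.any(K <= 0.0):
            raise ValueError("conductivities must be positive")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "K", K)

    def __len__(self) -> int:
        return self.h.size


def _as_positive_h(h) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0.0):
        raise ValueError("pressure head h must be positive (suction magnitude, cm)")
    return h


def theta_of_h(h, params: KosugiBimodalParams):
    """Volumetric water content at pressure head ``h`` (cm).

    Scalar in, scalar out; array in, array out.  Result lies in
    [theta_r, theta_s] and decreases with h.
    """
    h = _as_positive_h(h)
    p = params
    s1 = 0.5 * erfc(np.log(h / p.hm1) / (p.sigma1 * _SQRT2))
    s2 = 0.5 * erfc(np.log(h / p.hm2) / (p.sigma2 * _SQRT2))
    out = p.theta_r + (p.theta_s - p.theta_r) * (p.w * s1 + (1.0 - p.w) * s2)
    return out if out.ndim else float(out)


def effective_saturation(h, params: KosugiBimodalParams):
    """Overall effective saturation Se(h) = (theta - theta_r)/(theta_s - theta_r)."""
    h = _as_positive_h(h)
    p = params
    s1 = 0.5 * erfc(np.log(h / p.hm1) / (p.sigma1 * _SQRT2))
    s2 = 0.5 * erfc(np.log(h / p.hm2) / (p.sigma2 * _SQRT2))
    out = p.w * s1 + (1.0 - p.w) * s2
    return out if out.ndim else float(out)


def K_of_h(h, params: KosugiBimodalParams):
    """Hydraulic conductivity at pressure head ``h`` (cm), in cm d^-1.

    Evaluates the Mualem-type closed form of the bimodal lognormal model.
    Per-domain saturations that fall outside [0, 1] by floating-point noise
    are clamped (with a debug log) before the inverse-erfc step.
    """
    h = _as_positive_h(h)
    p = params
    s1 = 0.5 * erfc(np.log(h / p.hm1) / (p.sigma1 * _SQRT2))
    s2 = 0.5 * erfc(np.log(h / p.hm2) / (p.sigma2 * _SQRT2))
    se = p.w * s1 + (1.0 - p.w) * s2
    eps_hi = np.nextafter(1.0, 0.0)
    clipped = (s1 > 1.0) | (s2 > 1.0) | (se > 1.0) | (s1 < 0.0) | (s2 < 0.0) | (se < 0.0)
    if np.any(clipped):
        logger.debug("clamped %d effective-saturation values into [0, 1]", int(np.sum(clipped)))
    s1 = np.clip(s1, 0.0, eps_hi)
    s2 = np.clip(s2, 0.0, eps_hi)
    se = np.clip(se, 0.0, eps_hi)

    a = p.w / p.hm1 * math.exp(0.5 * p.sigma1**2)
    b = (1.0 - p.w) / p.hm2 * math.exp(0.5 * p.sigma2**2)
    with np.errstate(divide="ignore", over="ignore"):
        t1 = a * erfc(p.sigma1 / _SQRT2 + erfcinv(2.0 * s1))
        t2 = b * erfc(p.sigma2 / _SQRT2 + erfcinv(2.0 * s2))
        out = p.Ks * se**p.tau * (t1 + t2) ** 2 / (4.0 * (a + b) ** 2)
    out = np.where(se <= 0.0, 0.0, out)
    return out if out.ndim else float(out)


def rmse(measured, predicted) -> float:
    """Root-mean-square error between two equal-length value sequences."""
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("rmse of empty sequences is undefined")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


# -- fitting -----------------------------------------------------------------

# search-space bounds; hm and Ks are searched in log10
_BOUND_NAMES = ("theta_r", "theta_s", "w", "log_hm1", "sigma1", "log_hm2", "sigma2", "log_Ks", "tau")
_DEFAULT_BOUNDS = {
    "theta_r": (0.0, 0.25),
    "theta_s": (0.25, 0.65),
    "w": (0.01, 0.99),
    "log_hm1": (0.0, 5.0),
    "sigma1": (0.1, 3.5),
    "log_hm2": (0.0, 5.0),
    "sigma2": (0.1, 3.5),
    "log_Ks": (-3.0, 4.0),
    "tau": (-2.0, 3.0),
}


@dataclass
class FitConfig:
    """Controls for the multistart least-squares fit.

    ``lambda_K`` weights the squared log10-K residuals relative to the
    theta residuals; None (the default) uses inverse-measurement-variance
    weighting, lambda = (sigma_theta / sigma_logK)^2, so each residual
    block contributes in proportion to its information content and noisy
    conductivity data cannot degrade the retention fit.  Set it to
    ``n_theta / n_K`` for per-point balancing instead.  ``fixed`` pins
    named parameters (natural units, e.g. ``{"theta_r": 0.05}``) which are
    then excluded from the search.
    """

    n_starts: int = 16
    seed: int = 42
    lambda_K: float | None = None
    sigma_theta: float = 0.003  # typical evaporation-method theta error, cm^3 cm^-3
    sigma_logK: float = 0.1  # typical log10-conductivity error
    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    fixed: dict = field(default_factory=dict)
    xtol: float = 1e-12
    ftol: float = 1e-12


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bimodal Kosugi fit."""

    params: KosugiBimodalParams
    rmse_theta: float
    rmse_logK: float | None
    n_theta: int
    n_K: int
    converged: bool
    seed: int
    cost: float


def _vector_to_params(x: np.ndarray, names: list[str], fixed: dict) -> KosugiBimodalParams:
    vals = dict(fixed)
    for name, v in zip(names, x):
        vals[name] = v
    kw = {
        "theta_r": vals["theta_r"],
        "theta_s": vals["theta_s"],
        "w": vals["w"],
        "hm1": 10.0 ** vals["log_hm1"] if "log_hm1" in vals else vals["hm1"],
        "sigma1": vals["sigma1"],
        "hm2": 10.0 ** vals["log_hm2"] if "log_hm2" in vals else vals["hm2"],
        "sigma2": vals["sigma2"],
        "Ks": 10.0 ** vals.get("log_Ks", 2.0) if "Ks" not in vals else vals["Ks"],
        "tau": vals.get("tau", 0.5),
    }
    return KosugiBimodalParams(**kw)


def fit_kosugi_bimodal(
    ret: RetentionDataset,
    cond: ConductivityDataset | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the bimodal Kosugi model to retention (and optional conductivity) data.

    Minimizes sum of squared theta residuals plus ``lambda_K`` times the sum
    of squared log10-K residuals, by bounded trust-region least squares from
    ``n_starts`` Latin-hypercube start points (deterministic under
    ``config.seed``).  When no conductivity data are supplied, Ks and tau do
    not enter the objective and are reported at fixed placeholder values.

    Raises
    ------
    ValueError
        If the retention data have fewer than 9 points or span less than
        two decades of pressure head.
    """
    config = config or FitConfig()
    if len(ret) < 9:
        raise ValueError(f"need at least 9 retention points, got {len(ret)}")
    span = math.log10(ret.h.max() / ret.h.min())
    if span < 2.0:
        raise ValueError(f"retention heads span only {span:.2f} decades; need >= 2")

    have_K = cond is not None and len(cond) > 0
    n_theta, n_K = len(ret), (len(cond) if have_K else 0)
    lam = (
        config.lambda_K
        if config.lambda_K is not None
        else ((config.sigma_theta / config.sigma_logK) ** 2 if have_K else 0.0)
    )
    sqrt_lam = math.sqrt(lam) if have_K else 0.0

    # free parameter list: drop fixed ones; drop K-only ones without K data
    fixed = dict(config.fixed)
    names = [n for n in _BOUND_NAMES if n not in fixed]
    if not have_K:
        names = [n for n in names if n not in ("log_Ks", "tau")]
    lo = np.array([config.bounds[n][0] for n in names])
    hi = np.array([config.bounds[n][1] for n in names])

    log_h = None
    if have_K:
        logK_meas = np.log10(cond.K)

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            p = _vector_to_params(x, names, fixed)
        except ValueError:
            return np.full(n_theta + n_K, 1e3)
        r_theta = theta_of_h(ret.h, p) - ret.theta
        if not have_K:
            return r_theta
        with np.errstate(divide="ignore"):
            logK_pred = np.log10(np.maximum(K_of_h(cond.h, p), 1e-300))
        return np.concatenate([r_theta, sqrt_lam * (logK_pred - logK_meas)])

    sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
    starts = qmc.scale(sampler.random(config.n_starts), lo, hi)

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=config.xtol, ftol=config.ftol, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    params = _vector_to_params(best.x, names, fixed).sorted_domains()
    r_theta = rmse(ret.theta, theta_of_h(ret.h, params))
    r_logK = None
    if have_K:
        r_logK = rmse(logK_meas, np.log10(np.maximum(K_of_h(cond.h, params), 1e-300)))
    converged = bool(best.success)
    if not converged:
        logger.warning("fit did not report convergence (status %s)", best.status)
    return FitResult(
        params=params,
        rmse_theta=r_theta,
        rmse_logK=r_logK,
        n_theta=n_theta,
        n_K=n_K,
        converged=converged,
        seed=config.seed,
        cost=float(best.cost),
    )


# -- derived water points ----------------------------------------------------


@dataclass(frozen=True)
class WaterPoints:
    """Standard water-retention summary points.

    Fc: field capacity (theta at pF 1.8) in vol-%; PWP: permanent wilting
    point (theta at pF 4.2) in vol-%; Wa = Fc - PWP; phi: total porosity.
    """

    Fc: float
    PWP: float
    Wa: float
    phi: float


def water_points(
    params: KosugiBimodalParams,
    bulk_density: float,
    particle_density: float = DEFAULT_PARTICLE_DENSITY,
) -> WaterPoints:
    """Field capacity, wilting point, plant-available water and porosity.

    Fc is evaluated at pF 1.8 (h = 10^1.8 cm) and PWP at pF 4.2, both as
    volume percent; porosity phi = 1 - bulk_density/particle_density.
    """
    if not (0.0 < bulk_density < particle_density):
        raise ValueError(
            f"need 0 < bulk density ({bulk_density}) < particle density ({particle_density})"
        )
    fc = 100.0 * theta_of_h(10.0**1.8, params)
    pwp = 100.0 * theta_of_h(10.0**4.2, params)
    return WaterPoints(Fc=fc, PWP=pwp, Wa=fc - pwp, phi=1.0 - bulk_density / particle_density)
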