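"""Synthetic field-trial generator.

Emulates the measurements of a small amendment trial on a silt-loam soil:
a randomized design with control, basalt and lime treatments (three
blocks each) sampled at two depths (1-6 and 15-20 cm).  Per sample it
produces evaporation-method style retention points (near saturation to
about h = 3000 cm) plus dew-point dry-range points toward pF 4.2, a
four-class aggregate fractionation with OC concentrations, a texture
triplet with a matching cumulative particle-size distribution, bulk
density, and a basic soil-chemistry table.

Treatment effects are injected where the analysis should find signal: a
coarse-pore-mode enhancement for lime (and, weaker, for basalt at the
surface) so the structure index responds, pH/Ca shifts in the chemistry,
and a depth gradient in silt-and-clay-fraction OC enrichment (surface
depleted, subsoil enriched).  Everything is a pure function of
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aggregates import AGGREGATE_CLASSES
from .hydraulics import ConductivityDataset, K_of_h, KosugiBimodalParams, RetentionDataset, theta_of_h

__all__ = [
    "TrialDesign",
    "BASE_PARAMS",
    "simulate_retention_dataset",
    "simulate_trial",
]

#: Baseline "true" hydraulic parameters per depth, silt-loam-like: a textural
#: (fine) domain around hm ~ 1500-2500 cm plus a structural (coarse) domain
#: around hm ~ 50-70 cm; saturated contents match porosities of about 0.50
#: at the surface and 0.45 at depth.
BASE_PARAMS = {
    "1-6": KosugiBimodalParams(
        theta_r=0.04, theta_s=0.50, w=0.42, hm1=60.0, sigma1=1.0,
        hm2=2000.0, sigma2=1.5, Ks=150.0, tau=0.5,
    ),
    "15-20": KosugiBimodalParams(
        theta_r=0.04, theta_s=0.45, w=0.36, hm1=70.0, sigma1=1.0,
        hm2=2200.0, sigma2=1.5, Ks=90.0, tau=0.5,
    ),
}


@dataclass(frozen=True)
class TrialDesign:
    """Design and effect sizes of the simulated trial.

    ``coarse_mode_boost`` is added to the coarse-domain weight w of the
    truth parameters (the structural signal the KL index detects);
    ``ph_shift`` and ``ca_shift`` are additive treatment effects on pH
    and on Mehlich-III Ca (mg kg^-1).  Depth multipliers scale surface
    effects for the deeper layer (basalt is incorporated shallowly, lime
    dissolves and moves faster).  Noise: Gaussian sd for theta, lognormal
    sd in log10 for K, coefficient of variation for OC concentrations.
    """

    treatments: tuple = ("control", "basalt", "lime")
    n_blocks: int = 3
    depths: tuple = ("1-6", "15-20")
    seed: int = 0
    theta_noise_sd: float = 0.003
    k_noise_sd_log10: float = 0.1
    oc_cv: float = 0.05
    coarse_mode_boost: dict = field(
        default_factory=lambda: {"control": 0.0, "basalt": 0.05, "lime": 0.12}
    )
    deep_effect_multiplier: dict = field(
        default_factory=lambda: {"control": 1.0, "basalt": 0.3, "lime": 0.8}
    )
    ph_shift: dict = field(
        default_factory=lambda: {"control": 0.0, "basalt": 0.35, "lime": 0.7}
    )
    ca_shift: dict = field(
        default_factory=lambda: {"control": 0.0, "basalt": 900.0, "lime": 1500.0}
    )

    def zero_effects(self) -> "TrialDesign":
        """A copy with all treatment effects removed (null design)."""
        zero = {t: 0.0 for t in self.treatments}
        return replace(
            self,
            coarse_mode_boost=dict(zero),
            ph_shift=dict(zero),
            ca_shift=dict(zero),
        )


def _heads(n_points: int, pf_range: tuple, n_dry: int, dry_pf_max: float) -> np.ndarray:
    n_wet = n_points - n_dry
    if n_wet < 1:
        raise ValueError("n_points must exceed n_dry")
    h_wet = np.logspace(pf_range[0], pf_range[1], n_wet)
    if n_dry == 0:
        return h_wet
    h_dry = np.logspace(pf_range[1] + 0.2, dry_pf_max, n_dry)
    return np.concatenate([h_wet, h_dry])


def simulate_retention_dataset(
    params: KosugiBimodalParams,
    n_points: int = 100,
    noise_sd: float = 0.003,
    seed: int = 0,
    pf_range: tuple = (0.0, 3.5),
    n_dry: int = 3,
    dry_pf_max: float = 4.2,
    with_conductivity: bool = False,
    k_noise_sd_log10: float = 0.1,
    sample_id: str = "",
):
    """Synthetic retention (and optionally conductivity) points from known truth.

    Heads are log-spaced over ``pf_range`` (evaporation-method span) with
    ``n_dry`` extra dry-range points up to ``dry_pf_max`` (dew-point
    measurements); theta gets additive Gaussian noise, K multiplicative
    lognormal noise.  Deterministic under ``seed``.
    """
    if n_points < 9:
        raise ValueError("need at least 9 points")
    if noise_sd < 0:
        raise ValueError("noise sd cannot be negative")
    rng = np.random.default_rng(seed)
    h = _heads(n_points, pf_range, n_dry, dry_pf_max)
    theta = theta_of_h(h, params) + rng.normal(0.0, noise_sd, size=h.size)
    ret = RetentionDataset(h=h, theta=np.clip(theta, 0.0, 1.0), sample_id=sample_id)
    if not with_conductivity:
        return ret
    h_k = np.logspace(0.5, 2.8, max(n_points // 4, 9))
    logk = np.log10(K_of_h(h_k, params)) + rng.normal(0.0, k_noise_sd_log10, size=h_k.size)
    cond = ConductivityDataset(h=h_k, K=10.0**logk, sample_id=sample_id)
    return ret, cond


# aggregate "truth": corrected mass fractions and OC patterns per depth.
_AGG_MASS_FRACTIONS = {"1-6": (0.42, 0.22, 0.24, 0.12), "15-20": (0.30, 0.22, 0.30, 0.18)}
_AGG_SAND_SHARE = (0.22, 0.18, 0.15, 0.0)  # of fraction mass; none measured < 53 um
# E_OC truth per class: surface silt+clay depleted, subsoil enriched
_AGG_EOC = {"1-6": (1.10, 1.00, 0.95, 0.86), "15-20": (0.95, 1.00, 0.98, 1.12)}
_BULK_OC = {"1-6": 15.0, "15-20": 11.0}  # mg g^-1
_BD = {"1-6": 1.31, "15-20": 1.42}  # g cm^-3
_TEXTURE = {"1-6": (24.0, 65.0, 11.0), "15-20": (20.0, 67.0, 13.0)}  # sand/silt/clay %
_CHEM_BASE = {"1-6": {"ph": 5.9, "ca_mg_per_kg": 2600.0, "p_mg_per_kg": 30.0,
                      "k_mg_per_kg": 150.0, "cec_meq_per_100g": 16.0},
              "15-20": {"ph": 6.0, "ca_mg_per_kg": 2500.0, "p_mg_per_kg": 22.0,
                        "k_mg_per_kg": 120.0, "cec_meq_per_100g": 15.0}}


def true_params_for(design: TrialDesign, treatment: str, depth: str) -> KosugiBimodalParams:
    """Truth hydraulic parameters for one treatment x depth cell (no block noise)."""
    base = BASE_PARAMS[depth]
    boost = design.coarse_mode_boost[treatment]
    if depth != design.depths[0]:
        boost *= design.deep_effect_multiplier[treatment]
    return replace(base, w=min(base.w + boost, 0.95))


def simulate_trial(design: TrialDesign) -> dict:
    """Simulate the complete input bundle for one trial realization.

    Returns a dict of tidy DataFrames — ``retention``, ``conductivity``,
    ``texture``, ``particle_size``, ``aggregates``, ``bulk``, ``chemistry``
    — plus ``manifest``: the per-sample truth (hydraulic parameters, seed)
    for recovery tests.  Byte-identical for a fixed design.
    """
    root = np.random.SeedSequence(design.seed)
    ret_rows, cond_rows, tex_rows, psd_rows = [], [], [], []
    agg_rows, bulk_rows, chem_rows = [], [], []
    manifest = {"seed": design.seed, "samples": {}}

    for ti, treatment in enumerate(design.treatments):
        for di, depth in enumerate(design.depths):
            for block in range(1, design.n_blocks + 1):
                sid = f"{treatment}_{depth}_b{block}"
                child = np.random.SeedSequence(
                    entropy=design.seed, spawn_key=(ti, di, block)
                )
                rng = np.random.default_rng(child)
                sub_seed = int(rng.integers(0, 2**31 - 1))

                truth = true_params_for(design, treatment, depth)
                # small block-level variability on the truth
                truth = replace(
                    truth,
                    theta_s=float(np.clip(truth.theta_s + rng.normal(0, 0.01), 0.3, 0.6)),
                    hm1=float(truth.hm1 * np.exp(rng.normal(0, 0.08))),
                    hm2=float(truth.hm2 * np.exp(rng.normal(0, 0.08))),
                )
                ret, cond = simulate_retention_dataset(
                    truth, n_points=60, noise_sd=design.theta_noise_sd, seed=sub_seed,
                    with_conductivity=True, k_noise_sd_log10=design.k_noise_sd_log10,
                    sample_id=sid,
                )
                top, bot = depth.split("-")
                for h, th in zip(ret.h, ret.theta):
                    ret_rows.append(
                        {"sample_id": sid, "depth_cm_top": float(top),
                         "depth_cm_bottom": float(bot), "h_cm": h, "theta": th}
                    )
                for h, k in zip(cond.h, cond.K):
                    cond_rows.append({"sample_id": sid, "h_cm": h, "K_cm_per_d": k})

                sand, silt, clay = _TEXTURE[depth]
                jitter = rng.normal(0, 1.0, size=2)
                sand_s = max(sand + jitter[0], 1.0)
                clay_s = max(clay + jitter[1], 1.0)
                silt_s = 100.0 - sand_s - clay_s
                tex_rows.append(
                    {"sample_id": sid, "treatment": treatment, "depth": depth,
                     "sand": sand_s, "silt": silt_s, "clay": clay_s}
                )
                # cumulative particle-size curve consistent with the triplet
                sizes = np.array([0.2, 2.0, 10.0, 53.0, 200.0, 2000.0])
                cum = np.array([
                    0.3 * clay_s, clay_s, clay_s + 0.45 * silt_s, clay_s + silt_s,
                    clay_s + silt_s + 0.55 * sand_s, 100.0,
                ]) / 100.0
                for s, c in zip(sizes, cum):
                    psd_rows.append(
                        {"sample_id": sid, "size_um": s, "cumulative_mass_fraction": c}
                    )

                bulk_oc = _BULK_OC[depth] * np.exp(rng.normal(0, design.oc_cv))
                mass_frac = np.asarray(_AGG_MASS_FRACTIONS[depth])
                mass_frac = rng.dirichlet(mass_frac * 150.0)  # tight around truth
                input_mass = 10.0
                recovered = input_mass * (1.0 - abs(rng.normal(0.005, 0.003)))
                sand_share = np.asarray(_AGG_SAND_SHARE)
                frac_mass = recovered * mass_frac
                sand_mass = frac_mass * sand_share
                eoc = np.asarray(_AGG_EOC[depth])
                oc = bulk_oc * eoc * np.exp(rng.normal(0, design.oc_cv, size=4))
                for i, cls in enumerate(AGGREGATE_CLASSES):
                    agg_rows.append(
                        {"sample_id": sid, "treatment": treatment, "depth": depth,
                         "class_label": cls, "fraction_mass_g": frac_mass[i],
                         "sand_mass_g": sand_mass[i], "oc_mg_per_g": oc[i],
                         "input_mass_g": input_mass}
                    )
                bulk_rows.append(
                    {"sample_id": sid, "treatment": treatment, "depth": depth,
                     "bulk_oc_mg_per_g": bulk_oc,
                     "bulk_density_g_per_cm3": float(
                         np.clip(_BD[depth] + rng.normal(0, 0.04), 0.9, 1.8)
                     )}
                )
                chem = _CHEM_BASE[depth]
                depth_mult = 1.0 if di == 0 else design.deep_effect_multiplier[treatment]
                chem_rows.append(
                    {"sample_id": sid, "treatment": treatment, "depth": depth,
                     "ph": chem["ph"] + design.ph_shift[treatment] * depth_mult
                           + rng.normal(0, 0.08),
                     "ca_mg_per_kg": chem["ca_mg_per_kg"]
                           + design.ca_shift[treatment] * depth_mult
                           + rng.normal(0, 120.0),
                     "p_mg_per_kg": chem["p_mg_per_kg"] * np.exp(rng.normal(0, 0.10)),
                     "k_mg_per_kg": chem["k_mg_per_kg"] * np.exp(rng.normal(0, 0.10)),
                     "cec_meq_per_100g": chem["cec_meq_per_100g"]
                           + rng.normal(0, 0.5)}
                )
                manifest["samples"][sid] = {
                    "treatment": treatment, "depth": depth, "block": block,
                    "seed": sub_seed,
                    "true_params": {
                        k: getattr(truth, k)
                        for k in ("theta_r", "theta_s", "w", "hm1", "sigma1",
                                  "hm2", "sigma2", "Ks", "tau")
                    },
                }

    return {
        "retention": pd.DataFrame(ret_rows),
        "conductivity": pd.DataFrame(cond_rows),
        "texture": pd.DataFrame(tex_rows),
        "particle_size": pd.DataFrame(psd_rows),
        "aggregates": pd.DataFrame(agg_rows),
        "bulk": pd.DataFrame(bulk_rows),
        "chemistry": pd.DataFrame(chem_rows),
        "manifest": manifest,
    }
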