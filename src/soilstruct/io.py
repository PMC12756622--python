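"""Readers, writers, configuration and the end-to-end pipeline.

All tabular inputs are comma-separated, dot-decimal, UTF-8 CSV with a
mandatory header row.  Heads may be supplied in cm of water or hPa
(converted on read; 1 hPa = 1.0197 cm H2O).  Every numeric output column
carries a units suffix.  The pipeline writes a manifest recording the
configuration, its hash, and package versions, and re-running on
identical inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregates import AGGREGATE_CLASSES, AggregateFractionation, aggregate_table
from .amendment import (
    SIEVE_CLASSES,
    AmendmentSchedule,
    Application,
    basalt_contribution,
    dilution_correct,
    fraction_basalt_contribution,
)
from .hydraulics import (
    ConductivityDataset,
    FitConfig,
    RetentionDataset,
    fit_kosugi_bimodal,
    water_points,
)
from .stats_glue import group_tests, pca_scores
from .structure import (
    DEFAULT_R_MAX_UM,
    DEFAULT_R_MIN_UM,
    ReferenceSoilSpec,
    kl_divergence,
    psd_from_retention,
    reference_psd,
)
from .texture import TextureTriplet, classify_texture

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "read_tables", "write_bundle", "run_pipeline"]

CM_PER_HPA = 1.0197162129779282


_SCHEMAS = {
    "retention": {"sample_id", "depth_cm_top", "depth_cm_bottom", "h_cm", "theta"},
    "conductivity": {"sample_id", "h_cm", "K_cm_per_d"},
    "texture": {"sample_id", "treatment", "depth", "sand", "silt", "clay"},
    "particle_size": {"sample_id", "size_um", "cumulative_mass_fraction"},
    "aggregates": {
        "sample_id", "treatment", "depth", "class_label",
        "fraction_mass_g", "sand_mass_g", "oc_mg_per_g", "input_mass_g",
    },
    "bulk": {"sample_id", "treatment", "depth", "bulk_oc_mg_per_g", "bulk_density_g_per_cm3"},
    "chemistry": {
        "sample_id", "treatment", "depth", "ph", "ca_mg_per_kg",
        "p_mg_per_kg", "k_mg_per_kg", "cec_meq_per_100g",
    },
}

_KNOWN_CONFIG_KEYS = None  # filled after PipelineConfig definition


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable to/from YAML.

    ``head_units`` applies to the retention and conductivity input files;
    ``psd_normalized`` selects the normalized pore-size-density convention
    for the structure index; ``packing_factor`` scales particle radius to
    equivalent pore radius when building the reference soil;
    ``dilution_exact_mixing`` switches the dilution correction from the
    first-order (1 + B) form to exact de-mixing 1/(1 - B).
    """

    input_dir: str = "."
    output_dir: str = "results"
    head_units: str = "cm"  # cm | hPa
    r_min_um: float = DEFAULT_R_MIN_UM
    r_max_um: float = DEFAULT_R_MAX_UM
    psd_normalized: bool = True
    packing_factor: float = 0.3
    theta_s_reference: float = 0.30
    particle_density: float = 2.65
    dilution_exact_mixing: bool = False
    amendment_bulk_density: float = 1.4
    incorporation_depth_cm: float = 18.0
    applications: list = field(default_factory=list)  # dicts: year, rate_t_per_ha, rock, grain_fractions
    fit_n_starts: int = 16
    fit_seed: int = 42
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.head_units not in ("cm", "hPa"):
            raise ValueError(f"head_units must be 'cm' or 'hPa', got {cfg.head_units!r}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def schedule(self) -> AmendmentSchedule:
        apps = tuple(
            Application(
                year=int(a["year"]),
                rate_t_per_ha=float(a["rate_t_per_ha"]),
                rock=str(a.get("rock", "")),
                grain_fractions=tuple(float(g) for g in a["grain_fractions"]),
            )
            for a in self.applications
        )
        return AmendmentSchedule(
            applications=apps,
            incorporation_depth_cm=self.incorporation_depth_cm,
            bulk_density=self.amendment_bulk_density,
        )


def write_bundle(bundle: dict, out_dir) -> None:
    """Write a simulate_trial bundle as the CSV/JSON files the readers expect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        if name == "manifest":
            (out / "manifest.json").write_text(json.dumps(df, indent=2), encoding="utf-8")
        else:
            df.to_csv(out / f"{name}.csv", index=False)


def _read_csv(path: Path, name: str, errors: list) -> pd.DataFrame | None:
    if not path.exists():
        errors.append(f"{path}: file not found")
        return None
    df = pd.read_csv(path)
    missing = _SCHEMAS[name] - set(df.columns)
    if missing:
        errors.append(f"{path}: missing columns {sorted(missing)}")
        return None
    return df


def read_tables(config: PipelineConfig) -> dict:
    """Read and validate the full input bundle.

    Heads are converted to cm if supplied in hPa.  All validation problems
    across all files are collected and raised as one consolidated error.
    """
    d = Path(config.input_dir)
    errors: list[str] = []
    tables = {name: _read_csv(d / f"{name}.csv", name, errors) for name in _SCHEMAS}
    if errors:
        raise ValueError("input validation failed:\n  " + "\n  ".join(errors))

    if config.head_units == "hPa":
        tables["retention"]["h_cm"] = tables["retention"]["h_cm"] * CM_PER_HPA
        tables["conductivity"]["h_cm"] = tables["conductivity"]["h_cm"] * CM_PER_HPA

    ret = tables["retention"]
    if (ret["h_cm"] <= 0).any():
        errors.append("retention.csv: non-positive pressure heads")
    if ((ret["theta"] < 0) | (ret["theta"] > 1)).any():
        errors.append("retention.csv: theta outside [0, 1]")
    agg = tables["aggregates"]
    dup = agg.duplicated(["sample_id", "class_label"])
    if dup.any():
        pairs = agg.loc[dup, ["sample_id", "class_label"]].apply(tuple, axis=1).tolist()
        errors.append(f"aggregates.csv: duplicated sample/class rows: {pairs}")
    if (agg["fraction_mass_g"] < 0).any() or (agg["sand_mass_g"] < 0).any():
        errors.append("aggregates.csv: negative masses")
    bad_cls = set(agg["class_label"]) - set(AGGREGATE_CLASSES)
    if bad_cls:
        errors.append(f"aggregates.csv: unknown class labels {sorted(bad_cls)}")
    for sid, grp in tables["particle_size"].groupby("sample_id"):
        if not grp["size_um"].is_monotonic_increasing:
            errors.append(f"particle_size.csv: sizes not ascending for {sid}")
    if errors:
        raise ValueError("input validation failed:\n  " + "\n  ".join(errors))

    ret["pF"] = np.log10(ret["h_cm"])
    return tables


def fractionations_from_tables(tables: dict) -> list:
    """Assemble AggregateFractionation objects from the tidy input tables."""
    bulk = tables["bulk"].set_index("sample_id")
    fracs = []
    for sid, grp in tables["aggregates"].groupby("sample_id"):
        grp = grp.set_index("class_label").loc[list(AGGREGATE_CLASSES)]
        fracs.append(
            AggregateFractionation(
                fraction_mass=grp["fraction_mass_g"].to_numpy(),
                sand_mass=grp["sand_mass_g"].to_numpy(),
                oc_conc=grp["oc_mg_per_g"].to_numpy(),
                bulk_oc=float(bulk.loc[sid, "bulk_oc_mg_per_g"]),
                replicate_id=str(sid),
                treatment=str(grp["treatment"].iloc[0]),
                depth=str(grp["depth"].iloc[0]),
                input_mass_g=float(grp["input_mass_g"].iloc[0]),
            )
        )
    return fracs


def _fit_all(tables: dict, config: PipelineConfig) -> dict:
    """Fit the retention/conductivity model for every sample; keyed by sample_id."""
    fits = {}
    cond_by_sid = dict(tuple(tables["conductivity"].groupby("sample_id")))
    fit_config = FitConfig(n_starts=config.fit_n_starts, seed=config.fit_seed)
    for sid, grp in tables["retention"].groupby("sample_id"):
        ret = RetentionDataset(
            h=grp["h_cm"].to_numpy(), theta=grp["theta"].to_numpy(), sample_id=str(sid)
        )
        cond = None
        if sid in cond_by_sid:
            cg = cond_by_sid[sid]
            cond = ConductivityDataset(
                h=cg["h_cm"].to_numpy(), K=cg["K_cm_per_d"].to_numpy(), sample_id=str(sid)
            )
        fits[str(sid)] = fit_kosugi_bimodal(ret, cond, fit_config)
    return fits


_OUTPUT_FILES = (
    "fits.json", "kld.csv", "aggregates_eoc.csv", "dilution.csv",
    "dilution_corrected_oc.csv", "texture_class.csv", "stats_summary.csv",
    "pca_scores.csv", "pca_loadings.csv", "manifest.json",
)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on the configured input bundle and write results.

    Outputs (all under ``config.output_dir``): ``fits.json`` (per-sample
    hydraulic parameters, RMSEs and derived water points), ``kld.csv``
    (structure index per sample), ``aggregates_eoc.csv``, ``dilution.csv``,
    ``texture_class.csv``, ``stats_summary.csv``, ``pca_scores.csv`` /
    ``pca_loadings.csv`` and ``manifest.json``.  On a stage failure any
    partial outputs of this run are removed before the error propagates.
    """
    out = Path(config.output_dir)
    try:
        return _run_pipeline_stages(config, out)
    except Exception:
        for name in _OUTPUT_FILES:
            (out / name).unlink(missing_ok=True)
        raise


def _run_pipeline_stages(config: PipelineConfig, out: Path) -> Path:
    tables = read_tables(config)
    out.mkdir(parents=True, exist_ok=True)

    meta = tables["bulk"].set_index("sample_id")
    tex = tables["texture"].set_index("sample_id")

    logger.info("fitting retention/conductivity curves")
    fits = _fit_all(tables, config)

    fit_records = {}
    fit_bounds = FitConfig().bounds
    for sid, fr in fits.items():
        bd = float(meta.loc[sid, "bulk_density_g_per_cm3"])
        wp = water_points(fr.params, bd, config.particle_density)
        fit_records[sid] = {
            "bounds": {k: list(v) for k, v in fit_bounds.items()},
            "params": {k: float(getattr(fr.params, k)) for k in (
                "theta_r", "theta_s", "w", "hm1", "sigma1", "hm2", "sigma2", "Ks", "tau")},
            "rmse_theta": fr.rmse_theta,
            "rmse_logK": fr.rmse_logK,
            "n_theta": fr.n_theta,
            "n_K": fr.n_K,
            "converged": fr.converged,
            "seed": fr.seed,
            "Fc_vol_pct": wp.Fc, "PWP_vol_pct": wp.PWP,
            "Wa_vol_pct": wp.Wa, "porosity": wp.phi,
        }
    (out / "fits.json").write_text(json.dumps(fit_records, indent=2, sort_keys=True))

    logger.info("computing structure index")
    kld_rows = []
    convention = "normalized" if config.psd_normalized else "water_content"
    psd_by_sid = dict(tuple(tables["particle_size"].groupby("sample_id")))
    for sid, fr in fits.items():
        p = psd_from_retention(
            fr.params, config.r_min_um, config.r_max_um, convention=convention
        )
        pg = psd_by_sid[sid]
        spec = ReferenceSoilSpec(
            size_um=pg["size_um"].to_numpy(),
            cum_mass_fraction=pg["cumulative_mass_fraction"].to_numpy(),
            theta_r_fixed=float(fr.params.theta_r),
            theta_s_ref=config.theta_s_reference,
            packing_factor=config.packing_factor,
        )
        q, _ = reference_psd(
            spec, FitConfig(n_starts=config.fit_n_starts, seed=config.fit_seed),
            r_min=config.r_min_um, r_max=config.r_max_um, convention=convention,
        )
        kld = kl_divergence(p, q, config.r_min_um, config.r_max_um)
        kld_rows.append(
            {"sample_id": sid,
             "treatment": str(tex.loc[sid, "treatment"]),
             "depth": str(tex.loc[sid, "depth"]),
             "kld": kld, "r_min_um": config.r_min_um, "r_max_um": config.r_max_um,
             "psd_kind": "dSe_dr_normalized" if config.psd_normalized else "dtheta_dr"}
        )
    kld_df = pd.DataFrame(kld_rows).sort_values("sample_id").reset_index(drop=True)
    kld_df.to_csv(out / "kld.csv", index=False)

    logger.info("aggregate accounting")
    agg_df = aggregate_table(fractionations_from_tables(tables))
    agg_df.to_csv(out / "aggregates_eoc.csv", index=False)

    logger.info("dilution mass balance")
    schedule = config.schedule()
    B = basalt_contribution(schedule)
    mean_shares = (
        agg_df.groupby("class_label")["corrected_mass_fraction"].mean()
    )
    shares = (mean_shares / mean_shares.sum()).to_dict()
    per_class = fraction_basalt_contribution(schedule, shares) if schedule.applications else {
        c: 0.0 for c in AGGREGATE_CLASSES
    }
    dil_rows = [{"scope": "bulk", "class_label": "", "B": B}]
    dil_rows += [{"scope": "aggregate_class", "class_label": c, "B": per_class[c]}
                 for c in AGGREGATE_CLASSES]
    dil = pd.DataFrame(dil_rows)
    oc = tables["bulk"][["sample_id", "treatment", "depth", "bulk_oc_mg_per_g"]].copy()
    oc["bulk_oc_corrected_mg_per_g"] = dilution_correct(
        oc["bulk_oc_mg_per_g"].to_numpy(), B, exact_mixing=config.dilution_exact_mixing
    )
    dil.to_csv(out / "dilution.csv", index=False)
    oc.to_csv(out / "dilution_corrected_oc.csv", index=False)

    logger.info("texture classification")
    tex_out = tables["texture"].copy()
    tex_out["texture_class"] = [
        classify_texture(TextureTriplet(r.sand, r.silt, r.clay), abbreviated=True)
        for r in tex_out.itertuples(index=False)
    ]
    tex_out.to_csv(out / "texture_class.csv", index=False)

    logger.info("group statistics")
    chem = tables["chemistry"].merge(
        kld_df[["sample_id", "kld"]], on="sample_id", how="left"
    )
    value_cols = ["ph", "ca_mg_per_kg", "p_mg_per_kg", "k_mg_per_kg",
                  "cec_meq_per_100g", "kld"]
    stat_rows = []
    for depth, sub in chem.groupby("depth"):
        for res in group_tests(sub, value_cols, "treatment", alpha=config.alpha):
            stat_rows.append(
                {"depth": depth, "variable": res.variable,
                 "kruskal_statistic": res.statistic, "p_value": res.p_value,
                 "letters": json.dumps(res.letters, sort_keys=True),
                 "skipped": res.skipped}
            )
    pd.DataFrame(stat_rows).to_csv(out / "stats_summary.csv", index=False)

    chem_complete = chem.dropna(subset=value_cols)
    scores, loadings, evr = pca_scores(chem_complete, value_cols)
    scores.insert(0, "sample_id", chem_complete["sample_id"].to_numpy())
    scores.to_csv(out / "pca_scores.csv", index=False)
    loadings.index.name = "variable"
    loadings.to_csv(out / "pca_loadings.csv")

    manifest = {
        "soilstruct_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_samples": len(fits),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
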