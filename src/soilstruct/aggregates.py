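"""Aggregate-fraction bookkeeping: sand correction, OC contributions, enrichment.

Wet sieving splits a soil sample into four water-stable aggregate size
classes — large macroaggregates (>500 um), small macroaggregates
(250-500 um), large microaggregates (53-250 um) and the silt- and
clay-sized fraction (<53 um).  Because loose sand grains are recovered
with aggregates of their own size, class masses are corrected by
subtracting the per-class sand mass before computing mass fractions.
The relative organic-carbon enrichment of a class is
E_OC = OC_class / OC_bulk; values above one mean the class concentrates
carbon relative to the bulk soil.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AGGREGATE_CLASSES",
    "AggregateFractionation",
    "sand_corrected_fractions",
    "enrichment_factor",
    "oc_contribution",
    "aggregate_table",
]

#: Canonical class labels, coarsest first (sieve tower 500/250/53 um).
AGGREGATE_CLASSES = ("gt500", "250_500", "53_250", "lt53")

#: Tolerated recovered-mass excess over input mass (sieving gain), fractional.
MASS_TOLERANCE = 0.02


@dataclass(frozen=True)
class AggregateFractionation:
    """Masses, sand masses and OC concentrations of the four aggregate classes.

    Arrays are ordered as :data:`AGGREGATE_CLASSES`.  ``sand_mass`` of the
    <53 um class is conventionally zero (no sand correction is measured
    there).  ``input_mass_g``, when given, is used to flag sieving losses.
    """

    fraction_mass: np.ndarray
    sand_mass: np.ndarray
    oc_conc: np.ndarray  # mg g^-1 per class
    bulk_oc: float  # mg g^-1
    replicate_id: str = ""
    depth: str = ""
    treatment: str = ""
    input_mass_g: float | None = None

    def __post_init__(self) -> None:
        fm = np.asarray(self.fraction_mass, dtype=float)
        sm = np.asarray(self.sand_mass, dtype=float)
        oc = np.asarray(self.oc_conc, dtype=float)
        for name, arr in (("fraction_mass", fm), ("sand_mass", sm), ("oc_conc", oc)):
            if arr.shape != (len(AGGREGATE_CLASSES),):
                raise ValueError(f"{name} must have {len(AGGREGATE_CLASSES)} entries")
            if np.any(arr < 0.0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(sm > fm + 1e-12):
            raise ValueError("sand mass cannot exceed fraction mass in any class")
        if self.bulk_oc <= 0.0:
            raise ValueError("bulk OC concentration must be positive")
        if self.input_mass_g is not None:
            recovered = fm.sum()
            if recovered > self.input_mass_g * (1.0 + MASS_TOLERANCE):
                raise ValueError(
                    f"recovered mass {recovered:.3f} g exceeds input "
                    f"{self.input_mass_g:.3f} g beyond tolerance"
                )
            loss = 1.0 - recovered / self.input_mass_g
            if loss > MASS_TOLERANCE:
                logger.warning(
                    "sieving loss of %.1f%% for replicate %r", 100 * loss, self.replicate_id
                )
        object.__setattr__(self, "fraction_mass", fm)
        object.__setattr__(self, "sand_mass", sm)
        object.__setattr__(self, "oc_conc", oc)


def sand_corrected_fractions(f: AggregateFractionation) -> np.ndarray:
    """Sand-corrected mass fractions of the four classes (sum to 1).

    Per-class corrected mass = fraction mass - sand mass, then normalized.
    """
    corrected = f.fraction_mass - f.sand_mass
    total = corrected.sum()
    if total <= 0.0:
        raise ValueError("all sand-corrected masses are zero; nothing to normalize")
    return corrected / total


def enrichment_factor(oc_aggregate: float, oc_bulk: float) -> float:
    """Relative OC enrichment E_OC = OC_aggregate / OC_bulk (both mg g^-1)."""
    if oc_bulk <= 0.0:
        raise ValueError("bulk OC must be positive")
    if oc_aggregate < 0.0:
        raise ValueError("aggregate OC cannot be negative")
    return oc_aggregate / oc_bulk


def oc_contribution(mass_fraction: float, oc_conc: float) -> float:
    """Class contribution to whole-soil OC: mass_fraction x OC, mg g^-1 of bulk soil."""
    if not (0.0 <= mass_fraction <= 1.0):
        raise ValueError(f"mass fraction must lie in [0, 1], got {mass_fraction}")
    return mass_fraction * oc_conc


def aggregate_table(fractionations: list[AggregateFractionation]) -> pd.DataFrame:
    """Tidy per-class results for a set of fractionation replicates.

    Returns one row per (replicate, class) with the sand-corrected mass
    fraction, the OC contribution to bulk soil, and E_OC.  A replicate
    whose mass-weighted OC differs from the measured bulk OC by more than
    15% is flagged in the ``oc_balance_flag`` column (sieving-loss
    diagnostic, not an error).
    """
    rows = []
    for f in fractionations:
        frac = sand_corrected_fractions(f)
        contrib = frac * f.oc_conc
        weighted = float(contrib.sum())
        flag = abs(weighted - f.bulk_oc) / f.bulk_oc > 0.15
        if flag:
            logger.warning(
                "mass-weighted OC %.2f vs bulk %.2f mg/g differs by >15%% "
                "(replicate %r)", weighted, f.bulk_oc, f.replicate_id,
            )
        for i, cls in enumerate(AGGREGATE_CLASSES):
            rows.append(
                {
                    "replicate_id": f.replicate_id,
                    "treatment": f.treatment,
                    "depth": f.depth,
                    "class_label": cls,
                    "corrected_mass_fraction": frac[i],
                    "oc_mg_per_g": f.oc_conc[i],
                    "oc_contribution_mg_per_g": contrib[i],
                    "E_OC": enrichment_factor(f.oc_conc[i], f.bulk_oc),
                    "oc_balance_flag": flag,
                }
            )
    return pd.DataFrame(rows)
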