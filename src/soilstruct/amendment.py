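"""Rock-amendment dilution mass balance.

Crushed basalt spread on a field and plowed in adds mineral mass to the
topsoil.  Elemental concentrations measured afterwards are therefore
diluted relative to the unamended soil.  The basalt contribution

    B = sum(M_basalt) / (M_soil + sum(M_basalt))

is the mass fraction of rock in the amended layer, where M_soil is the
areal soil mass of the incorporation depth.  Measured concentrations are
corrected as C_hat = C (1 + B) (first-order de-dilution, the convention
used in the source accounting), with an exact de-mixing alternative
C_hat = C / (1 - B) available; the two agree to first order in B.

The rock's sieve classes (>600, 250-600, 75-250, <75 um) are mapped onto
the aggregate size classes (>500, 250-500, 53-250, <53 um) to estimate
per-class dilution; the 75 um rock sieve is equalized with the 53 um
aggregate boundary, which adds uncertainty to the finest class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregates import AGGREGATE_CLASSES

__all__ = [
    "SIEVE_CLASSES",
    "SIEVE_TO_AGGREGATE",
    "Application",
    "AmendmentSchedule",
    "soil_mass_areal",
    "basalt_contribution",
    "dilution_correct",
    "fraction_basalt_contribution",
]

#: Rock grain-size sieve classes, coarsest first.
SIEVE_CLASSES = ("gt600", "250_600", "75_250", "lt75")

#: Sieve class -> aggregate class equalization (75 um boundary mapped to 53 um).
SIEVE_TO_AGGREGATE = {
    "gt600": "gt500",
    "250_600": "250_500",
    "75_250": "53_250",
    "lt75": "lt53",
}


@dataclass(frozen=True)
class Application:
    """One field application: year, rate in t ha^-1 and grain-size fractions.

    ``grain_fractions`` are rock mass fractions over :data:`SIEVE_CLASSES`
    and must sum to 1.
    """

    year: int
    rate_t_per_ha: float
    rock: str
    grain_fractions: tuple

    def __post_init__(self) -> None:
        if self.rate_t_per_ha < 0.0:
            raise ValueError("application rate cannot be negative")
        gf = tuple(float(g) for g in self.grain_fractions)
        if len(gf) != len(SIEVE_CLASSES):
            raise ValueError(f"need {len(SIEVE_CLASSES)} grain-size fractions")
        if any(g < 0.0 for g in gf):
            raise ValueError("grain-size fractions cannot be negative")
        if abs(sum(gf) - 1.0) > 1e-6:
            raise ValueError(f"grain-size fractions must sum to 1, got {sum(gf)}")
        object.__setattr__(self, "grain_fractions", gf)


@dataclass(frozen=True)
class AmendmentSchedule:
    """A sequence of rock applications with incorporation depth and bulk density."""

    applications: tuple
    incorporation_depth_cm: float = 18.0
    bulk_density: float = 1.4  # g cm^-3

    def __post_init__(self) -> None:
        if self.incorporation_depth_cm <= 0.0:
            raise ValueError("incorporation depth must be positive")
        if self.bulk_density <= 0.0:
            raise ValueError("bulk density must be positive")
        object.__setattr__(self, "applications", tuple(self.applications))

    @property
    def total_applied_t_per_ha(self) -> float:
        return sum(a.rate_t_per_ha for a in self.applications)


def soil_mass_areal(bulk_density: float, depth_cm: float) -> float:
    """Areal soil mass (t ha^-1) of a layer: BD [g cm^-3] x depth [cm] x 100."""
    if bulk_density <= 0.0 or depth_cm <= 0.0:
        raise ValueError("bulk density and depth must be positive")
    return bulk_density * depth_cm * 100.0


def basalt_contribution(schedule: AmendmentSchedule) -> float:
    """Mass fraction B of applied rock in the amended layer; 0 <= B < 1."""
    m_basalt = schedule.total_applied_t_per_ha
    if m_basalt == 0.0:
        return 0.0
    m_soil = soil_mass_areal(schedule.bulk_density, schedule.incorporation_depth_cm)
    return m_basalt / (m_soil + m_basalt)


def dilution_correct(concentration, B: float, exact_mixing: bool = False):
    """Dilution-corrected concentration.

    Default (printed) mode: C_hat = C (1 + B).  With ``exact_mixing`` the
    exact de-mixing C_hat = C / (1 - B) is used instead; both agree to
    first order in B.  Units follow the input.
    """
    if not (0.0 <= B < 1.0):
        raise ValueError(f"basalt contribution must lie in [0, 1), got {B}")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0.0):
        raise ValueError("concentrations cannot be negative")
    out = c / (1.0 - B) if exact_mixing else c * (1.0 + B)
    return out if out.ndim else float(out)


def fraction_basalt_contribution(
    schedule: AmendmentSchedule,
    soil_class_mass_fractions: dict[str, float],
) -> dict[str, float]:
    """Per-aggregate-class basalt contribution.

    Rock mass is allocated to aggregate classes through the sieve-class
    mapping; each class's B is that class's rock mass over its amended
    (soil + rock) mass, with the soil's class masses given by
    ``soil_class_mass_fractions`` (fractions of the bulk soil mass over
    :data:`AGGREGATE_CLASSES`, summing to 1).  Weighting per-class B by
    amended class mass recovers the bulk B exactly.
    """
    missing = set(AGGREGATE_CLASSES) - set(soil_class_mass_fractions)
    if missing:
        raise ValueError(f"missing soil mass fractions for classes: {sorted(missing)}")
    shares = np.array([soil_class_mass_fractions[c] for c in AGGREGATE_CLASSES])
    if np.any(shares < 0.0) or abs(shares.sum() - 1.0) > 1e-6:
        raise ValueError("soil class mass fractions must be non-negative and sum to 1")

    m_soil = soil_mass_areal(schedule.bulk_density, schedule.incorporation_depth_cm)
    rock_per_class = dict.fromkeys(AGGREGATE_CLASSES, 0.0)
    for app in schedule.applications:
        for sieve, frac in zip(SIEVE_CLASSES, app.grain_fractions):
            agg = SIEVE_TO_AGGREGATE.get(sieve)
            if agg is None:  # pragma: no cover - mapping is total by construction
                raise ValueError(f"sieve class {sieve!r} has no aggregate mapping")
            rock_per_class[agg] += app.rate_t_per_ha * frac

    out = {}
    for cls, share in zip(AGGREGATE_CLASSES, shares):
        m_rock = rock_per_class[cls]
        denom = share * m_soil + m_rock
        out[cls] = 0.0 if denom == 0.0 else m_rock / denom
    return out
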