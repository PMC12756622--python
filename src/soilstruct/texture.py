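"""Soil texture classification on the 12-class USDA/FAO triangle.

A texture triplet (sand, silt, clay percent of fine earth) is assigned to
exactly one of the twelve classes of the texture triangle.  Class
boundaries follow the standard USDA definitions with half-open
conventions (lower bounds inclusive) so the partition of the simplex is
exact: every valid triplet maps to one and only one class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = ["TextureTriplet", "classify_texture", "TEXTURE_CLASSES"]

TEXTURE_CLASSES = (
    "Sand",
    "Loamy sand",
    "Sandy loam",
    "Loam",
    "Silt loam",
    "Silt",
    "Sandy clay loam",
    "Clay loam",
    "Silty clay loam",
    "Sandy clay",
    "Silty clay",
    "Clay",
)

#: Short FAO-style abbreviations.
ABBREVIATIONS = {
    "Sand": "S",
    "Loamy sand": "LS",
    "Sandy loam": "SL",
    "Loam": "L",
    "Silt loam": "SiL",
    "Silt": "Si",
    "Sandy clay loam": "SCL",
    "Clay loam": "CL",
    "Silty clay loam": "SiCL",
    "Sandy clay": "SC",
    "Silty clay": "SiC",
    "Clay": "C",
}

_SUM_TOLERANCE = 0.5


@dataclass(frozen=True)
class TextureTriplet:
    """Sand/silt/clay percentages; renormalized to 100 if within +/-0.5."""

    sand: float
    silt: float
    clay: float

    def __post_init__(self) -> None:
        for name in ("sand", "silt", "clay"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} percentage cannot be negative")
        total = self.sand + self.silt + self.clay
        if abs(total - 100.0) > _SUM_TOLERANCE:
            raise ValueError(f"sand+silt+clay = {total}; must equal 100 +/- {_SUM_TOLERANCE}")
        if total != 100.0:
            logger.info("renormalizing texture triplet summing to %.2f", total)
            scale = 100.0 / total
            object.__setattr__(self, "sand", self.sand * scale)
            object.__setattr__(self, "silt", self.silt * scale)
            object.__setattr__(self, "clay", self.clay * scale)


def classify_texture(t: TextureTriplet, abbreviated: bool = False) -> str:
    """Texture class of a sand/silt/clay triplet on the 12-class triangle.

    Boundary conventions are half-open with lower bounds inclusive, so
    every point of the simplex falls in exactly one class.
    """
    sand, silt, clay = t.sand, t.silt, t.clay
    if silt + 1.5 * clay < 15.0:
        name = "Sand"
    elif silt + 2.0 * clay < 30.0:
        name = "Loamy sand"
    elif clay >= 40.0 and silt >= 40.0:
        name = "Silty clay"
    elif clay >= 35.0 and sand > 45.0:
        name = "Sandy clay"
    elif clay >= 40.0:
        name = "Clay"
    elif clay >= 27.0 and sand <= 20.0:
        name = "Silty clay loam"
    elif clay >= 27.0 and sand <= 45.0:
        name = "Clay loam"
    elif clay >= 20.0 and sand > 45.0 and silt < 28.0:
        name = "Sandy clay loam"
    elif silt >= 80.0 and clay < 12.0:
        name = "Silt"
    elif silt >= 50.0 and (clay >= 12.0 or silt < 80.0):
        name = "Silt loam"
    elif clay >= 7.0 and silt >= 28.0 and sand <= 52.0:
        name = "Loam"
    else:
        name = "Sandy loam"
    return ABBREVIATIONS[name] if abbreviated else name
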