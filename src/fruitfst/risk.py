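"""Sunburn-risk classification from fruit surface temperature.

Two heat-driven sunburn types are distinguished by peel temperature:
sunburn browning (peel discoloration) sets in between 46 and 49 degC, and
sunburn necrosis (thermal death of epidermal cells) at about 52 +/- 1
degC.  The unnamed 49-52 degC band is classified as browning risk — the
conservative call for a grower-alerting tool.  Photo-oxidative sunburn is
driven by light shock rather than FST alone and is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class RiskClass(str, Enum):
    NONE = "none"
    BROWNING = "browning"
    NECROSIS = "necrosis"


@dataclass(frozen=True)
class RiskThresholds:
    """Physiological FST thresholds, degC.

    necrosis_c uses the central value of the 52 +/- 1 degC onset;
    necrosis_uncertainty_c surfaces the +/- 1 as a reported band, not a
    separate class.  browning_high_c marks the printed upper bound of the
    browning range (informational; classification extends browning up to
    the necrosis threshold).
    """

    browning_low_c: float = 46.0
    browning_high_c: float = 49.0
    necrosis_c: float = 52.0
    necrosis_uncertainty_c: float = 1.0

    def __post_init__(self) -> None:
        if not (self.browning_low_c <= self.browning_high_c <= self.necrosis_c):
            raise ValueError("thresholds must be ordered: browning low <= high <= necrosis")


@dataclass(frozen=True)
class RiskAssessment:
    fst_c: float
    risk_class: RiskClass
    margin_c: float  # degC below the next-higher threshold; 0 at necrosis

    def __post_init__(self) -> None:
        if self.margin_c < 0:
            raise ValueError("margin must be >= 0")


def classify_risk(
    fst_c: float, thresholds: RiskThresholds | None = None
) -> RiskAssessment:
    """Map an FST to a sunburn-risk class, monotone in temperature.

    necrosis at fst >= necrosis_c; browning at browning_low_c <= fst <
    necrosis_c; none below.  margin_c is the headroom to the next-higher
    threshold.
    """
    t = thresholds or RiskThresholds()
    if not math.isfinite(fst_c):
        raise ValueError("fst_c must be finite")
    if fst_c >= t.necrosis_c:
        return RiskAssessment(fst_c, RiskClass.NECROSIS, 0.0)
    if fst_c >= t.browning_low_c:
        return RiskAssessment(fst_c, RiskClass.BROWNING, t.necrosis_c - fst_c)
    return RiskAssessment(fst_c, RiskClass.NONE, t.browning_low_c - fst_c)
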