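"""Pressure-bounded CFR and MRR intervals.

The trans-lesion pressure drop obeys dP = f*Q + s*Q^2 (viscous plus
separation losses). Without knowing f and s individually, the resting and
hyperemic gradients alone still bound the flow ratio CFR = Q_hyp/Q_rest:

* purely quadratic loss (f = 0):  CFR = sqrt(dP_hyp / dP_rest)  -> lower bound
* purely linear loss (s = 0):     CFR = dP_hyp / dP_rest        -> upper bound

Each CFR bound maps to an MRR bound through MRR = CFR * Pa_rest / cPd_hyp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .pressure import CorrectedPressures

CFR_PB_THRESHOLD = 2.0
"""Default abnormality threshold for the pressure-bounded CFR interval."""


@dataclass(frozen=True)
class PBInterval:
    """A pressure-bounded [lower, upper] interval of CFR or MRR.

    ``floored`` marks bounds clamped up to 1.0 (a flow or resistance
    reserve below unity is non-physical under the loss model); ``valid``
    is False when the gradients did not permit a bound at all.
    """

    lower: float
    upper: float
    quantity: Literal["CFR", "MRR"]
    floored: bool = False
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not self.lower <= self.upper:
            raise ValueError(
                f"invalid {self.quantity} interval: lower {self.lower} "
                f"> upper {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


def cfr_pb(cp: CorrectedPressures) -> PBInterval:
    """Pressure-bounded CFR interval from corrected gradients.

    Returns an invalid interval when either gradient is non-positive
    (wedge pressure or hydrostatic over-correction).
    """
    if cp.dP_rest <= 0 or cp.dP_hyp <= 0:
        return PBInterval(math.nan, math.nan, "CFR", valid=False)
    ratio = cp.dP_hyp / cp.dP_rest
    upper = ratio
    lower = math.sqrt(ratio)
    floored = False
    if lower < 1.0:
        lower = 1.0
        floored = True
    if upper < 1.0:
        upper = 1.0
        floored = True
    return PBInterval(lower, upper, "CFR", floored=floored)


def mrr_pb(cp: CorrectedPressures, interval: PBInterval | None = None) -> PBInterval:
    """Pressure-bounded MRR interval: each CFR bound times Pa_rest/cPd_hyp."""
    if interval is None:
        interval = cfr_pb(cp)
    if interval.quantity != "CFR":
        raise ValueError("mrr_pb expects a CFR interval")
    if not interval.valid or cp.cPd_hyp <= 0:
        return PBInterval(math.nan, math.nan, "MRR", valid=False)
    factor = cp.Pa_rest / cp.cPd_hyp
    return PBInterval(
        interval.lower * factor,
        interval.upper * factor,
        "MRR",
        floored=interval.floored,
    )


def classify_cfr_pb(
    interval: PBInterval, threshold: float = CFR_PB_THRESHOLD
) -> Literal["abnormal", "normal", "indeterminate"]:
    """Classify a pressure-bounded CFR interval against a threshold.

    abnormal when both bounds are strictly below the threshold, normal when
    both bounds are at or above it, indeterminate when the interval
    straddles it.
    """
    if not interval.valid:
        raise ValueError("cannot classify an invalid interval")
    if interval.upper < threshold:
        return "abnormal"
    if interval.lower >= threshold:
        return "normal"
    return "indeterminate"


def mrr_from_cfr(cfr: float, cp: CorrectedPressures) -> float:
    """MRR from a CFR value: MRR = CFR * Pa_rest / cPd_hyp.

    Algebraically identical to the form CFR / FFR * (Pa_rest / Pa_hyp),
    since FFR = cPd_hyp / Pa_hyp.
    """
    if cp.cPd_hyp <= 0:
        raise ValueError("cPd_hyp must be > 0 to form an MRR")
    return cfr * cp.Pa_rest / cp.cPd_hyp
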