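"""Raw intracoronary pressure records and hydrostatic correction.

In the supine patient the pressure-wire sensor usually sits above or below
the catheter tip where the system was equalized. The blood column between
the two levels adds (sensor below tip) or removes (sensor above tip)
hydrostatic pressure from the measured distal pressure Pd, while the aortic
reference Pa is unaffected. A sensor elevated by ``h`` centimetres therefore
reads a Pd that is too low by ``0.77 * h`` mmHg, and the correction adds
that amount back:

    cPd = Pd + 0.77 * height_cm        (height_cm > 0: sensor above tip)

FFR and resting Pd/Pa are always formed from the corrected distal pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

MAX_ABS_HEIGHT_CM = 25.0
"""Sanity bound on the sensor-to-tip height difference (cm)."""


@dataclass(frozen=True)
class PressureRecord:
    """Paired resting/hyperemic aortic and distal pressures for one vessel.

    ``height_cm`` is signed: positive means the wire sensor lies *above*
    the catheter tip (typical distal LAD), negative below it (typical LCx).
    """

    vessel_id: str
    Pa_rest: float
    Pd_rest: float
    Pa_hyp: float
    Pd_hyp: float
    height_cm: float = 0.0
    max_abs_height_cm: float = MAX_ABS_HEIGHT_CM

    def __post_init__(self) -> None:
        for name in ("Pa_rest", "Pd_rest", "Pa_hyp", "Pd_hyp"):
            if not getattr(self, name) > 0:
                raise ValueError(
                    f"{self.vessel_id}: pressure {name} must be > 0, "
                    f"got {getattr(self, name)!r}"
                )
        if abs(self.height_cm) >= self.max_abs_height_cm:
            raise ValueError(
                f"{self.vessel_id}: |height_cm| must be < "
                f"{self.max_abs_height_cm} cm, got {self.height_cm}"
            )


@dataclass(frozen=True)
class CorrectedPressures:
    """Hydrostatic-corrected pressures and the basic indices derived from them.

    ``flags`` collects per-record quality issues (e.g. a non-positive
    trans-lesion gradient after correction) without aborting cohort
    processing.
    """

    cPd_rest: float
    cPd_hyp: float
    dP_rest: float
    dP_hyp: float
    FFR: float
    PdPa_rest: float
    Pa_rest: float
    Pa_hyp: float
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def gradients_valid(self) -> bool:
        """True when both corrected gradients are strictly positive."""
        return self.dP_rest > 0 and self.dP_hyp > 0


def hydrostatic_offset(
    height_cm: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Hydrostatic pressure offset in mmHg for a signed height difference.

    Antisymmetric in ``height_cm``; 1 cm of blood column corresponds to
    0.77 mmHg at the default constants.
    """
    return constants.mmhg_per_cm * height_cm


def correct_record(
    record: PressureRecord, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> CorrectedPressures:
    """Apply the hydrostatic correction and compute FFR and resting Pd/Pa.

    The correction is added to the measured distal pressures in both
    states (the same column of blood separates sensor and tip at rest and
    during hyperemia). Non-positive corrected gradients are flagged, not
    fatal: wedge pressures or over-correction make the downstream bound
    arithmetic undefined but should not abort a cohort run.
    """
    offset = hydrostatic_offset(record.height_cm, constants)
    cPd_rest = record.Pd_rest + offset
    cPd_hyp = record.Pd_hyp + offset
    dP_rest = record.Pa_rest - cPd_rest
    dP_hyp = record.Pa_hyp - cPd_hyp

    flags: set[str] = set()
    if dP_rest <= 0:
        flags.add("nonpositive_gradient_rest")
    if dP_hyp <= 0:
        flags.add("nonpositive_gradient_hyp")
    if cPd_hyp <= 0:
        flags.add("nonpositive_cpd_hyp")

    return CorrectedPressures(
        cPd_rest=cPd_rest,
        cPd_hyp=cPd_hyp,
        dP_rest=dP_rest,
        dP_hyp=dP_hyp,
        FFR=cPd_hyp / record.Pa_hyp,
        PdPa_rest=cPd_rest / record.Pa_rest,
        Pa_rest=record.Pa_rest,
        Pa_hyp=record.Pa_hyp,
        flags=frozenset(flags),
    )
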