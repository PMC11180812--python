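"""Vessel-specific hemodynamics from 3D-QCA geometry.

A single-lesion vessel is modelled as three segments in series (proximal,
stenosis, distal), each contributing a Poiseuille viscous pressure loss
linear in flow, plus one separation (expansion) loss at the lesion,
quadratic in flow:

    dP = (f_prox + f_sten + f_dist) * Q + s * Q^2

with

    f = 128 * mu * L / (pi * D^4)                       [per segment]
    s = k_e * (rho / 2) * (1/A_sten - 1/A_ref)^2        [lesion]

Coefficients depend on geometry only, so they are identical at rest and
during hyperemia; the resting and hyperemic flows follow by inverting the
quadratic for the two corrected gradients. From the flows:

    CFR = Q_hyp / Q_rest
    MRR = CFR * Pa_rest / cPd_hyp = R_rest / R_hyp

where R_rest = Pa_rest / Q_rest and R_hyp = cPd_hyp / Q_hyp are the
resting and hyperemic microvascular resistances.

Units at the surface are clinical: mmHg, ml/s, mm. SI conversion is
internal to the coefficient formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .bounds import PBInterval, cfr_pb, mrr_pb
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .pressure import CorrectedPressures

SegmentRole = Literal["proximal", "stenosis", "distal"]

MRR_RATIO_DEGENERATE_TOL = 1e-12

_M3S_PER_MLS = 1e-6  # ml/s -> m^3/s


class HemodynamicsError(ValueError):
    """Geometry or gradient input that the loss model cannot handle."""


@dataclass(frozen=True)
class SegmentGeometry:
    """One vessel segment: role, length and mean lumen diameter (mm)."""

    role: SegmentRole
    length_mm: float
    mean_diameter_mm: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise HemodynamicsError(f"{self.role}: length must be > 0 mm")
        if self.mean_diameter_mm <= 0:
            raise HemodynamicsError(f"{self.role}: diameter must be > 0 mm")


@dataclass(frozen=True)
class VesselGeometry:
    """Three-segment single-lesion geometry from 3D-QCA.

    ``reference_diameter_mm`` is the healthy reference lumen at the lesion;
    when omitted it defaults to the distal segment's mean diameter, which
    is also the reference area used by the separation-loss term.
    ``as_percent`` (percent area stenosis) is computed from the diameters
    when not supplied by the QCA software.
    """

    proximal: SegmentGeometry
    stenosis: SegmentGeometry
    distal: SegmentGeometry
    reference_diameter_mm: float | None = None
    as_percent: float | None = None

    def __post_init__(self) -> None:
        for seg, role in (
            (self.proximal, "proximal"),
            (self.stenosis, "stenosis"),
            (self.distal, "distal"),
        ):
            if seg.role != role:
                raise HemodynamicsError(
                    f"segment in {role} slot has role {seg.role!r}"
                )
        if self.stenosis.mean_diameter_mm > self.ref_diameter_mm * (1 + 1e-12):
            raise HemodynamicsError(
                "stenosis diameter exceeds the reference diameter"
            )
        if self.as_percent is not None and not 0 <= self.as_percent < 100:
            raise HemodynamicsError("as_percent must lie in [0, 100)")

    @property
    def ref_diameter_mm(self) -> float:
        if self.reference_diameter_mm is not None:
            return self.reference_diameter_mm
        return self.distal.mean_diameter_mm

    @property
    def segments(self) -> tuple[SegmentGeometry, SegmentGeometry, SegmentGeometry]:
        return (self.proximal, self.stenosis, self.distal)


@dataclass(frozen=True)
class HemoCoefficients:
    """Viscous (f, mmHg per ml/s) and separation (s, mmHg per (ml/s)^2) losses."""

    f_prox: float
    f_sten: float
    f_dist: float
    s: float

    @property
    def f_total(self) -> float:
        return self.f_prox + self.f_sten + self.f_dist


@dataclass(frozen=True)
class HemoResult:
    """Solved flows, reserves and microvascular resistances for one vessel."""

    Q_rest: float
    Q_hyp: float
    CFR_p3d: float
    MRR_p3d: float
    R_rest: float
    R_hyp: float
    mrr_ratio: float
    coefficients: HemoCoefficients


def area_stenosis_percent(geometry: VesselGeometry) -> float:
    """Percent area stenosis from diameters: (1 - (D_sten/D_ref)^2) * 100."""
    d_ratio = geometry.stenosis.mean_diameter_mm / geometry.ref_diameter_mm
    return (1.0 - d_ratio**2) * 100.0


def _lumen_area_m2(diameter_mm: float) -> float:
    return math.pi * (diameter_mm * 1e-3 / 2.0) ** 2


def viscous_coefficient(
    segment: SegmentGeometry, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Poiseuille loss coefficient of one segment, in mmHg per ml/s."""
    length_m = segment.length_mm * 1e-3
    diameter_m = segment.mean_diameter_mm * 1e-3
    f_si = 128.0 * constants.mu * length_m / (math.pi * diameter_m**4)
    return f_si * _M3S_PER_MLS / constants.pa_per_mmhg


def separation_coefficient(
    geometry: VesselGeometry, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Separation (expansion) loss coefficient, in mmHg per (ml/s)^2.

    Zero when the stenosis area equals the reference area (no lesion).
    """
    a_sten = _lumen_area_m2(geometry.stenosis.mean_diameter_mm)
    a_ref = _lumen_area_m2(geometry.ref_diameter_mm)
    if a_sten > a_ref:
        raise HemodynamicsError("stenosis area exceeds reference area")
    s_si = constants.k_e * (constants.rho / 2.0) * (1.0 / a_sten - 1.0 / a_ref) ** 2
    return s_si * _M3S_PER_MLS**2 / constants.pa_per_mmhg


def loss_coefficients(
    geometry: VesselGeometry, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> HemoCoefficients:
    """All loss coefficients of a vessel, built once from its geometry."""
    return HemoCoefficients(
        f_prox=viscous_coefficient(geometry.proximal, constants),
        f_sten=viscous_coefficient(geometry.stenosis, constants),
        f_dist=viscous_coefficient(geometry.distal, constants),
        s=separation_coefficient(geometry, constants),
    )


def solve_flow(f: float, s: float, dP_net: float) -> float:
    """Invert dP = f*Q + s*Q^2 for the volumetric flow Q (ml/s).

    ``dP_net`` is the hydrostatic-corrected trans-lesion gradient in mmHg.
    The positive root of the quadratic is taken; at s = 0 the analytic
    linear limit Q = dP/f applies.
    """
    if f < 0 or s < 0:
        raise HemodynamicsError("loss coefficients must be non-negative")
    if f == 0 and s == 0:
        raise HemodynamicsError("f and s cannot both be zero")
    if dP_net < 0:
        raise HemodynamicsError(f"corrected gradient must be >= 0, got {dP_net}")
    if s == 0:
        return dP_net / f
    # rationalized root: stable when s*dP << f^2 (no cancellation)
    return 2.0 * dP_net / (f + math.sqrt(f * f + 4.0 * s * dP_net))


def mrr_ratio(
    mrr_p3d: float,
    interval: PBInterval,
    tol: float = MRR_RATIO_DEGENERATE_TOL,
) -> float:
    """Position of the actual MRR inside its pressure-bounded interval.

    0 at the upper bound, 1 at the lower bound; NaN when the interval is
    degenerate (width below ``tol``).
    """
    if interval.quantity != "MRR":
        raise ValueError("mrr_ratio expects an MRR interval")
    if not interval.valid:
        return math.nan
    width = interval.upper - interval.lower
    if width <= tol:
        return math.nan
    return (interval.upper - mrr_p3d) / width


def vessel_hemodynamics(
    geometry: VesselGeometry,
    cp: CorrectedPressures,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    vessel_id: str = "",
) -> HemoResult:
    """Solve the full per-vessel model: flows, CFR, MRR and resistances.

    The loss coefficients are built once from geometry and shared between
    the resting and hyperemic solves (geometry does not change with the
    vasodilator). Requires strictly positive corrected gradients.
    """
    label = f"{vessel_id}: " if vessel_id else ""
    if cp.dP_rest <= 0 or cp.dP_hyp <= 0:
        raise HemodynamicsError(
            f"{label}corrected gradients must be positive "
            f"(dP_rest={cp.dP_rest:.3g}, dP_hyp={cp.dP_hyp:.3g})"
        )
    if cp.cPd_hyp <= 0:
        raise HemodynamicsError(f"{label}corrected cPd_hyp must be positive")
    try:
        coefs = loss_coefficients(geometry, constants)
        q_rest = solve_flow(coefs.f_total, coefs.s, cp.dP_rest)
        q_hyp = solve_flow(coefs.f_total, coefs.s, cp.dP_hyp)
    except HemodynamicsError as err:
        raise HemodynamicsError(f"{label}{err}") from err

    cfr = q_hyp / q_rest
    mrr = cfr * cp.Pa_rest / cp.cPd_hyp
    r_rest = cp.Pa_rest / q_rest
    r_hyp = cp.cPd_hyp / q_hyp

    interval = mrr_pb(cp, cfr_pb(cp))
    ratio = mrr_ratio(mrr, interval) if interval.valid else math.nan

    return HemoResult(
        Q_rest=q_rest,
        Q_hyp=q_hyp,
        CFR_p3d=cfr,
        MRR_p3d=mrr,
        R_rest=r_rest,
        R_hyp=r_hyp,
        mrr_ratio=ratio,
        coefficients=coefs,
    )
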