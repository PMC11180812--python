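"""Synthetic vessel cohorts with known hemodynamic ground truth.

Each vessel is drawn with a three-segment geometry, a resting flow and a
true flow reserve, and its pressure record is produced by evaluating the
forward loss model: the measured distal pressure is the aortic pressure
minus the viscous + separation pressure drop, minus the hydrostatic
offset of the sensor, plus optional Gaussian measurement noise.

    Pd_measured = Pa - (f*Q + s*Q^2) - 0.77 * height_cm + noise

Because truth (flows, CFR, MRR, AS%, height) is recorded before noise,
every downstream stage — hydrostatic correction, pressure bounds, the
3D-geometry flow solve, the prediction models — can be tested for exact
recovery at zero noise and for graceful degradation with noise, without
any clinical data.

Synthetic Doppler velocities are generated from the true flows through a
fixed sensor-site lumen area, so the velocity ratio equals the flow ratio
(the assumption behind a Doppler CFR); a distortion knob breaks that
equality on demand.

Default ranges emulate an intermediate-severity single-lesion cohort:
they land FFR roughly in 0.6-0.95 and CFR in 1.2-4, with height offsets
positive for LAD vessels, negative for LCx and mixed for RCA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .hemo3d import SegmentGeometry, VesselGeometry, loss_coefficients
from .pressure import PressureRecord, hydrostatic_offset

_VESSEL_LABELS = ("LAD", "LCx", "RCA")


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-level simulation settings; ``seed`` is mandatory.

    Ranges are (low, high) uniform draws unless noted. Heights are drawn
    per vessel label: LAD positive (sensor above tip), LCx negative,
    RCA either sign.
    """

    n_vessels: int
    seed: int
    diam_dist_range: tuple[float, float] = (2.2, 3.5)  # mm; also the reference
    prox_taper_range: tuple[float, float] = (1.05, 1.3)  # D_prox / D_dist
    len_prox_range: tuple[float, float] = (15.0, 45.0)  # mm
    len_sten_range: tuple[float, float] = (5.0, 20.0)  # mm
    len_dist_range: tuple[float, float] = (20.0, 60.0)  # mm
    as_percent_range: tuple[float, float] = (30.0, 75.0)
    q_rest_range: tuple[float, float] = (0.7, 1.6)  # ml/s
    cfr_range: tuple[float, float] = (1.3, 3.8)
    pa_rest_mean: float = 95.0  # mmHg, normal draw
    pa_rest_sd: float = 8.0
    pa_hyp_drop_range: tuple[float, float] = (2.0, 8.0)  # mmHg below Pa_rest
    height_lad_range: tuple[float, float] = (3.0, 9.0)  # cm, sensor above tip
    height_lcx_range: tuple[float, float] = (-9.0, -3.0)
    height_rca_range: tuple[float, float] = (-4.0, 4.0)
    noise_sd: float = 0.0  # mmHg, on each measured pressure
    apv_noise_sd: float = 0.0  # cm/s, on each Doppler velocity
    doppler_distortion: float = 0.0  # fractional bias on APV_hyp
    min_true_ffr: float = 0.55  # feasibility floor; infeasible draws resampled
    constants: PhysicalConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")
        for name in (
            "diam_dist_range", "prox_taper_range", "len_prox_range",
            "len_sten_range", "len_dist_range", "as_percent_range",
            "q_rest_range", "cfr_range", "pa_hyp_drop_range",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a non-degenerate (low, high) range")


def _vessel_rng(params: SimulationParams, index: int) -> np.random.Generator:
    # one stream per (seed, vessel): cohorts extend without reshuffling rows
    return np.random.default_rng([params.seed, index])


def _draw_geometry(rng: np.random.Generator, params: SimulationParams) -> VesselGeometry:
    d_dist = rng.uniform(*params.diam_dist_range)
    d_prox = d_dist * rng.uniform(*params.prox_taper_range)
    as_pct = rng.uniform(*params.as_percent_range)
    d_sten = d_dist * math.sqrt(1.0 - as_pct / 100.0)
    return VesselGeometry(
        proximal=SegmentGeometry("proximal", rng.uniform(*params.len_prox_range), d_prox),
        stenosis=SegmentGeometry("stenosis", rng.uniform(*params.len_sten_range), d_sten),
        distal=SegmentGeometry("distal", rng.uniform(*params.len_dist_range), d_dist),
        reference_diameter_mm=d_dist,
        as_percent=as_pct,
    )


def generate_vessel(params: SimulationParams, draw_index: int) -> VesselGeometry:
    """Deterministic geometry draw for vessel ``draw_index`` under ``params``."""
    return _draw_geometry(_vessel_rng(params, draw_index), params)


def simulate_measurement(
    geometry: VesselGeometry,
    true_q_rest: float,
    true_q_hyp: float,
    pa_rest: float,
    pa_hyp: float,
    height_cm: float,
    noise_sd: float,
    rng: np.random.Generator,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    vessel_id: str = "sim",
) -> tuple[PressureRecord, dict[str, float]]:
    """Forward-simulate one pressure record and return it with its truth.

    Raises ValueError when the drawn conditions produce a non-positive
    measured distal pressure (caller should resample).
    """
    if not 0 < true_q_rest <= true_q_hyp:
        raise ValueError("flows must satisfy 0 < Q_rest <= Q_hyp")
    coefs = loss_coefficients(geometry, constants)
    dp_rest = coefs.f_total * true_q_rest + coefs.s * true_q_rest**2
    dp_hyp = coefs.f_total * true_q_hyp + coefs.s * true_q_hyp**2
    offset = hydrostatic_offset(height_cm, constants)

    cpd_hyp_true = pa_hyp - dp_hyp
    truth = {
        "q_rest_true": true_q_rest,
        "q_hyp_true": true_q_hyp,
        "cfr_true": true_q_hyp / true_q_rest,
        "mrr_true": (true_q_hyp / true_q_rest) * pa_rest / cpd_hyp_true,
        "dp_rest_true": dp_rest,
        "dp_hyp_true": dp_hyp,
        "as_percent_true": geometry.as_percent
        if geometry.as_percent is not None
        else math.nan,
        "height_cm_true": height_cm,
    }

    noise = rng.normal(0.0, noise_sd, size=4) if noise_sd > 0 else np.zeros(4)
    pd_rest = pa_rest - dp_rest - offset + noise[0]
    pd_hyp = pa_hyp - dp_hyp - offset + noise[1]
    pa_rest_meas = pa_rest + noise[2]
    pa_hyp_meas = pa_hyp + noise[3]
    if pd_rest <= 0 or pd_hyp <= 0:
        raise ValueError("simulated distal pressure is non-positive; resample")

    record = PressureRecord(
        vessel_id=vessel_id,
        Pa_rest=pa_rest_meas,
        Pd_rest=pd_rest,
        Pa_hyp=pa_hyp_meas,
        Pd_hyp=pd_hyp,
        height_cm=height_cm,
    )
    return record, truth


def _height_range(params: SimulationParams, label: str) -> tuple[float, float]:
    return {
        "LAD": params.height_lad_range,
        "LCx": params.height_lcx_range,
        "RCA": params.height_rca_range,
    }[label]


def generate_cohort(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort table and its ground-truth table.

    Returns ``(cohort, truth)`` DataFrames keyed by ``vessel_id``. The
    cohort carries exactly what a clinical study would export: pressures,
    height offsets, QCA geometry columns and Doppler velocities. At zero
    noise the Doppler CFR equals the true CFR by construction.
    """
    cohort_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(params.n_vessels):
        rng = _vessel_rng(params, i)
        geometry = _draw_geometry(rng, params)
        label = _VESSEL_LABELS[i % len(_VESSEL_LABELS)]
        vessel_id = f"{label}-{i:03d}"

        coefs = loss_coefficients(geometry, params.constants)
        for _attempt in range(200):
            q_rest = rng.uniform(*params.q_rest_range)
            q_hyp = q_rest * rng.uniform(*params.cfr_range)
            pa_rest = float(np.clip(rng.normal(params.pa_rest_mean, params.pa_rest_sd), 70, 130))
            pa_hyp = pa_rest - rng.uniform(*params.pa_hyp_drop_range)
            height = rng.uniform(*_height_range(params, label))
            # feasibility screen: the microvasculature cannot sustain a flow
            # whose stenosis drop leaves (almost) no distal driving pressure
            dp_hyp = coefs.f_total * q_hyp + coefs.s * q_hyp**2
            if (pa_hyp - dp_hyp) / pa_hyp < params.min_true_ffr:
                continue
            try:
                record, truth = simulate_measurement(
                    geometry, q_rest, q_hyp, pa_rest, pa_hyp, height,
                    params.noise_sd, rng, params.constants, vessel_id,
                )
            except ValueError:
                continue
            break
        else:
            raise RuntimeError(
                f"{vessel_id}: no feasible draw in 200 attempts; "
                "check simulation parameter ranges"
            )

        # Doppler APV from true flow through the sensor-site lumen (distal
        # segment): v [cm/s] = Q [ml/s] / A [cm^2]
        area_cm2 = math.pi * (geometry.distal.mean_diameter_mm / 20.0) ** 2
        apv_rest = q_rest / area_cm2
        apv_hyp = q_hyp / area_cm2 * (1.0 + params.doppler_distortion)
        if params.apv_noise_sd > 0:
            apv_rest += rng.normal(0.0, params.apv_noise_sd)
            apv_hyp += rng.normal(0.0, params.apv_noise_sd)

        cohort_rows.append({
            "vessel_id": vessel_id,
            "Pa_rest": record.Pa_rest,
            "Pd_rest": record.Pd_rest,
            "Pa_hyp": record.Pa_hyp,
            "Pd_hyp": record.Pd_hyp,
            "height_cm": height,
            "len_prox_mm": geometry.proximal.length_mm,
            "diam_prox_mm": geometry.proximal.mean_diameter_mm,
            "len_sten_mm": geometry.stenosis.length_mm,
            "diam_sten_mm": geometry.stenosis.mean_diameter_mm,
            "len_dist_mm": geometry.distal.length_mm,
            "diam_dist_mm": geometry.distal.mean_diameter_mm,
            "ref_diam_mm": geometry.ref_diameter_mm,
            "as_percent": geometry.as_percent,
            "apv_rest": apv_rest,
            "apv_hyp": apv_hyp,
        })
        truth_rows.append({"vessel_id": vessel_id, **truth})

    return pd.DataFrame(cohort_rows), pd.DataFrame(truth_rows)
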