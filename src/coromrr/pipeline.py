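"""The per-cohort computation chain.

Columns are appended in calculation order: hydrostatic-corrected
pressures and basic indices, pressure-bounded CFR/MRR intervals with
their classification, then — when geometry columns are present — the
vessel-specific flow solve (CFR_p-3D, MRR_p-3D, microvascular
resistances, interval position), then — when a coefficient set is given —
the linear and quadratic MRR predictions with the CMD flag, and finally
the Doppler reference MRR when velocities are available. Rows whose
inputs fail a stage are flagged and carried through with NaN results,
never dropped.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from . import bounds, hemo3d, prediction
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .io import has_doppler, has_geometry
from .prediction import PredictionCoefficients
from .pressure import PressureRecord, correct_record

logger = logging.getLogger("coromrr")

_NAN_ROW_HEMO = dict(
    q_rest=math.nan, q_hyp=math.nan, cfr_p3d=math.nan, mrr_p3d=math.nan,
    r_mu_rest=math.nan, r_mu_hyp=math.nan, mrr_ratio=math.nan,
)


def _row_record(row: pd.Series) -> PressureRecord:
    return PressureRecord(
        vessel_id=str(row["vessel_id"]),
        Pa_rest=float(row["Pa_rest"]),
        Pd_rest=float(row["Pd_rest"]),
        Pa_hyp=float(row["Pa_hyp"]),
        Pd_hyp=float(row["Pd_hyp"]),
        height_cm=float(row.get("height_cm", 0.0)),
    )


def _row_geometry(row: pd.Series) -> hemo3d.VesselGeometry:
    ref = row.get("ref_diam_mm")
    as_pct = row.get("as_percent")
    return hemo3d.VesselGeometry(
        proximal=hemo3d.SegmentGeometry(
            "proximal", float(row["len_prox_mm"]), float(row["diam_prox_mm"])),
        stenosis=hemo3d.SegmentGeometry(
            "stenosis", float(row["len_sten_mm"]), float(row["diam_sten_mm"])),
        distal=hemo3d.SegmentGeometry(
            "distal", float(row["len_dist_mm"]), float(row["diam_dist_mm"])),
        reference_diameter_mm=float(ref) if ref is not None and not pd.isna(ref) else None,
        as_percent=float(as_pct) if as_pct is not None and not pd.isna(as_pct) else None,
    )


def run_pipeline(
    cohort: pd.DataFrame,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    coefficients: PredictionCoefficients | None = None,
    cfr_threshold: float = bounds.CFR_PB_THRESHOLD,
    cmd_threshold: float = prediction.CMD_MRR_THRESHOLD,
    use_corrected_pd_for_doppler: bool = True,
) -> pd.DataFrame:
    """Run every applicable stage on a validated cohort table.

    Returns a copy with computed columns appended; the input is not
    mutated, and re-running on the output is idempotent for the computed
    columns. A summary (rows processed / rows flagged) is logged.
    """
    df = cohort.copy()
    if "flags" not in df.columns:
        df["flags"] = ""
    df["flags"] = df["flags"].fillna("").astype(str)

    geometry_available = has_geometry(df)
    doppler_available = has_doppler(df)

    results: list[dict] = []
    for _, row in df.iterrows():
        out: dict = {}
        row_flags: list[str] = []
        if row["flags"]:
            row_flags.extend(f for f in row["flags"].split(";") if f)

        try:
            record = _row_record(row)
        except (ValueError, TypeError) as err:
            logger.debug("row %s unusable: %s", row.get("vessel_id"), err)
            results.append({"flags": ";".join(dict.fromkeys(row_flags + ["bad_pressures"]))})
            continue

        cp = correct_record(record, constants)
        row_flags.extend(sorted(cp.flags))
        out.update(
            cpd_rest=cp.cPd_rest, cpd_hyp=cp.cPd_hyp,
            dp_rest=cp.dP_rest, dp_hyp=cp.dP_hyp,
            ffr=cp.FFR, pdpa_rest=cp.PdPa_rest,
        )

        cfr_iv = bounds.cfr_pb(cp)
        mrr_iv = bounds.mrr_pb(cp, cfr_iv)
        out.update(
            cfr_pb_min=cfr_iv.lower, cfr_pb_max=cfr_iv.upper,
            mrr_pb_min=mrr_iv.lower, mrr_pb_max=mrr_iv.upper,
            cfr_pb_class=bounds.classify_cfr_pb(cfr_iv, cfr_threshold)
            if cfr_iv.valid else "invalid",
        )
        if cfr_iv.valid and cfr_iv.floored:
            row_flags.append("bounds_floored")
        if not cfr_iv.valid:
            row_flags.append("bounds_invalid")

        if geometry_available:
            out.update(_NAN_ROW_HEMO)
            try:
                geometry = _row_geometry(row)
                hemo = hemo3d.vessel_hemodynamics(
                    geometry, cp, constants, vessel_id=record.vessel_id)
            except (hemo3d.HemodynamicsError, ValueError, TypeError) as err:
                logger.debug("hemodynamics failed for %s: %s", record.vessel_id, err)
                row_flags.append("hemo_failed")
            else:
                out.update(
                    q_rest=hemo.Q_rest, q_hyp=hemo.Q_hyp,
                    cfr_p3d=hemo.CFR_p3d, mrr_p3d=hemo.MRR_p3d,
                    r_mu_rest=hemo.R_rest, r_mu_hyp=hemo.R_hyp,
                    mrr_ratio=hemo.mrr_ratio,
                )
                if "as_percent" not in df.columns or pd.isna(row.get("as_percent")):
                    out["as_percent"] = hemo3d.area_stenosis_percent(geometry)

        if coefficients is not None and mrr_iv.valid:
            out["mrr_pl"] = prediction.predict_mrr_linear(mrr_iv.upper, coefficients)
            as_pct = out.get("as_percent", row.get("as_percent"))
            if as_pct is not None and not pd.isna(as_pct):
                out["mrr_pq"] = prediction.predict_mrr_quadratic(
                    mrr_iv.lower, mrr_iv.upper, float(as_pct), coefficients)
            else:
                # no stenosis quantitation: fall back to the pressure-only model
                out["mrr_pq"] = out["mrr_pl"]
                row_flags.append("mrr_pq_fallback_linear")
            if not math.isnan(out.get("mrr_p3d", math.nan)):
                out["cmd"] = prediction.classify_cmd(out["mrr_p3d"], cmd_threshold)

        if doppler_available and not pd.isna(row.get("apv_rest")) and not pd.isna(row.get("apv_hyp")):
            try:
                doppler = prediction.DopplerRecord(float(row["apv_rest"]), float(row["apv_hyp"]))
                pd_hyp = cp.cPd_hyp if use_corrected_pd_for_doppler else record.Pd_hyp
                out["mrr_doppler"] = prediction.mrr_doppler(doppler, cp.Pa_rest, pd_hyp)
            except ValueError:
                row_flags.append("doppler_invalid")

        out["flags"] = ";".join(dict.fromkeys(row_flags))
        results.append(out)

    computed = pd.DataFrame(results, index=df.index)
    for col in computed.columns:
        df[col] = computed[col]

    n_flagged = int((df["flags"] != "").sum())
    logger.info("pipeline: %d rows processed, %d flagged", len(df), n_flagged)
    return df


def derive_coefficients(
    computed: pd.DataFrame,
    base: PredictionCoefficients | None = None,
) -> tuple[PredictionCoefficients, dict]:
    """Re-derive prediction coefficients from a computed derivation cohort.

    Fits the straight line MRRpb_max -> MRR_p-3D and the quadratic
    AS% -> interval position on unflagged rows, returning a fresh
    coefficient set (presets are never mutated) plus fit statistics.
    """
    required = ["mrr_pb_max", "mrr_p3d", "as_percent", "mrr_ratio"]
    missing = [c for c in required if c not in computed.columns]
    if missing:
        raise ValueError(f"cohort lacks computed columns: {missing}")
    ok = computed["flags"].fillna("").eq("")
    for col in required:
        ok &= computed[col].notna()
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("derive: excluding %d flagged/incomplete rows", n_excluded)
    sub = computed.loc[ok]

    lin = prediction.fit_linear(sub["mrr_pb_max"].to_numpy(), sub["mrr_p3d"].to_numpy())
    quad = prediction.fit_quadratic(sub["as_percent"].to_numpy(), sub["mrr_ratio"].to_numpy())

    base = base or PredictionCoefficients()
    coefs = PredictionCoefficients(
        linear_intercept=lin.coefficients[0],
        linear_slope=lin.coefficients[1],
        ratio_a0=quad.coefficients[0],
        ratio_a1=quad.coefficients[1],
        ratio_a2=quad.coefficients[2],
        clamp_ratio=base.clamp_ratio,
    )
    fit_info = {
        "linear": {"r_squared": lin.r_squared, "p_value": lin.p_value, "n": lin.n},
        "quadratic": {"r_squared": quad.r_squared, "p_value": quad.p_value, "n": quad.n},
        "n_excluded": n_excluded,
    }
    return coefs, fit_info


def validate_predictions(computed: pd.DataFrame) -> dict:
    """Correlation and agreement of each predictor against the Doppler MRR."""
    if "mrr_doppler" not in computed.columns:
        raise ValueError("cohort lacks an mrr_doppler column; was Doppler data provided?")
    out: dict = {}
    for pred_col in ("mrr_pl", "mrr_pq"):
        if pred_col not in computed.columns:
            continue
        ok = computed["mrr_doppler"].notna() & computed[pred_col].notna()
        ref = computed.loc[ok, "mrr_doppler"].to_numpy()
        test = computed.loc[ok, pred_col].to_numpy()
        r, p = prediction.pearson(test, ref)
        ba = prediction.bland_altman(ref, test)
        out[pred_col] = {
            "pearson_r": r, "p_value": p, "n": int(ok.sum()),
            "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
        }
    if not out:
        raise ValueError("no prediction columns (mrr_pl/mrr_pq) to validate")
    return out
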