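"""Reverse-calibration fitting and figures of merit.

The reversed calibration varies the heavy SIL standard against a constant
light internal standard, fitting log10(heavy:light area ratio) on
log10(nominal concentration) by unweighted ordinary least squares.  From the
fitted curve the module derives LLOD (blank mean + 3*SD, through the curve),
LLOQ/ULOQ (CV < 20% with back-calculated accuracy 85-115%, relaxed to
80-120% at the LLOQ), linearity (R^2 on the log-log scale), per-level
accuracy/precision tables, transition-ratio specificity QC (30% rule), and a
blank-interference selectivity check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from aquamrm.signal import integrate_peak
from aquamrm.synthetic_data import SimulatedChromatogram

logger = logging.getLogger(__name__)

CV_MAX_PCT = 20.0
ACCURACY_RANGE_PCT = (85.0, 115.0)
ACCURACY_RANGE_LLOQ_PCT = (80.0, 120.0)
TRANSITION_RATIO_MAX_DEV_PCT = 30.0


class ValidationError(ValueError):
    """Fatal input error in assay validation."""


@dataclass(frozen=True)
class CalibrationFit:
    """Unweighted log-log OLS of heavy:light ratio on nominal concentration."""

    peptide_name: str
    slope: float
    intercept: float
    r_squared: float
    levels_used: tuple[float, ...]
    fit_diagnostics: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class FiguresOfMerit:
    peptide_name: str
    llod: float
    lloq: float | None
    uloq: float | None
    linear_range: tuple[float, float] | None
    r_squared: float
    accuracy_by_level: dict[float, float]
    precision_by_level: dict[float, float]
    pass_flags: dict[float, bool]


def fit_reverse_calibration(
    ratios: pd.DataFrame, manifest: pd.DataFrame, peptide_name: str
) -> CalibrationFit:
    """Fit the reversed calibration line for one peptide pair.

    Calibration injections only; blanks are excluded by role.  Non-positive
    ratios at a level are dropped with a warning; fewer than three surviving
    levels is fatal.  R^2 is the squared Pearson correlation of the log-log
    points.
    """
    df = ratios.merge(manifest, on="injection_id")
    df = df[(df["role"] == "calibration") & (df["peptide_pair"] == peptide_name)]
    if df.empty:
        raise ValidationError(f"no calibration injections for {peptide_name!r}")
    bad = df["heavy_to_light"] <= 0
    if bad.any():
        logger.warning(
            "dropping %d non-positive calibration ratio(s) for %s",
            int(bad.sum()),
            peptide_name,
        )
        df = df[~bad]
    levels = sorted(df["nominal_conc_fmol_per_uL"].unique())
    if len(levels) < 3:
        raise ValidationError(
            f"calibration for {peptide_name!r} has {len(levels)} usable levels; >=3 required"
        )
    x = np.log10(df["nominal_conc_fmol_per_uL"].to_numpy(float))
    y = np.log10(df["heavy_to_light"].to_numpy(float))
    res = stats.linregress(x, y)
    diagnostics = pd.DataFrame(
        {
            "injection_id": df["injection_id"].to_numpy(),
            "nominal_conc_fmol_per_uL": df["nominal_conc_fmol_per_uL"].to_numpy(),
            "log10_conc": x,
            "log10_ratio": y,
            "residual": y - (res.intercept + res.slope * x),
        }
    )
    return CalibrationFit(
        peptide_name=peptide_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        levels_used=tuple(levels),
        fit_diagnostics=diagnostics,
    )


def predict_ratio(fit: CalibrationFit, concentration: float) -> float:
    """Expected heavy:light ratio at a nominal concentration."""
    return 10.0 ** (fit.intercept + fit.slope * math.log10(concentration))


def back_calculate(fit: CalibrationFit, ratio: float) -> float:
    """Invert the calibration line: ratio -> concentration (fmol/µL).

    Non-positive ratios are undefined on the log scale; NaN is returned and
    the caller decides how to treat the record.
    """
    if ratio <= 0:
        logger.warning("back-calculation undefined for non-positive ratio %g", ratio)
        return float("nan")
    return 10.0 ** ((math.log10(ratio) - fit.intercept) / fit.slope)


def accuracy_precision_table(
    fit: CalibrationFit, ratios: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Per-level accuracy (% of nominal) and precision (%CV of back-calcs).

    Accuracy is mean back-calculated concentration over nominal x100;
    precision is the sample-SD CV of the back-calculated replicates.  Pass
    flags apply the 85-115% rule (80-120% at a prospective LLOQ) and the
    CV < 20% rule.
    """
    df = ratios.merge(manifest, on="injection_id")
    df = df[(df["role"] == "calibration") & (df["peptide_pair"] == fit.peptide_name)]
    rows = []
    for level, grp in df.groupby("nominal_conc_fmol_per_uL"):
        back = np.array([back_calculate(fit, r) for r in grp["heavy_to_light"]])
        back = back[np.isfinite(back)]
        n = back.size
        mean_back = float(back.mean()) if n else float("nan")
        accuracy = 100.0 * mean_back / level if n else float("nan")
        if n >= 2:
            precision = 100.0 * float(back.std(ddof=1)) / mean_back
        else:
            logger.warning("level %g has <2 replicates: precision undefined", level)
            precision = float("nan")
        acc_ok = ACCURACY_RANGE_PCT[0] <= accuracy <= ACCURACY_RANGE_PCT[1]
        acc_ok_lloq = ACCURACY_RANGE_LLOQ_PCT[0] <= accuracy <= ACCURACY_RANGE_LLOQ_PCT[1]
        cv_ok = (not math.isnan(precision)) and precision < CV_MAX_PCT
        rows.append(
            {
                "nominal_conc_fmol_per_uL": level,
                "n": n,
                "mean_back_calc": mean_back,
                "accuracy_pct": accuracy,
                "precision_cv_pct": precision,
                "pass_accuracy": acc_ok,
                "pass_accuracy_lloq": acc_ok_lloq,
                "pass_cv": cv_ok,
            }
        )
    return pd.DataFrame(rows).sort_values("nominal_conc_fmol_per_uL").reset_index(drop=True)


def estimate_llod(
    blank_ratios: np.ndarray | pd.Series,
    fit: CalibrationFit | None = None,
    mode: str = "mean_plus_3sd",
) -> tuple[float, float]:
    """LLOD from blank injections: mean + 3*SD of the blank signal.

    ``blank_ratios`` are the heavy:light ratios of the blank injections (the
    blank's signal on the calibration axis).  ``mode='3sd'`` drops the mean
    term.  Returns ``(llod_concentration, llod_signal)``; with a fit the
    signal is converted through the curve, otherwise the signal is returned
    for both (useful when the axis is already concentration-equivalent).
    All-zero blanks give an LLOD of 0.
    """
    vals = np.asarray(blank_ratios, dtype=float)
    if vals.size < 3:
        raise ValidationError(f"need >=3 blank injections, got {vals.size}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if mode == "mean_plus_3sd":
        signal = mean + 3.0 * sd
    elif mode == "3sd":
        signal = 3.0 * sd
    else:
        raise ValidationError(f"unknown LLOD mode {mode!r}")
    if signal == 0:
        return 0.0, 0.0
    conc = back_calculate(fit, signal) if fit is not None else signal
    return float(conc), signal


def determine_lloq_uloq(
    level_table: pd.DataFrame,
) -> tuple[float | None, float | None, tuple[float, float] | None]:
    """Apply the quantification-limit rules to the per-level table.

    ULOQ is the highest level passing CV < 20% and accuracy 85-115%; LLOQ is
    the lowest level passing CV < 20% with accuracy 80-120% such that every
    level between it and the ULOQ also passes at 85-115% (contiguity).  A
    non-contiguous pass pattern moves the LLOQ above the last interior
    failure, with a warning.  Returns ``(lloq, uloq, linear_range)`` or
    ``(None, None, None)`` when no level passes.
    """
    tbl = level_table.sort_values("nominal_conc_fmol_per_uL").reset_index(drop=True)
    full_pass = (tbl["pass_accuracy"] & tbl["pass_cv"]).to_numpy()
    lloq_pass = (tbl["pass_accuracy_lloq"] & tbl["pass_cv"]).to_numpy()
    levels = tbl["nominal_conc_fmol_per_uL"].to_numpy(float)
    if not full_pass.any():
        logger.warning("assay fails: no calibration level passes accuracy and CV rules")
        return None, None, None
    uloq_idx = int(np.max(np.nonzero(full_pass)))
    # walk down from the ULOQ while interior levels pass at 85-115%; the
    # terminal (LLOQ) level itself may pass at the relaxed 80-120% rule
    lloq_idx = uloq_idx
    for i in range(uloq_idx - 1, -1, -1):
        if full_pass[i]:
            lloq_idx = i
        elif lloq_pass[i]:
            lloq_idx = i
            break
        else:
            break
    if full_pass[:lloq_idx].any():
        logger.warning("non-contiguous pass pattern; LLOQ set above the last interior failure")
    lloq = float(levels[lloq_idx])
    uloq = float(levels[uloq_idx])
    return lloq, uloq, (lloq, uloq)


def figures_of_merit(
    fit: CalibrationFit,
    ratios: pd.DataFrame,
    manifest: pd.DataFrame,
    llod_mode: str = "mean_plus_3sd",
) -> FiguresOfMerit:
    """Full Table-2-style summary for one peptide pair."""
    tbl = accuracy_precision_table(fit, ratios, manifest)
    blanks = ratios.merge(manifest, on="injection_id")
    blanks = blanks[(blanks["role"] == "blank") & (blanks["peptide_pair"] == fit.peptide_name)]
    llod, _ = estimate_llod(blanks["heavy_to_light"].to_numpy(float), fit, llod_mode)
    lloq, uloq, linear_range = determine_lloq_uloq(tbl)
    return FiguresOfMerit(
        peptide_name=fit.peptide_name,
        llod=llod,
        lloq=lloq,
        uloq=uloq,
        linear_range=linear_range,
        r_squared=fit.r_squared,
        accuracy_by_level=dict(
            zip(tbl["nominal_conc_fmol_per_uL"], tbl["accuracy_pct"])
        ),
        precision_by_level=dict(
            zip(tbl["nominal_conc_fmol_per_uL"], tbl["precision_cv_pct"])
        ),
        pass_flags=dict(
            zip(tbl["nominal_conc_fmol_per_uL"], tbl["pass_accuracy"] & tbl["pass_cv"])
        ),
    )


def transition_ratio_qc(
    peaks: pd.DataFrame,
    manifest: pd.DataFrame,
    lloq: float,
    max_deviation_pct: float = TRANSITION_RATIO_MAX_DEV_PCT,
) -> pd.DataFrame:
    """Specificity QC: percentage peak areas per transition vs their mean.

    Each transition's area is normalized to the total peptide area in its
    injection (percentage areas, summing to 100).  The reference is the mean
    percentage per transition over calibration standards above the LLOQ;
    samples deviating more than ``max_deviation_pct`` from that mean are
    flagged as potential interference.
    """
    df = peaks.merge(manifest, on="injection_id")
    totals = df.groupby(["injection_id", "peptide_name", "label_state"])["area"].transform("sum")
    zero = totals == 0
    if zero.any():
        logger.warning(
            "excluding %d zero-total-area peptide record(s) from transition QC",
            int(df[zero].groupby(["injection_id", "peptide_name", "label_state"]).ngroups),
        )
        df = df[~zero]
        totals = totals[~zero]
    df = df.assign(pct_area=100.0 * df["area"] / totals)
    ref_mask = (df["role"] == "calibration") & (df["nominal_conc_fmol_per_uL"] >= lloq)
    ref = (
        df[ref_mask]
        .groupby(["peptide_name", "label_state", "transition_label"])["pct_area"]
        .mean()
        .rename("ref_pct_area")
    )
    out = df.merge(ref, on=["peptide_name", "label_state", "transition_label"], how="left")
    out["deviation_pct"] = 100.0 * (out["pct_area"] - out["ref_pct_area"]).abs() / out["ref_pct_area"]
    out["flag"] = out["deviation_pct"] > max_deviation_pct
    cols = [
        "injection_id",
        "role",
        "peptide_name",
        "label_state",
        "transition_label",
        "pct_area",
        "ref_pct_area",
        "deviation_pct",
        "flag",
    ]
    return out[cols]


def selectivity_check(
    blank_peaks: pd.DataFrame | None = None,
    blank_traces: list[SimulatedChromatogram] | None = None,
    rt_window: tuple[float, float] | None = None,
    llod_signal_area: float = 0.0,
) -> pd.DataFrame:
    """Interference check in blanks at the analyte retention-time region.

    An automated surrogate for visual blank inspection: a transition fails
    when the blank's integrated area in the analyte window exceeds the LLOD
    signal (expressed in area units).  Accepts either blank peak rows
    (areas already integrated at the analyte RT) or raw traces plus a
    window.
    """
    rows = []
    if blank_traces is not None:
        if rt_window is None:
            raise ValidationError("rt_window required with traces")
        for tr in blank_traces:
            area, _ = integrate_peak(tr, rt_window)
            rows.append(
                {
                    "injection_id": tr.injection_id,
                    "transition_label": tr.transition_label,
                    "blank_area": area,
                }
            )
    elif blank_peaks is not None:
        df = blank_peaks
        if rt_window is not None:
            df = df[
                (df["retention_time"] >= rt_window[0])
                & (df["retention_time"] <= rt_window[1])
            ]
        for r in df.itertuples(index=False):
            rows.append(
                {
                    "injection_id": r.injection_id,
                    "transition_label": r.transition_label,
                    "blank_area": float(r.area),
                }
            )
    else:
        raise ValidationError("provide blank peak rows or blank traces")
    out = pd.DataFrame(rows, columns=["injection_id", "transition_label", "blank_area"])
    out["pass"] = out["blank_area"] <= llod_signal_area
    return out


def write_validation_report(
    out_dir: str | Path,
    fom: FiguresOfMerit,
    level_table: pd.DataFrame,
    qc: pd.DataFrame | None = None,
) -> None:
    """Delimited summary + per-level detail (+ optional transition QC) tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    safe = fom.peptide_name.replace("[", "").replace("]", "").replace("/", "_")
    summary = pd.DataFrame(
        [
            {
                "peptide_name": fom.peptide_name,
                "llod_fmol_per_uL": fom.llod,
                "lloq_fmol_per_uL": fom.lloq,
                "uloq_fmol_per_uL": fom.uloq,
                "linear_range_low": fom.linear_range[0] if fom.linear_range else np.nan,
                "linear_range_high": fom.linear_range[1] if fom.linear_range else np.nan,
                "r_squared": fom.r_squared,
                "accuracy_min_pct": min(fom.accuracy_by_level.values()),
                "accuracy_max_pct": max(fom.accuracy_by_level.values()),
                "precision_max_cv_pct": max(fom.precision_by_level.values()),
            }
        ]
    )
    summary.to_csv(out / f"validation_summary_{safe}.tsv", sep="\t", index=False)
    level_table.to_csv(out / f"validation_levels_{safe}.tsv", sep="\t", index=False)
    if qc is not None:
        qc.to_csv(out / f"transition_ratio_qc_{safe}.tsv", sep="\t", index=False)
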