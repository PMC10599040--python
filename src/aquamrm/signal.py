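"""Peak integration, summed transition areas, and light:heavy ratios.

Peptide-level signal is the sum of its transition peak areas; quantification
compares the light (endogenous) form against the co-eluting heavy SIL
standard within each injection.  Ratios are computed per injection and
statistics taken over injections afterwards, matching how replicate CVs are
reported for this assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from aquamrm.synthetic_data import SimulatedChromatogram

logger = logging.getLogger(__name__)


class SignalError(ValueError):
    """Fatal input error in signal processing."""


@dataclass(frozen=True)
class PeptideArea:
    injection_id: str
    peptide_name: str
    label_state: str
    summed_area: float
    transition_areas: dict[str, float]
    rt_apex: float

    def __post_init__(self) -> None:
        total = sum(self.transition_areas.values())
        if self.summed_area < 0:
            raise SignalError("summed area must be >= 0")
        if abs(self.summed_area - total) > 1e-9 * max(1.0, abs(total)):
            raise SignalError("summed_area inconsistent with transition breakdown")


@dataclass(frozen=True)
class RatioRecord:
    """Directional light/heavy area ratios for one peptide pair in one injection."""

    injection_id: str
    peptide_pair: tuple[str, str]
    light_to_heavy: float
    heavy_to_light: float
    flagged: bool = False  # heavy area zero: ratio undefined, exclude downstream


def integrate_peak(
    trace: SimulatedChromatogram,
    window: tuple[float, float],
    baseline_points: int = 3,
) -> tuple[float, float]:
    """Trapezoidal area above an edge-mean baseline, and the apex time.

    The baseline is the mean intensity of the first and last
    ``baseline_points`` samples of the window; the net area is clipped at 0.
    The apex is the time of maximum 3-point-smoothed intensity.
    """
    start, end = window
    if start >= end:
        raise SignalError(f"empty integration window ({start}, {end})")
    mask = (trace.time >= start) & (trace.time <= end)
    t = trace.time[mask]
    y = trace.intensity[mask]
    if t.size == 0:
        raise SignalError("integration window contains no samples")
    k = min(baseline_points, t.size)
    baseline = float(np.concatenate([y[:k], y[-k:]]).mean())
    area = float(max(np.trapezoid(y - baseline, t), 0.0))
    if y.size >= 3:
        smoothed = np.convolve(y, np.ones(3) / 3.0, mode="same")
    else:
        smoothed = y
    apex = float(t[int(np.argmax(smoothed))])
    return area, apex


def sum_transition_areas(peak_rows: pd.DataFrame) -> PeptideArea:
    """Collapse one injection's transition rows for one peptide form.

    The assay monitors three transitions; fewer is tolerated with a warning,
    duplicates are an error.
    """
    if len(peak_rows) == 0:
        raise SignalError("no transition rows to sum")
    for col in ("injection_id", "peptide_name", "label_state"):
        if peak_rows[col].nunique() != 1:
            raise SignalError(f"peak rows mix multiple values of {col}")
    labels = peak_rows["transition_label"]
    if labels.duplicated().any():
        dup = labels[labels.duplicated()].iloc[0]
        raise SignalError(f"duplicate transition {dup!r} within one injection")
    if len(peak_rows) < 3:
        logger.warning(
            "only %d transition(s) for %s/%s in %s",
            len(peak_rows),
            peak_rows["peptide_name"].iloc[0],
            peak_rows["label_state"].iloc[0],
            peak_rows["injection_id"].iloc[0],
        )
    areas = dict(zip(labels, peak_rows["area"].astype(float)))
    return PeptideArea(
        injection_id=str(peak_rows["injection_id"].iloc[0]),
        peptide_name=str(peak_rows["peptide_name"].iloc[0]),
        label_state=str(peak_rows["label_state"].iloc[0]),
        summed_area=float(sum(areas.values())),
        transition_areas=areas,
        rt_apex=float(peak_rows["retention_time"].median()),
    )


def light_heavy_ratio(light: PeptideArea, heavy: PeptideArea) -> RatioRecord:
    """Both directional ratios; a zero heavy area flags the record instead of inf."""
    if light.injection_id != heavy.injection_id:
        raise SignalError(
            f"injection mismatch: {light.injection_id} vs {heavy.injection_id}"
        )
    if light.peptide_name != heavy.peptide_name:
        raise SignalError(
            f"peptide mismatch: {light.peptide_name} vs {heavy.peptide_name}"
        )
    if light.label_state != "light" or heavy.label_state != "heavy":
        raise SignalError("arguments must be (light, heavy) in that order")
    pair = (f"{light.peptide_name}", f"{light.peptide_name}-heavy")
    if heavy.summed_area == 0:
        logger.warning(
            "zero heavy area for %s in %s: ratio undefined", light.peptide_name,
            light.injection_id,
        )
        return RatioRecord(light.injection_id, pair, float("nan"), float("nan"), flagged=True)
    l2h = light.summed_area / heavy.summed_area
    h2l = heavy.summed_area / light.summed_area if light.summed_area > 0 else float("inf")
    return RatioRecord(light.injection_id, pair, l2h, h2l, flagged=False)


def rt_coherence_check(
    peak_rows: pd.DataFrame, tolerance: float = 0.1
) -> tuple[bool, float]:
    """Co-elution check: max apex spread across transitions vs a tolerance.

    Transitions of one analyte (and its SIL pair, identical sequence) must
    overlap in retention time; a spread beyond ``tolerance`` minutes fails.
    Returns ``(passed, max_spread)``.
    """
    rts = peak_rows["retention_time"].astype(float)
    if len(rts) < 2:
        logger.info("single transition: retention-time coherence trivially passes")
        return True, 0.0
    spread = float(rts.max() - rts.min())
    return spread <= tolerance, spread


def peptide_areas_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Summed areas per injection x peptide x label state (long peak table in)."""
    records = []
    for (inj, pep, state), grp in peaks.groupby(
        ["injection_id", "peptide_name", "label_state"], sort=False
    ):
        pa = sum_transition_areas(grp)
        records.append(
            {
                "injection_id": inj,
                "peptide_name": pep,
                "label_state": state,
                "summed_area": pa.summed_area,
                "rt_apex": pa.rt_apex,
            }
        )
    return pd.DataFrame(records)


def ratios_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Light:heavy and heavy:light ratios per injection and peptide pair.

    Expects both label states of each peptide in each injection; injections
    missing one state are skipped with a warning.  ``qc_flags`` notes
    undefined ratios (zero heavy area).
    """
    areas = peptide_areas_table(peaks)
    wide = areas.pivot_table(
        index=["injection_id", "peptide_name"],
        columns="label_state",
        values="summed_area",
        aggfunc="first",
    )
    rows = []
    for (inj, pep), r in wide.iterrows():
        light = r.get("light", np.nan)
        heavy = r.get("heavy", np.nan)
        if np.isnan(light) or np.isnan(heavy):
            logger.warning("injection %s lacks a label state for %s; skipped", inj, pep)
            continue
        flagged = heavy == 0
        rows.append(
            {
                "injection_id": inj,
                "peptide_pair": pep,
                "light_to_heavy": light / heavy if not flagged else np.nan,
                "heavy_to_light": heavy / light if light > 0 else np.inf,
                "flagged": bool(flagged),
                "qc_flags": "zero_heavy" if flagged else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "injection_id",
            "peptide_pair",
            "light_to_heavy",
            "heavy_to_light",
            "flagged",
            "qc_flags",
        ],
    )
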