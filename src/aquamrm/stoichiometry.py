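"""Absolute abundances, K14ac stoichiometry, and condition comparisons.

The endogenous (light) peptide abundance follows from its light:heavy area
ratio and the known heavy-spike concentration.  Site stoichiometry is the
acetylated fraction of the K14-containing peptide,

    stoichiometry (%) = 100 * mod / (mod + unmod),

computed per technical replicate, averaged replicate -> donor and then
donor -> condition (sample SD and %CV at each tier), with pairwise Welch
unequal-variance t-tests between conditions at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MODIFIED_PEPTIDE = "K9[Poy]K14[Ac]"
UNMODIFIED_PEPTIDE = "K9[Poy]K14[Poy]"
ALPHA = 0.05


class StoichiometryError(ValueError):
    """Fatal input error in stoichiometry computation."""


@dataclass(frozen=True)
class ConditionComparison:
    pair: tuple[str, str]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool


def absolute_abundance(light_to_heavy: float, heavy_spike: float) -> float:
    """Endogenous concentration (fmol/µL) from a light:heavy ratio and spike."""
    if heavy_spike <= 0:
        raise StoichiometryError(f"heavy spike must be positive, got {heavy_spike}")
    if not np.isfinite(light_to_heavy):
        raise StoichiometryError("flagged/undefined ratio cannot be converted")
    return light_to_heavy * heavy_spike


def abundances_table(
    ratios: pd.DataFrame, manifest: pd.DataFrame, heavy_spike: float
) -> pd.DataFrame:
    """Per-injection absolute abundances of the modified/unmodified forms.

    Flagged ratio records (undefined, zero heavy area) are skipped with a
    warning.  Output columns: injection_id, donor_id, condition, replicate,
    peptide_form (modified/unmodified), abundance_fmol_per_uL.
    """
    df = ratios.merge(manifest, on="injection_id")
    df = df[df["role"] == "donor"]
    form_of = {MODIFIED_PEPTIDE: "modified", UNMODIFIED_PEPTIDE: "unmodified"}
    rows = []
    for r in df.itertuples(index=False):
        if r.peptide_pair not in form_of:
            continue
        if getattr(r, "flagged", False) or not np.isfinite(r.light_to_heavy):
            logger.warning(
                "skipping flagged ratio for %s in %s", r.peptide_pair, r.injection_id
            )
            continue
        rows.append(
            {
                "injection_id": r.injection_id,
                "donor_id": r.donor_id,
                "condition": r.condition,
                "replicate": r.replicate,
                "peptide_form": form_of[r.peptide_pair],
                "abundance_fmol_per_uL": absolute_abundance(r.light_to_heavy, heavy_spike),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "injection_id",
            "donor_id",
            "condition",
            "replicate",
            "peptide_form",
            "abundance_fmol_per_uL",
        ],
    )


def stoichiometry_percent(mod_abundance: float, unmod_abundance: float) -> float:
    """Acetylated fraction of the site as a percentage."""
    if mod_abundance < 0 or unmod_abundance < 0:
        raise StoichiometryError("abundances must be non-negative")
    total = mod_abundance + unmod_abundance
    if total == 0:
        logger.warning("both abundances zero: stoichiometry undefined")
        return float("nan")
    return 100.0 * mod_abundance / total


def stoichiometry_table(abundances: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate stoichiometry from the paired modified/unmodified records."""
    wide = abundances.pivot_table(
        index=["injection_id", "donor_id", "condition", "replicate"],
        columns="peptide_form",
        values="abundance_fmol_per_uL",
        aggfunc="first",
    ).reset_index()
    missing = wide["modified"].isna() | wide["unmodified"].isna()
    if missing.any():
        logger.warning("%d injection(s) lack a peptide form; dropped", int(missing.sum()))
        wide = wide[~missing]
    wide["stoichiometry_pct"] = [
        stoichiometry_percent(m, u) for m, u in zip(wide["modified"], wide["unmodified"])
    ]
    undef = wide["stoichiometry_pct"].isna()
    if undef.any():
        logger.warning("excluding %d undefined stoichiometries", int(undef.sum()))
        wide = wide[~undef]
    return wide[
        ["injection_id", "donor_id", "condition", "replicate", "stoichiometry_pct"]
    ].reset_index(drop=True)


def _summarize(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else 0.0
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return mean, sd, cv


def aggregate(stoich: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-tier aggregation: replicates -> donor means, then donors -> condition.

    Returns ``(donor_level, condition_level)`` tables, each with mean, sample
    SD and %CV of the underlying values (technical replicates for the donor
    tier, donor means for the condition tier).
    """
    donor_rows = []
    for (donor, cond), grp in stoich.groupby(["donor_id", "condition"]):
        vals = grp["stoichiometry_pct"].to_numpy(float)
        if vals.size == 0:
            logger.warning("empty group %s/%s omitted", donor, cond)
            continue
        mean, sd, cv = _summarize(vals)
        donor_rows.append(
            {
                "donor_id": donor,
                "condition": cond,
                "n_replicates": vals.size,
                "mean_pct": mean,
                "sd_pct": sd,
                "cv_pct": cv,
            }
        )
    donor_level = pd.DataFrame(donor_rows)
    cond_rows = []
    for cond, grp in donor_level.groupby("condition"):
        vals = grp["mean_pct"].to_numpy(float)
        mean, sd, cv = _summarize(vals)
        cond_rows.append(
            {
                "condition": cond,
                "n_donors": vals.size,
                "mean_pct": mean,
                "sd_pct": sd,
                "cv_pct": cv,
            }
        )
    return donor_level, pd.DataFrame(cond_rows)


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray) -> ConditionComparison:
    """Two-sample unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StoichiometryError("each group needs >=2 values for the Welch test")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ConditionComparison(
        pair=("a", "b"),
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < ALPHA),
    )


def compare_conditions(
    stoich: pd.DataFrame,
    donor_level: pd.DataFrame,
    level: str = "donor",
    conditions: tuple[str, ...] = ("CIC", "CIM", "MIM"),
) -> pd.DataFrame:
    """All pairwise condition comparisons at the chosen analysis level.

    ``level='donor'`` tests, per donor, the technical replicates of one
    condition against another (note the pseudo-replication caveat: technical
    replicates measure instrument variability, not biology).
    ``level='cohort'`` tests the per-donor means across the cohort.
    """
    rows = []
    pairs = list(itertools.combinations(conditions, 2))
    if level == "donor":
        for donor, grp in stoich.groupby("donor_id"):
            for ca, cb in pairs:
                a = grp.loc[grp["condition"] == ca, "stoichiometry_pct"].to_numpy(float)
                b = grp.loc[grp["condition"] == cb, "stoichiometry_pct"].to_numpy(float)
                if a.size < 2 or b.size < 2:
                    logger.warning("%s %s vs %s: not testable (<2 replicates)", donor, ca, cb)
                    continue
                cmp = welch_t_test(a, b)
                rows.append(
                    {
                        "level": "donor",
                        "donor_id": donor,
                        "condition_a": ca,
                        "condition_b": cb,
                        "t_statistic": cmp.t_statistic,
                        "df": cmp.degrees_of_freedom,
                        "p_value": cmp.p_value,
                        "significant": cmp.significant,
                    }
                )
    elif level == "cohort":
        for ca, cb in pairs:
            a = donor_level.loc[donor_level["condition"] == ca, "mean_pct"].to_numpy(float)
            b = donor_level.loc[donor_level["condition"] == cb, "mean_pct"].to_numpy(float)
            if a.size < 2 or b.size < 2:
                logger.warning("cohort %s vs %s: not testable", ca, cb)
                continue
            cmp = welch_t_test(a, b)
            rows.append(
                {
                    "level": "cohort",
                    "donor_id": "",
                    "condition_a": ca,
                    "condition_b": cb,
                    "t_statistic": cmp.t_statistic,
                    "df": cmp.degrees_of_freedom,
                    "p_value": cmp.p_value,
                    "significant": cmp.significant,
                }
            )
    else:
        raise StoichiometryError(f"unknown analysis level {level!r}")
    return pd.DataFrame(
        rows,
        columns=[
            "level",
            "donor_id",
            "condition_a",
            "condition_b",
            "t_statistic",
            "df",
            "p_value",
            "significant",
        ],
    )


def write_results(
    out_dir: str | Path,
    abundances: pd.DataFrame,
    stoich: pd.DataFrame,
    donor_level: pd.DataFrame,
    condition_level: pd.DataFrame,
    comparisons: pd.DataFrame,
) -> None:
    """Write the abundance, stoichiometry, summary and comparison tables.

    The comparison table's donor-level rows rest on technical replicates;
    they quantify measurement repeatability, not donor-level biology.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    abundances.to_csv(out / "abundances.tsv", sep="\t", index=False)
    stoich.to_csv(out / "stoichiometry.tsv", sep="\t", index=False)
    donor_level.to_csv(out / "stoichiometry_by_donor.tsv", sep="\t", index=False)
    condition_level.to_csv(out / "stoichiometry_by_condition.tsv", sep="\t", index=False)
    comparisons.to_csv(out / "condition_comparisons.tsv", sep="\t", index=False)
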