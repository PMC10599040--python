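"""Simulated MRM datasets with the statistical structure the assay assumes.

Emulates every sample role of the study design: a 7-level reversed
calibration ladder (heavy standard varied against a constant 100-fmol light
internal standard), matrix blanks, a mid-range QC, and donor samples (three
exposure conditions, technical triplicates) spiked with heavy standards at
50 fmol/µL.  Peak areas carry multiplicative lognormal noise parameterized
to unit mean, split across the y6/y7/y8 transitions with additional
per-transition noise so that transition-ratio QC has realistic structure.

The generator can emit peak tables directly (fast path) or Gaussian
chromatogram traces for exercising the integrator (slow path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

PEAK_COLUMNS = [
    "injection_id",
    "sample_role",
    "peptide_name",
    "label_state",
    "transition_label",
    "area",
    "retention_time",
]

MANIFEST_COLUMNS = [
    "injection_id",
    "role",
    "nominal_conc_fmol_per_uL",
    "donor_id",
    "condition",
    "replicate",
]

TRUTH_COLUMNS = ["donor_id", "condition", "true_stoichiometry", "total_peptide"]

CONDITIONS = ("CIC", "CIM", "MIM")


class SimulationError(ValueError):
    """Fatal input error in the simulator."""


@dataclass(frozen=True)
class AssayDesign:
    """Injection plan and spike levels of the quantification experiment.

    Defaults are the validated assay's design: calibration at 0.5-2500
    fmol/µL in five replicates, nine matrix blanks, QC at 12.5 fmol/µL,
    100 fmol light internal standard for calibration runs and a 50 fmol/µL
    heavy spike for donor runs.
    """

    calibration_levels: tuple[float, ...] = (0.5, 1.25, 5.0, 50.0, 500.0, 1250.0, 2500.0)
    replicates_per_level: int = 5
    blank_replicates: int = 9
    qc_level: float = 12.5
    qc_replicates: int = 5
    light_is_amount: float = 100.0
    heavy_spike_donor: float = 50.0
    injection_volume: float = 4.0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.calibration_levels):
            raise SimulationError("calibration levels must be positive")
        if list(self.calibration_levels) != sorted(set(self.calibration_levels)):
            raise SimulationError("calibration levels must be strictly increasing")

    @property
    def n_injections(self) -> int:
        """Calibration + blank + QC injections per peptide pair."""
        return (
            len(self.calibration_levels) * self.replicates_per_level
            + self.blank_replicates
            + self.qc_replicates
        )


@dataclass(frozen=True)
class DonorScenario:
    """Ground truth for one donor-condition sample.

    ``true_stoichiometry`` is the acetylated fraction of the K14 site;
    ``total_peptide`` the summed concentration (fmol/µL) of the acetyl and
    propionyl forms of the H3 3-17 peptide.
    """

    donor_id: str
    condition: str
    true_stoichiometry: float
    total_peptide: float
    technical_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.true_stoichiometry < 1.0:
            raise SimulationError(
                f"true stoichiometry must be in (0,1), got {self.true_stoichiometry}"
            )
        if self.total_peptide <= 0:
            raise SimulationError("total peptide concentration must be positive")


def default_transition_fractions() -> dict[str, float]:
    # y7 is the dominant product in this assay family; shares are a design
    # choice, downstream results depend only on their stability.
    return {"y7": 0.45, "y8": 0.35, "y6": 0.20}


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic structure of simulated peak areas and traces.

    ``area_cv`` is the fractional CV of the multiplicative lognormal noise on
    peptide-level areas (the validated assay reports replicate CVs of a few
    percent, hence the 0.05 default).  ``baseline_sd`` is per-point trace
    noise; ``blank_area_sd`` is the scale of baseline-only integrated areas
    in blank injections on the fast path.  The seed is mandatory and is
    recorded in dataset metadata.
    """

    seed: int
    area_cv: float = 0.05
    baseline_sd: float = 1.0
    blank_area_sd: float = 30.0
    rt_mean: float = 12.0
    rt_jitter_sd: float = 0.01
    peak_sigma: float = 0.05
    transition_fractions: dict[str, float] = field(default_factory=default_transition_fractions)
    sampling_interval: float = 0.005

    def __post_init__(self) -> None:
        if self.area_cv < 0:
            raise SimulationError("area_cv must be >= 0")
        if self.peak_sigma <= 0:
            raise SimulationError("peak_sigma must be > 0")
        if abs(sum(self.transition_fractions.values()) - 1.0) > 1e-9:
            raise SimulationError("transition fractions must sum to 1")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(seed=seed, area_cv=0.0, baseline_sd=0.0, blank_area_sd=0.0, rt_jitter_sd=0.0)


@dataclass(frozen=True)
class SimulatedChromatogram:
    """A single-transition trace on a uniform time grid."""

    injection_id: str
    transition_label: str
    time: np.ndarray
    intensity: np.ndarray


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative noise: sigma^2 = ln(1+cv^2), mu = -sigma^2/2."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_chromatogram(
    true_area: float,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
    injection_id: str = "sim",
    transition_label: str = "y7",
    window_sigmas: float = 6.0,
) -> SimulatedChromatogram:
    """One Gaussian elution peak plus baseline noise on a uniform grid.

    The realized area is ``true_area`` times unit-mean lognormal noise; the
    apex sits at ``rt_mean`` plus Normal retention-time jitter.
    """
    if true_area < 0:
        raise SimulationError(f"true_area must be >= 0, got {true_area}")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    realized = float(true_area * _lognormal_factors(rng, noise.area_cv, 1)[0])
    rt = noise.rt_mean + (rng.normal(0.0, noise.rt_jitter_sd) if noise.rt_jitter_sd else 0.0)
    half = window_sigmas * noise.peak_sigma
    n = int(round(2 * half / noise.sampling_interval)) + 1
    t = noise.rt_mean - half + noise.sampling_interval * np.arange(n)
    intensity = realized * np.exp(-0.5 * ((t - rt) / noise.peak_sigma) ** 2) / (
        noise.peak_sigma * math.sqrt(2 * math.pi)
    )
    if noise.baseline_sd > 0:
        intensity = intensity + rng.normal(0.0, noise.baseline_sd, size=n)
    return SimulatedChromatogram(injection_id, transition_label, t, intensity)


def _transition_rows(
    rng: np.random.Generator,
    injection_id: str,
    role: str,
    peptide_name: str,
    label_state: str,
    peptide_area: float,
    rt: float,
    noise: NoiseModel,
) -> list[dict]:
    """Split a noisy peptide-level area across transitions (fast path)."""
    rows = []
    ions = list(noise.transition_fractions.items())
    extra = _lognormal_factors(rng, noise.area_cv / 2.0, len(ions))
    for (ion, frac), f in zip(ions, extra):
        rows.append(
            {
                "injection_id": injection_id,
                "sample_role": role,
                "peptide_name": peptide_name,
                "label_state": label_state,
                "transition_label": ion,
                "area": peptide_area * frac * f,
                "retention_time": rt + (rng.normal(0.0, noise.rt_jitter_sd / 5.0)
                                        if noise.rt_jitter_sd else 0.0),
            }
        )
    return rows


def _blank_rows(
    rng: np.random.Generator,
    injection_id: str,
    role: str,
    peptide_name: str,
    label_state: str,
    rt: float,
    noise: NoiseModel,
) -> list[dict]:
    """Baseline-only areas for a peptide absent from the injection."""
    rows = []
    for ion in noise.transition_fractions:
        area = abs(rng.normal(0.0, noise.blank_area_sd)) if noise.blank_area_sd else 0.0
        rows.append(
            {
                "injection_id": injection_id,
                "sample_role": role,
                "peptide_name": peptide_name,
                "label_state": label_state,
                "transition_label": ion,
                "area": area,
                "retention_time": rt,
            }
        )
    return rows


def _peptide_pair_names(peptide_pairs: Sequence[str] | None) -> list[str]:
    if peptide_pairs is None:
        return ["K9[Poy]K14[Ac]", "K9[Poy]K14[Poy]"]
    return list(peptide_pairs)


def simulate_calibration_series(
    design: AssayDesign,
    response: float,
    noise: NoiseModel,
    peptide_pairs: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the reversed-calibration experiment for each peptide pair.

    Heavy areas scale with the nominal level, light areas with the constant
    internal-standard amount, each with independent multiplicative noise;
    blanks carry baseline-only heavy signal.  Returns ``(peaks, manifest)``.
    """
    if response <= 0:
        raise SimulationError("response must be positive")
    rng = np.random.default_rng(noise.seed)
    pairs = _peptide_pair_names(peptide_pairs)
    peak_rows: list[dict] = []
    manifest_rows: list[dict] = []

    def _injection(injection_id: str, role: str, conc: float, replicate: int) -> None:
        rt = noise.rt_mean + (rng.normal(0.0, noise.rt_jitter_sd) if noise.rt_jitter_sd else 0.0)
        for pep in pairs:
            light_area = response * design.light_is_amount * _lognormal_factors(
                rng, noise.area_cv, 1
            )[0]
            peak_rows.extend(
                _transition_rows(rng, injection_id, role, pep, "light", light_area, rt, noise)
            )
            if conc > 0:
                heavy_area = response * conc * _lognormal_factors(rng, noise.area_cv, 1)[0]
                peak_rows.extend(
                    _transition_rows(rng, injection_id, role, pep, "heavy", heavy_area, rt, noise)
                )
            else:
                peak_rows.extend(_blank_rows(rng, injection_id, role, pep, "heavy", rt, noise))
        manifest_rows.append(
            {
                "injection_id": injection_id,
                "role": role,
                "nominal_conc_fmol_per_uL": conc,
                "donor_id": "",
                "condition": "",
                "replicate": replicate,
            }
        )

    for r in range(1, design.blank_replicates + 1):
        _injection(f"blank_r{r}", "blank", 0.0, r)
    for li, level in enumerate(design.calibration_levels, start=1):
        for r in range(1, design.replicates_per_level + 1):
            _injection(f"cal_L{li}_r{r}", "calibration", level, r)
    for r in range(1, design.qc_replicates + 1):
        _injection(f"qc_r{r}", "qc", design.qc_level, r)

    peaks = pd.DataFrame(peak_rows, columns=PEAK_COLUMNS)
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    return peaks, manifest


def simulate_donor_samples(
    scenarios: Sequence[DonorScenario],
    design: AssayDesign,
    noise: NoiseModel,
    response: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate donor-condition injections spiked with heavy standards.

    The light acetyl form carries ``true_stoichiometry * total_peptide``,
    the light propionyl form the complement; both heavy standards sit at
    ``design.heavy_spike_donor``.  Returns ``(peaks, manifest, truth)`` where
    the ground-truth table enables parameter-recovery tests.
    """
    if not scenarios:
        raise SimulationError("at least one donor scenario required")
    rng = np.random.default_rng(noise.seed)
    peak_rows: list[dict] = []
    manifest_rows: list[dict] = []
    truth_rows: list[dict] = []
    forms = {
        "K9[Poy]K14[Ac]": lambda s: s.true_stoichiometry * s.total_peptide,
        "K9[Poy]K14[Poy]": lambda s: (1.0 - s.true_stoichiometry) * s.total_peptide,
    }
    for sc in scenarios:
        truth_rows.append(
            {
                "donor_id": sc.donor_id,
                "condition": sc.condition,
                "true_stoichiometry": sc.true_stoichiometry,
                "total_peptide": sc.total_peptide,
            }
        )
        for r in range(1, sc.technical_replicates + 1):
            injection_id = f"donor_{sc.donor_id}_{sc.condition}_r{r}"
            rt = noise.rt_mean + (
                rng.normal(0.0, noise.rt_jitter_sd) if noise.rt_jitter_sd else 0.0
            )
            for pep, conc_of in forms.items():
                light_area = response * conc_of(sc) * _lognormal_factors(rng, noise.area_cv, 1)[0]
                heavy_area = response * design.heavy_spike_donor * _lognormal_factors(
                    rng, noise.area_cv, 1
                )[0]
                peak_rows.extend(
                    _transition_rows(rng, injection_id, "donor", pep, "light", light_area, rt, noise)
                )
                peak_rows.extend(
                    _transition_rows(rng, injection_id, "donor", pep, "heavy", heavy_area, rt, noise)
                )
            manifest_rows.append(
                {
                    "injection_id": injection_id,
                    "role": "donor",
                    "nominal_conc_fmol_per_uL": design.heavy_spike_donor,
                    "donor_id": sc.donor_id,
                    "condition": sc.condition,
                    "replicate": r,
                }
            )
    peaks = pd.DataFrame(peak_rows, columns=PEAK_COLUMNS)
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return peaks, manifest, truth


def default_donor_scenarios(
    rng: np.random.Generator | None = None,
    n_donors: int = 6,
    technical_replicates: int = 3,
) -> list[DonorScenario]:
    """Six donors x three conditions with heterogeneous true stoichiometries.

    Baseline acetylation is drawn per donor (2-12%, the low-stoichiometry
    regime typical of histone acetyl marks) with condition shifts of either
    sign, mirroring the donor-divergent responses the assay is built to
    resolve.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    scenarios = []
    for d in range(1, n_donors + 1):
        base = rng.uniform(0.02, 0.12)
        direction = 1.0 if rng.random() < 0.5 else -1.0
        shifts = {"CIC": 0.0, "CIM": direction * base * 0.3, "MIM": direction * base * 0.6}
        total = rng.uniform(100.0, 400.0)
        for cond in CONDITIONS:
            s = min(max(base + shifts[cond], 0.005), 0.95)
            scenarios.append(
                DonorScenario(
                    donor_id=f"D{d:03d}",
                    condition=cond,
                    true_stoichiometry=s,
                    total_peptide=total,
                    technical_replicates=technical_replicates,
                )
            )
    return scenarios


def write_dataset(
    out_dir: str | Path,
    peaks: pd.DataFrame,
    manifest: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    noise: NoiseModel | None = None,
) -> None:
    """Write peaks/manifest (and optional truth) TSVs plus seed metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    if noise is not None:
        meta = {"seed": noise.seed, "area_cv": noise.area_cv}
        (out / "metadata.yaml").write_text(yaml.safe_dump(meta))


def read_peaks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("donor_id", "condition"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df
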