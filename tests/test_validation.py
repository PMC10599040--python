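"""Reverse-calibration fit, limits of detection/quantification, specificity QC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aquamrm import signal as sg
from aquamrm import synthetic_data as sd
from aquamrm import validation as vl

AC = "K9[Poy]K14[Ac]"


def _identity_fit(slope=1.0, intercept=0.0):
    return vl.CalibrationFit(
        peptide_name=AC, slope=slope, intercept=intercept, r_squared=1.0,
        levels_used=(1.0, 10.0, 100.0), fit_diagnostics=None,
    )


def _ratio_frames(backcalcs_by_level):
    """Build ratio + manifest frames whose identity-fit back-calcs are given."""
    rows, man = [], []
    i = 0
    for level, vals in backcalcs_by_level.items():
        for v in vals:
            i += 1
            inj = f"c{i}"
            rows.append({"injection_id": inj, "peptide_pair": AC,
                         "light_to_heavy": 1.0 / v, "heavy_to_light": v, "flagged": False})
            man.append({"injection_id": inj, "role": "calibration",
                        "nominal_conc_fmol_per_uL": level, "donor_id": "",
                        "condition": "", "replicate": 1})
    return pd.DataFrame(rows), pd.DataFrame(man)


class TestCalibrationFit:
    def test_noiseless_fit_is_exact(self, noiseless_calibration):
        peaks, manifest = noiseless_calibration
        ratios = sg.ratios_table(peaks)
        fit = vl.fit_reverse_calibration(ratios, manifest, AC)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(-2.0, abs=1e-12)  # -log10(100 fmol IS)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_low_noise_r_squared_envelope(self, default_design):
        """2% area CV keeps log-log linearity at the validated assay's level."""
        peaks, manifest = sd.simulate_calibration_series(
            default_design, 1000.0, sd.NoiseModel(seed=42, area_cv=0.02)
        )
        ratios = sg.ratios_table(peaks)
        fit = vl.fit_reverse_calibration(ratios, manifest, AC)
        assert fit.r_squared >= 0.9997

    def test_jackknife_stability(self, noisy_calibration):
        """Deleting one replicate per level moves the fit only at noise scale."""
        peaks, manifest = noisy_calibration
        ratios = sg.ratios_table(peaks)
        fit_all = vl.fit_reverse_calibration(ratios, manifest, AC)
        drop = manifest[(manifest["role"] == "calibration") & (manifest["replicate"] == 1)][
            "injection_id"
        ]
        sub = ratios[~ratios["injection_id"].isin(drop)]
        fit_sub = vl.fit_reverse_calibration(sub, manifest, AC)
        assert fit_sub.slope == pytest.approx(fit_all.slope, abs=0.02)
        assert fit_sub.intercept == pytest.approx(fit_all.intercept, abs=0.03)

    def test_too_few_levels_fatal(self):
        ratios, manifest = _ratio_frames({1.0: [1.0], 10.0: [10.0]})
        with pytest.raises(vl.ValidationError):
            vl.fit_reverse_calibration(ratios, manifest, AC)


class TestBackCalculate:
    def test_identity_fit(self):
        assert vl.back_calculate(_identity_fit(), 50.0) == pytest.approx(50.0)

    def test_round_trip_is_identity(self):
        fit = _identity_fit(slope=0.97, intercept=-1.8)
        rng = np.random.default_rng(5)
        for ratio in rng.uniform(1e-3, 1e3, size=50):
            conc = vl.back_calculate(fit, ratio)
            assert vl.predict_ratio(fit, conc) == pytest.approx(ratio, rel=1e-9)

    def test_fitted_points_recover_nominal(self, noiseless_calibration):
        peaks, manifest = noiseless_calibration
        ratios = sg.ratios_table(peaks)
        fit = vl.fit_reverse_calibration(ratios, manifest, AC)
        for level in (0.5, 50.0, 2500.0):
            assert vl.back_calculate(fit, level / 100.0) == pytest.approx(level, rel=1e-9)

    def test_nonpositive_ratio_flagged_nan(self):
        assert np.isnan(vl.back_calculate(_identity_fit(), 0.0))


class TestAccuracyPrecision:
    def test_hand_arithmetic(self):
        ratios, manifest = _ratio_frames({100.0: [95.0, 100.0, 105.0]})
        tbl = vl.accuracy_precision_table(_identity_fit(), ratios, manifest)
        assert tbl.loc[0, "accuracy_pct"] == pytest.approx(100.0)
        assert tbl.loc[0, "precision_cv_pct"] == pytest.approx(5.0)

    def test_noiseless_is_perfect(self, noiseless_calibration):
        peaks, manifest = noiseless_calibration
        ratios = sg.ratios_table(peaks)
        fit = vl.fit_reverse_calibration(ratios, manifest, AC)
        tbl = vl.accuracy_precision_table(fit, ratios, manifest)
        np.testing.assert_allclose(tbl["accuracy_pct"], 100.0, rtol=1e-9)
        np.testing.assert_allclose(tbl["precision_cv_pct"], 0.0, atol=1e-7)

    def test_default_noise_precision_envelope(self, noisy_calibration):
        """5% area CV keeps every level's replicate CV in the validated range."""
        peaks, manifest = noisy_calibration
        ratios = sg.ratios_table(peaks)
        fit = vl.fit_reverse_calibration(ratios, manifest, AC)
        tbl = vl.accuracy_precision_table(fit, ratios, manifest)
        assert (tbl["precision_cv_pct"] < 20.0).all()

    def test_single_replicate_precision_undefined(self):
        ratios, manifest = _ratio_frames({1.0: [1.0], 10.0: [10.0], 100.0: [100.0]})
        tbl = vl.accuracy_precision_table(_identity_fit(), ratios, manifest)
        assert tbl["precision_cv_pct"].isna().all()


class TestLlod:
    def test_all_zero_blanks(self):
        assert vl.estimate_llod(np.zeros(9), _identity_fit())[0] == 0.0

    def test_hand_arithmetic(self):
        conc, signal = vl.estimate_llod(np.array([1.0, 1.0, 1.0, 3.0]), _identity_fit())
        assert signal == pytest.approx(4.5)  # mean 1.5 + 3*SD 1.0
        assert conc == pytest.approx(4.5)

    def test_3sd_mode(self):
        _, signal = vl.estimate_llod(np.array([1.0, 1.0, 1.0, 3.0]), _identity_fit(), mode="3sd")
        assert signal == pytest.approx(3.0)

    def test_scaling_linearity(self):
        blanks = np.array([0.5, 1.0, 1.5, 2.0, 0.8])
        _, s1 = vl.estimate_llod(blanks, None)
        _, s2 = vl.estimate_llod(7.0 * blanks, None)
        assert s2 == pytest.approx(7.0 * s1)

    def test_too_few_blanks_fatal(self):
        with pytest.raises(vl.ValidationError):
            vl.estimate_llod(np.array([1.0, 2.0]), None)


def _level_table(full_pass, lloq_pass, levels=(0.5, 1.25, 5.0, 50.0, 500.0, 1250.0, 2500.0)):
    return pd.DataFrame(
        {
            "nominal_conc_fmol_per_uL": levels,
            "pass_accuracy": full_pass,
            "pass_accuracy_lloq": lloq_pass,
            "pass_cv": [True] * len(levels),
        }
    ).assign(
        pass_accuracy=lambda d: d.pass_accuracy.astype(bool),
        pass_accuracy_lloq=lambda d: d.pass_accuracy_lloq.astype(bool),
    )


def _brute_force_lloq_uloq(full_pass, lloq_pass, levels):
    """Independent statement of the contiguity rule, by enumeration."""
    passing = [i for i, p in enumerate(full_pass) if p]
    if not passing:
        return None, None
    uloq = max(passing)
    candidates = [
        i
        for i in range(uloq + 1)
        if lloq_pass[i] and all(full_pass[j] for j in range(i + 1, uloq + 1))
    ]
    return levels[min(candidates)], levels[uloq]


class TestLloqUloq:
    def test_all_pass(self):
        lloq, uloq, rng = vl.determine_lloq_uloq(_level_table([True] * 7, [True] * 7))
        assert (lloq, uloq) == (0.5, 2500.0)
        assert rng == (0.5, 2500.0)

    def test_lowest_level_fails_cv(self):
        tbl = _level_table([False] + [True] * 6, [False] + [True] * 6)
        lloq, uloq, _ = vl.determine_lloq_uloq(tbl)
        assert (lloq, uloq) == (1.25, 2500.0)

    def test_relaxed_accuracy_extends_down_one_level(self):
        # lowest level passes only the 80-120% rule
        tbl = _level_table([False] + [True] * 6, [True] * 7)
        lloq, _, _ = vl.determine_lloq_uloq(tbl)
        assert lloq == 0.5

    def test_no_passing_level(self):
        assert vl.determine_lloq_uloq(_level_table([False] * 7, [False] * 7)) == (
            None,
            None,
            None,
        )

    def test_all_patterns_match_brute_force(self):
        """Exhaustive check of the contiguity rule over every pass pattern."""
        levels = (0.5, 1.25, 5.0, 50.0, 500.0, 1250.0, 2500.0)
        rng = np.random.default_rng(8)
        for bits in itertools.product([False, True], repeat=7):
            full = list(bits)
            # relaxed-rule passes are a superset of strict passes
            lloq_pass = [f or (rng.random() < 0.3) for f in full]
            expect = _brute_force_lloq_uloq(full, lloq_pass, levels)
            got = vl.determine_lloq_uloq(_level_table(full, lloq_pass))[:2]
            assert got == expect, (full, lloq_pass)


class TestTransitionRatioQC:
    def test_identical_fractions_no_flags(self, noiseless_calibration):
        peaks, manifest = noiseless_calibration
        qc = vl.transition_ratio_qc(peaks, manifest, lloq=0.5)
        cal = qc[qc["role"] == "calibration"]
        np.testing.assert_allclose(cal["deviation_pct"], 0.0, atol=1e-9)
        assert not cal["flag"].any()

    def test_percentage_areas_sum_to_100(self, noisy_calibration):
        peaks, manifest = noisy_calibration
        qc = vl.transition_ratio_qc(peaks, manifest, lloq=0.5)
        sums = qc.groupby(["injection_id", "peptide_name", "label_state"])["pct_area"].sum()
        np.testing.assert_allclose(sums, 100.0, rtol=1e-9)

    def test_doubled_share_is_flagged(self, noiseless_calibration):
        peaks, manifest = noiseless_calibration
        peaks = peaks.copy()
        inj = "cal_L4_r1"
        sel = (
            (peaks.injection_id == inj)
            & (peaks.peptide_name == AC)
            & (peaks.label_state == "heavy")
            & (peaks.transition_label == "y6")
        )
        assert sel.sum() == 1
        peaks.loc[sel, "area"] *= 2.0
        qc = vl.transition_ratio_qc(peaks, manifest, lloq=0.5)
        hit = qc[
            (qc.injection_id == inj)
            & (qc.peptide_name == AC)
            & (qc.label_state == "heavy")
            & (qc.transition_label == "y6")
        ]
        assert hit["deviation_pct"].iloc[0] > 30.0
        assert hit["flag"].all()

    def test_unperturbed_default_noise_unflagged(self, noisy_calibration):
        peaks, manifest = noisy_calibration
        qc = vl.transition_ratio_qc(peaks, manifest, lloq=0.5)
        cal = qc[qc["role"] == "calibration"]
        assert not cal["flag"].any()


class TestSelectivity:
    def test_clean_blanks_pass(self, noiseless_calibration):
        peaks, manifest = noiseless_calibration
        merged = peaks.merge(manifest, on="injection_id")
        blanks = merged[(merged["role"] == "blank") & (merged["label_state"] == "heavy")]
        out = vl.selectivity_check(blank_peaks=blanks, llod_signal_area=0.0)
        assert out["pass"].all()

    def test_interference_in_window_fails(self):
        noise = sd.NoiseModel.noiseless(seed=0)
        spike = sd.simulate_chromatogram(5000.0, noise, injection_id="b1")
        window = (noise.rt_mean - 0.25, noise.rt_mean + 0.25)
        out = vl.selectivity_check(blank_traces=[spike], rt_window=window,
                                   llod_signal_area=100.0)
        assert not out["pass"].any()

    def test_interference_outside_window_passes(self):
        noise = sd.NoiseModel.noiseless(seed=0)
        spike = sd.simulate_chromatogram(5000.0, noise, injection_id="b1")
        window = (noise.rt_mean + 0.5, noise.rt_mean + 1.0)
        # no samples beyond the trace: integrate a shifted clean region instead
        shifted = sd.SimulatedChromatogram(
            "b1", "y7", spike.time + 1.0, np.zeros_like(spike.intensity)
        )
        out = vl.selectivity_check(blank_traces=[shifted], rt_window=window,
                                   llod_signal_area=100.0)
        assert out["pass"].all()


class TestFiguresOfMerit:
    def test_noiseless_summary(self, noiseless_calibration):
        peaks, manifest = noiseless_calibration
        ratios = sg.ratios_table(peaks)
        fit = vl.fit_reverse_calibration(ratios, manifest, AC)
        fom = vl.figures_of_merit(fit, ratios, manifest)
        assert fom.llod == 0.0
        assert fom.lloq == 0.5
        assert fom.uloq == 2500.0
        assert fom.r_squared == pytest.approx(1.0)

    def test_determinism(self, noisy_calibration):
        peaks, manifest = noisy_calibration
        ratios = sg.ratios_table(peaks)
        fit = vl.fit_reverse_calibration(ratios, manifest, AC)
        a = vl.figures_of_merit(fit, ratios, manifest)
        b = vl.figures_of_merit(fit, ratios, manifest)
        assert a == b

    def test_noise_monotonically_degrades_precision(self, default_design):
        """Mean replicate CV (over seeds) does not decrease with area CV."""
        def mean_cv(area_cv):
            cvs = []
            for seed in range(5):
                peaks, manifest = sd.simulate_calibration_series(
                    default_design, 1000.0, sd.NoiseModel(seed=seed, area_cv=area_cv)
                )
                ratios = sg.ratios_table(peaks)
                fit = vl.fit_reverse_calibration(ratios, manifest, AC)
                tbl = vl.accuracy_precision_table(fit, ratios, manifest)
                cvs.append(tbl["precision_cv_pct"].mean())
            return np.mean(cvs)

        assert mean_cv(0.02) < mean_cv(0.08)

    def test_report_files_written(self, tmp_path, noisy_calibration):
        peaks, manifest = noisy_calibration
        ratios = sg.ratios_table(peaks)
        fit = vl.fit_reverse_calibration(ratios, manifest, AC)
        fom = vl.figures_of_merit(fit, ratios, manifest)
        tbl = vl.accuracy_precision_table(fit, ratios, manifest)
        vl.write_validation_report(tmp_path, fom, tbl)
        assert list(tmp_path.glob("validation_summary_*.tsv"))
        assert list(tmp_path.glob("validation_levels_*.tsv"))
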