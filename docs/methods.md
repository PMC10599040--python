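# Methods

## The measurement problem

Histone H3 lysine-14 acetylation (H3K14ac) is a low-stoichiometry mark.
Quantifying its *absolute* stoichiometry by bottom-up proteomics requires
comparing the acetylated and unmodified forms of the same tryptic peptide on
a common absolute scale, because the two forms ionize differently (the
acetylated peptide is detected roughly half as efficiently). The AQUA
strategy solves this by spiking each endogenous (light) peptide with a
chemically identical stable-isotope-labeled (SIL, "heavy") standard of known
concentration and reading the light:heavy area ratio in a
multiple-reaction-monitoring (MRM) experiment.

Chemical propionylation of unmodified lysines before digestion blocks
tryptic cleavage at lysine, so the acetylated and unmodified K14 forms yield
the same 9-residue peptide, H3 3-17 `KSTGGKAPR` (K9 at peptide position 1,
K14 at position 6). The four analytes are:

| form | K9 | K14 | label |
|---|---|---|---|
| K9[Poy]K14[Ac] | propionyl | acetyl | light |
| K9[Poy]K14[Ac]-heavy | propionyl | acetyl | 13C6 15N4 C-term R |
| K9[Poy]K14[Poy] | propionyl | propionyl | light |
| K9[Poy]K14[Poy]-heavy | propionyl | propionyl | 13C6 15N4 C-term R |

## Mass and transition arithmetic (`masscalc`)

Monoisotopic residue masses come from pyteomics; the modification deltas are
propionyl +56.026215 Da, acetyl +42.010565 Da, and the heavy arginine label
+10.008269 Da (6x13C + 4x15N). The canonical peptide mass is the neutral
monoisotopic mass; `table_convention_mass` adds one hydrogen atom
(1.007825 Da), the convention under which the assay's documented masses
(e.g. 999.5587 Da for the light acetyl form) are printed. Precursors are
doubly protonated, products singly protonated y ions (y7/y8/y6 per peptide,
twelve transitions labeled MRM1-MRM12). Display rounding is one decimal,
half away from zero; all internal arithmetic is full precision.

Declared (assay-file) Q3 values are reconciled against computation when a
transition list is loaded: a deviation of at most 0.05 m/z is treated as
computed, 0.05-0.25 m/z is accepted as a declared instrument value with a
warning (the acquisition method's match tolerance is 0.25 m/z), and beyond
0.25 m/z is an error.

### Isobaric specificity

K9[Ac]K14[Poy] is a positional isomer of K9[Poy]K14[Ac] with identical
precursor mass, so only product ions whose m/z differs between the two
forms are usable. The filter excludes a candidate ion when the isomer's
same-series ion (same type and charge) falls within the 0.25 m/z tolerance:
y1-y3 (R, PR, APR) span neither K9 nor K14 and are excluded; y4-y8 are
retained, consistent with the assay's chosen y6/y7/y8.

A design note on the comparison rule: screening a candidate against the
isomer's *other* ion series as well (`cross_type=True`) would also exclude
y7, because b7 of K9[Ac]K14[Poy] (728.393) happens to fall 0.012 m/z from
y7 of K9[Poy]K14[Ac] (728.405). For arginine-terminated tryptic peptides
CID product spectra are dominated by the y series — b ions are minor, and a
same-series collision is the practically relevant interference — so the
same-series rule is the default and the cross-series screen is exposed as a
stricter diagnostic. b ions are never quantified.

## Synthetic data (`synthetic_data`)

The generator emulates the study's injection plan exactly:

* reversed calibration: heavy standard at 0.5, 1.25, 5, 50, 500, 1250,
  2500 fmol/µL (5 replicates each), light internal standard constant at
  100 fmol, 9 matrix blanks, QC at 12.5 fmol/µL (5 replicates) — 49
  injections per peptide pair;
* donor samples: per donor-condition, technical triplicates with the light
  acetyl form at `true_stoichiometry x total_peptide`, the light propionyl
  form at the complement, and both heavy standards at 50 fmol/µL.

Peak areas are `response x concentration` (response defaults to 1000 area
units per fmol/µL; all ratios are invariant to it) times multiplicative
lognormal noise parameterized to unit mean (sigma^2 = ln(1+CV^2),
mu = -sigma^2/2), keeping ratio estimators unbiased in expectation. The
default `area_cv = 0.05` matches the few-percent replicate CVs the
validated assay achieves. Peptide-level areas are split across y7/y8/y6 by
fixed fractions (0.45/0.35/0.20) with independent per-transition noise at
half the peptide-level CV, so transition-ratio QC sees realistic variation.

Blanks carry baseline-only heavy signal: on the fast (peak-table) path each
blank transition area is |N(0, `blank_area_sd`)| with a default of 30 area
units. Against the light-IS area of 1e5 this puts the simulated LLOD near
0.2 fmol/µL, the order of magnitude a validated assay of this kind reports;
setting it to 0 gives the noiseless limit (LLOD exactly 0). The slow path
renders Gaussian elution peaks (default apex 12.0 min, sigma 0.05 min,
5 ms sampling, retention jitter SD 0.01 min shared by all transitions of an
injection) for exercising the integrator.

What the generator does **not** model: isotope envelopes, ion
suppression/matrix effects, carryover, between-day drift, peak-shape
asymmetry, or a between-donor variance model (donor scenarios are
user-specified). Passing tests therefore demonstrate correctness of the
computational pipeline under the assay's nominal statistical assumptions,
not robustness to those instrument-level artifacts.

## Signal quantification (`signal`)

Peptide signal is the sum of its (three) transition areas; light:heavy
ratios are computed per injection and statistics are taken over injections
(never ratio-of-means). Trace integration is trapezoidal above an edge-mean
baseline (mean of the first/last 3 window points; the exact rule is
second-order at assay signal-to-noise, and is validated against the
closed-form Gaussian to <0.2%), with the net area clipped at zero and the
apex taken from a 3-point smoothed maximum. A zero heavy area flags the
ratio as undefined rather than producing an infinity; flagged records are
excluded downstream with a warning. Retention-time coherence across
transitions (and across the light/heavy pair, which co-elutes by
construction) is checked against a 0.1 min tolerance.

## Assay validation (`validation`)

The reversed calibration fits log10(heavy:light ratio) against log10(nominal
concentration) by unweighted OLS — weighting schemes (1/x, 1/x^2) are
deliberately not offered, matching the assay's unweighted log-space
regression — and reports R^2 as the squared Pearson correlation on the
log-log scale (a linear-scale R^2 is diagnostic only). Figures of merit:

* **LLOD**: blank mean + 3xSD of the blank's heavy:light signal, converted
  to concentration through the fitted curve (default); a `3sd`-only mode
  and a signal-axis (no-conversion) path exist because the fuller
  "mean + 3SD" phrase and the shorthand "3xSD" both circulate as the
  operative definition. Sample (n-1) SD everywhere.
* **Accuracy/precision** per level: mean back-calculated concentration over
  nominal x100, and %CV of back-calculated replicates.
* **LLOQ/ULOQ**: ULOQ is the highest level passing CV < 20% and accuracy
  85-115%; LLOQ is the lowest level passing CV < 20% with accuracy 80-120%
  such that every interior level up to the ULOQ passes at 85-115%
  (contiguity is a design choice — the endpoint definitions alone do not
  constrain interior levels; a non-contiguous pattern moves the LLOQ above
  the last interior failure with a warning). A stricter 15%-bias/CV profile
  can be applied by the caller; the 20% CV rule is the default.
* **Specificity**: percentage peak areas per transition, referenced to
  their mean over calibration standards above the LLOQ; deviations beyond
  30% are flagged.
* **Selectivity**: an automated surrogate for visual blank inspection — a
  transition fails when the blank's integrated area in the analyte
  retention window exceeds the LLOD signal.

## Stoichiometry and statistics (`stoichiometry`)

Absolute abundance = light:heavy ratio x heavy-spike concentration
(50 fmol/µL for donor runs). Site stoichiometry per replicate is
`100 * mod / (mod + unmod)`; aggregation is strictly two-tier (technical
replicates -> donor mean, donor means -> condition mean), with sample SD
and %CV at each tier. Condition pairs (CIC/CIM/MIM) are compared by Welch's
unequal-variance t-test, two-sided, significant at p < 0.05, at two levels:
per donor over technical replicates (note: this measures instrument
repeatability, not donor biology — the pseudo-replication caveat is stated
in the output), and per cohort over the six donor means. No
multiple-testing correction is applied across the three pairwise tests by
default. Abundances below the LLOQ are retained (censoring is left to the
caller). Sidedness and the replicate-level grouping were genuinely open
choices; both are documented here rather than hidden.

## Numerical and testing choices

* All randomness flows through one `numpy` Generator seeded from the
  mandatory `NoiseModel.seed`; identical seeds give bit-identical tables.
* Problem sizes in tests and the acceptance script are the study's own
  (49 calibration injections, 54 donor injections); the parameter-recovery
  property uses 200 simulated runs of five donors spanning 10-90%
  stoichiometry at 5% noise.
* Degenerate inputs (zero heavy area, all-zero blanks, empty groups,
  non-positive ratios on the log axis) are flagged-and-excluded with
  warnings rather than propagated as infinities; genuinely malformed input
  (unknown residues, out-of-range ions, duplicate transitions, <3
  calibration levels) raises a module-specific error naming the offender.

## Known limitations

* The LLOD depends on the synthetic blank-noise scale, which real matrix
  blanks would set empirically; only its order of magnitude is meaningful.
* Integration is single-peak by design: no peak picking, deconvolution or
  smoothing-parameter optimization.
* Only +2 precursors and +1 y-series products are modeled; no neutral-loss
  or a/c/x/z ions, no collision-energy prediction (instrument-parameter
  columns pass through opaquely).
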