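# Methods

This note documents the models, rules and numerical choices implemented in
xenoquant, the assumptions behind the synthetic-data generator, and the
limits of what the passing test suite demonstrates.

## Calibration

Responses are fitted by weighted least squares with weights wᵢ = 1/xᵢ,
solved in closed form from the weighted normal equations. The weighted
coefficient of determination is reported (computed on the same objective
that was minimised); an unweighted fit is available and coincides with the
weighted one on noiseless homoscedastic lines. At least five distinct
non-zero levels are required; zero-concentration points are excluded under
1/x weighting (their weight is undefined) with a warning. No extrapolation
is performed above the top calibrant — values above range are flagged, not
reported.

Analytes with a configured internal standard are quantified on the
area-ratio scale (analyte area ÷ IS area); measurements with a missing or
non-positive IS area are dropped with a warning. The IS link is an explicit
per-analyte mapping in the panel config, defaulting to none.

**Matrix effect.** SSE% = 100 × matrix slope ÷ solvent slope, defined only
when both curves share weighting and IS usage and the solvent slope is
positive.

**LOD/LOQ.** S/N is defined as (response − intercept) ÷ noise, with the
noise taken from an explicit per-measurement column — integration software
conventions differ, so the definition is fixed in-repo rather than
inferred. The LOQ is the concentration where S/N crosses 10, obtained by
log-linear interpolation between the two calibration levels bracketing the
threshold (exact when S/N is proportional to concentration, and insensitive
to the spacing of the level grid); when no pair brackets, a global
log-linear fit of S/N against concentration is extrapolated. The LOD uses
the same rule at S/N = 3, so interpolated estimates satisfy LOQ/LOD ≈ 10/3.
Per-run estimates are averaged arithmetically across validation runs; this
"average LOQ" is the one the quantitation rule consults. The estimate is
monotone: inflating every noise value cannot lower the LOQ.

## Quantitation rules

Order of operations for an unknown: inverse prediction, blank subtraction,
recovery correction, censoring.

- **Blank correction** applies only to analytes flagged as
  contamination-prone (tube/LC extractables: BPA, BPS, MBP, MEHP, the butyl
  phthalates, n-butylbenzenesulfonamide, nonylphenol). The contamination
  level is the mean of ≥3 water-extract blanks read through the solvent
  curve. Corrected values are floored at zero and re-censored on
  concentration alone (the raw S/N includes the subtracted signal and is
  not reused). Subtraction precedes recovery division because contamination
  is modelled as entering the extract after the lossy extraction step; in
  that model subtract-then-divide returns the true concentration exactly,
  which the noiseless end-to-end test asserts. Validation spikes are
  corrected with the same blank value as the unknowns.
- **Recovery correction** divides by the analyte's average extraction
  recovery — the mean over both spike levels and all three days — but only
  when the concentration exceeds the average LOQ or the measurement has
  S/N > 10; trace signals near the noise are left uncorrected. Recoveries
  are capped at 120% (values beyond that indicate an invalid calibration,
  not a correction factor).
- **Censoring** is closed on the right: a value exactly at the LOQ counts
  as quantified, exactly at the LOD as below-LOQ. Censored records enter
  descriptive statistics at LOQ/2 and upper-bound intake at the LOQ, so the
  intake substitution dominates the statistics substitution for every
  censored record by construction.

## Validation

Recovery is detected ÷ spiked concentration, computed before any recovery
correction (correcting first would make it 100% by construction) and
accepted in 50–120%. Intermediate precision pools the nine spike results
per level (3 days × 3 replicates); repeatability uses six same-day repeat
injections of one validation batch (both levels re-injected). Both RSDs use
the n−1 sample standard deviation and are compared to tiered ceilings —
32% below 10 ng/mL, 27% to 100, 23% to 1000, 16% above — which undercut
the Horwitz tolerance RSD% = 2^(1 − 0.5 log₁₀ C) at trace levels (C is the
dimensionless mass fraction; ng/mL converts with the aqueous density
convention, giving 45%, 64% and 91% at 1, 0.1 and 0.01 ng/mL). Linearity
requires weighted R² strictly above 0.9.

Selectivity fails when the mean matrix- or system-blank response exceeds
30% of a reference response — a configurable default, since "screened for
interfering peaks" admits many operationalisations. At the unit level the
reference is the lowest calibrant's response; the pipeline predicts the
reference from the fitted curve at the lowest *reportable* level (the
average LOQ, or the lowest calibrant if higher), because the demo design
calibrates from LOQ/3 where 30% of the raw response equals the noise floor
and a raw-area screen would flip on noise.

An analyte "fulfils all criteria" at a level when recovery, both
precisions, linearity and selectivity all pass; the matrix summary reports
the percentage fulfilling all criteria at at least one level plus the
median recovery. The evaluation is monotone: improving any one metric never
flips a pass to a fail.

## Exposure scenario

The high-exposure scenario fixes 1000 mL milk/day and a 6 kg body weight.
Assumed concentration: maximum quantified level, or the LOQ when the
analyte was only ever seen below it; analytes never detected are excluded.
hUBI = conc × 1000/6/1000 µg/kg bw/day. TDI/ADI values are divided by 3 for
infants under 16 weeks; BMDL10 values are never infant-corrected (the MoE
convention compares intake to the unmodified benchmark dose). Cumulative
class intake sums the member assumed concentrations into a single hUBI.

All intermediates are kept at full precision. Display rounding: two
significant figures below 100, nearest integer above; dimensionless ratios
below 10 keep two significant figures. Ratio and MoE cells are emitted in
two conventions side by side — full-precision division, and a
"report-arithmetic" mode that divides the display-rounded guidance and
intake values, reproducing how a table computed from its own printed cells
reads. Published risk tables mix both conventions, so neither mode is
privileged; the full-precision value is the default and the concern flag
(MoE < 10,000, strict) is always evaluated at full precision.

Guidance values are data, not code: they ship as an editable YAML registry
(name, class, assumed concentration and provenance, TDI/ADI/BMDL10 with
kind and source tag), because agency opinions change over time.

## Synthetic-data generator

The generator emulates the study designs, not chromatography. For a
prepared concentration c in matrix m:

    µ    = slope_m · (c · recovery + c_blank) + intercept
    area = max(µ · (1 + cv·ε₁) + floor·ε₂, 0),  ε ~ N(0,1)

with slope_m = solvent slope × SSE. The heteroscedastic proportional-plus-
floor noise is the model that motivates 1/x weighting. The noise floor is
emitted as the per-measurement noise column, making the true LOQ
10·floor/slope_m in closed form; the expected S/N at that concentration is
exactly 10. Contamination is a fixed post-extraction concentration present
in every extract including water blanks.

One batch contains: matrix-matched and solvent calibrants on a
seven-level grid spanning ~2.3 decades from LOQ/3 (so the S/N = 3 and 10
crossings are bracketed); spikes at 3× and 30× LOQ, 3 replicates × 3 days,
passing through recovery and contamination; six same-day repeat injections
of both levels; triplicate matrix and water blanks; and optional unknowns
(log-normal around 10× LOQ, or caller-specified). An optional log-normal
day effect drifts all areas of a day jointly; internal-standard areas share
the drift, so IS normalisation cancels it.

Longitudinal series are log-normal around a per-analyte median
(dispersion = log-sd). Episodic profiles multiply in rare bursts (Bernoulli
p = 0.1 per day, ~10× log-normal) mimicking isolated exposure events;
accumulating profiles use a quarter of the stated dispersion
(bioaccumulative compounds hovering near a floor); analytes in a
correlation group load 0.9 on a shared latent day factor. Days thin at
random (keep probability 0.6) when sampling gaps are enabled — a stand-in
for the irregular feeding-driven schedule of real longitudinal sampling,
not a reconstruction of it. Non-detection days and values under the
reporting limit are emitted censored.

**Demo conditions.** The eight-analyte milk panel spans the realistic
ranges: solvent slopes 500–10,000 area/(ng/mL), SSE 70–110%, recoveries
54–90% (milk extraction loses polar analytes), noise floors giving LOQs of
0.002–0.03 ng/mL, cv 5%, and system contamination of 0.30 and 0.10 ng/mL
on the two flagged plasticizers. Under these conditions 6 of 8 analytes
fulfil all validation criteria (the two contamination-flagged ones fail the
selectivity screen), stably across seeds.

What the generator does **not** emulate: chromatographic peak shape and
integration, retention-time interferences, carryover, real between-subject
variability, pharmacokinetics of mother-to-milk transfer, or conjugate
speciation. Passing tests therefore demonstrate the correctness of the
arithmetic chain and the statistical behaviour of the estimators under the
declared noise model — not performance on real cohort data, whose pass
rates and recovery medians are properties of real matrices and panels.

## Numerical choices and problem sizes

- All randomness flows from a single seed; per-stage substreams are derived
  deterministically, and identical seeds give byte-identical outputs.
- Quartiles use linear interpolation between order statistics (violin-plot
  software conventions differ; this one is asserted against a sort-based
  oracle).
- Correlation defaults to Spearman rank on pairwise-complete days with
  half-LOQ substitution — robust to the censoring mass point; Pearson is
  available. Cells with <3 overlapping days or a constant series are
  reported unavailable, not zero.
- Paired comparisons (deconjugation, volume downscaling) report the median
  treated/untreated ratio over sample-matched pairs, excluding and counting
  pairs lost to censoring. With a conjugated fraction f and lossless
  hydrolysis the expected ratio is 1/(1−f).
- Monte-Carlo test sizes: estimator-convergence checks run 100 seeds on a
  one-analyte panel, the correlation null 500 seeds at 30 days — sizes at
  which the whole suite completes in seconds while the standard errors are
  well inside the asserted tolerances.
- Plasma is treated as serum for calibration lookup, with a warning when
  mixed; no plasma-specific curves exist.

## Known limitations

- No uncertainty propagation on reported concentrations; point values only.
- Linear calibration only; no quadratic fallback for detector saturation.
- The blank-correction model assumes contamination is constant across a
  batch; drifting contamination would need per-sample blanks.
- The exposure scenario is a deterministic worst case (single maximum
  concentration, fixed intake and body weight), not a probabilistic
  exposure model; cumulative class intake is simple concentration addition
  without potency weighting.
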