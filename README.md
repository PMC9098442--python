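# xenoquant

Data-processing pipeline for multi-class targeted LC-MS/MS human
biomonitoring: weighted matrix-matched calibration and quantitation with
censoring and correction rules, guideline-style in-house method validation,
censoring-aware cohort statistics, and a breast-milk infant exposure/risk
assessment. A synthetic-data layer emulates the instrument and wet-lab
stages with known ground truth, so every estimator in the pipeline is
testable without any external download.

It is written for analytical chemists and exposome researchers who work
with integrated MRM peak areas (quantifier/qualifier transitions of trace
xenobiotics — plasticizers, PFAS, parabens, phyto- and mycotoxins — in
urine, serum/plasma and breast milk) and need the full arithmetic chain
from peak area to risk statement to be explicit, seeded and reproducible.

## The model in brief

**Calibration.** For each analyte the response (peak area, or area ratio to
an isotopically labelled internal standard) is fitted against concentration
by 1/x-weighted least squares, minimising Σ wᵢ(yᵢ − a − bxᵢ)² with wᵢ = 1/xᵢ
— the weighting that matches the roughly proportional noise of trace-level
peak areas. The matrix effect is SSE% = 100·b_matrix/b_solvent (<100%
suppression, >100% enhancement). LOD and LOQ are the concentrations where
S/N = (area − a)/noise reaches 3 and 10, interpolated log-linearly between
the bracketing calibration levels.

**Quantitation.** Unknowns are inverse-predicted through the matrix-matched
curve; system contamination (estimated by solvent regression of triplicate
water blanks) is subtracted for the flagged contamination-prone analytes;
the result is divided by the average extraction recovery only when it
exceeds the average LOQ or has S/N > 10; finally a censor status
(quantified / <LOQ / <LOD / above range) is assigned. Censored values enter
descriptive statistics at LOQ/2 and upper-bound intake estimates at the
LOQ.

**Validation.** Spikes at 3× and 30× the LOQ, in triplicate over three
days, give recovery (accepted 50–120%), intermediate precision (RSD, n=9)
and repeatability (n=6) against tiered ceilings (32% below 10 ng/mL, 27%
to 100, 23% to 1000, 16% above) that undercut the Horwitz tolerance
RSD% = 2^(1 − 0.5·log₁₀C), linearity (weighted R² > 0.9) and a blank
interference screen.

**Exposure.** For each analyte detected in breast milk, the assumed
concentration is the maximum quantified level (or the LOQ if only seen
below it), converted to a hypothetical upper-bound intake for a 6 kg infant
drinking 1000 mL/day:

    hUBI [µg/kg bw/day] = conc [ng/mL] × 1000 / (6 × 1000)

TDI/ADI guidance is corrected by one-third for infants under 16 weeks and
reported as the ratio guidance/hUBI; BMDL10 values are compared uncorrected
as a margin of exposure, with MoE < 10,000 flagged as a potential concern.

## Worked example

The built-in exposure registry carries the assumed breast-milk
concentrations and guidance values for 27 detected analytes:

```python
from xenoquant.exposure import build_assessment_table, load_assessment_inputs
table = build_assessment_table(entries=load_assessment_inputs())
print(table.set_index("analyte").loc["Mono-n-butyl phthalate (MBP)", "hubi_display"])
```

prints `1.1`: 6.4 ng/mL × 1000 mL/day ÷ 6 kg ÷ 1000 = 1.07 → 1.1 µg/kg
bw/day to two significant figures. A few rows of the full table
(`analysis/06_exposure_assessment.py` prints all of them):

| analyte | assumed conc (ng/mL) | infant guidance | hUBI | ratio / MoE |
|---|---|---|---|---|
| Bisphenol A (BPA) | 0.40 | 1.3 | 0.067 | 20 |
| Perfluorooctanoic acid (PFOA) | 0.092 | 0.21 | 0.015 | 14 |
| Methylparaben (MP) | 23 | 3333 | 3.8 | 870 |
| Jacobine-N-oxide | 0.11 | (BMDL10 70) | 0.018 | MoE 3818 (3889 report-mode) |
| PhIP | 0.042 | (BMDL10 480) | 0.0070 | MoE 68,571 |

Only jacobine-N-oxide falls below the MoE 10,000 line; against the more
conservative infant-corrected Dutch TDI (0.1/3 µg/kg bw/day) its margin is
1.8. Ratios are emitted in two conventions side by side: full-precision
intermediates, and a report-arithmetic mode that divides the
display-rounded values.

The simulated study runs end to end with:

```
xenoquant run --out results_demo --seed 1
```

or stage by stage through the numbered drivers in `analysis/` (simulate →
calibrate → validate → quantify → cohort summaries → exposure assessment),
each of which prints what it found and writes its tables under `results/`.
On the default eight-analyte panel the validation stage reports 75% of
analytes fulfilling all criteria at ≥1 level, and the calibration stage
recovers the generator's matrix effects and LOQs to within a few percent.

## Layout

- `src/xenoquant/` — the library: `types`, `io`, `simulate`, `calibration`,
  `quantitation`, `validation`, `exposure`, `cohort`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance tests (all synthetic, seeded).
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
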