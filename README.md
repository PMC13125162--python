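# vusreclass

Reclassification analysis for clinically reported missense variants of
uncertain significance (VUS) under the ACMG/AMP 2015 guidelines, using
ClinGen-recalibrated variant-effect-predictor (VEP) score thresholds for the
in-silico evidence criteria PP3 (computational support for pathogenicity)
and BP4 (computational support for benignity).

Clinical laboratories classify variants into Pathogenic (P), Likely
Pathogenic (LP), VUS, Likely Benign (LB) or Benign (B) by combining coded
evidence criteria (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7), each with
an evidentiary strength (Supporting < Moderate < Strong < Very Strong, plus
the stand-alone BA1). Originally PP3/BP4 could contribute only Supporting
weight; ClinGen-style recalibration maps each predictor's score range into
intervals that can carry PP3 or BP4 up to Strong or Very Strong. This
package answers: *if a laboratory swaps its original PP3/BP4 usage for the
calibrated assignment of a single predictor and re-runs the 2015 combining
rules, which VUS change tier, and how consistently do predictors agree?*

It provides:

- **`vusreclass.acmg`** — the 2015 evidence model and combining engine.
  Strength counting is code-agnostic: `PP3_Strong` fills a strong-pathogenic
  slot exactly as PS1 would. Gap cases are explicit options
  (`single_bs_is_lb`, `ba1_overrides`).
- **`vusreclass.calibration`** — calibrated score-interval tables for eight
  predictors (VARITY, AlphaMissense, ESM1b, BayesDel, VEST4, REVEL,
  PolyPhen-2, SIFT), a validated YAML config format, and the
  score → (PP3/BP4, strength) mapping.
- **`vusreclass.pipeline`** — the per-predictor evidence swap, eligibility
  accounting (by default only variants whose baseline classification used
  PP3/BP4), transition matrices and reclassification percentages, plus an
  ablation mode that removes in-silico evidence entirely.
- **`vusreclass.stats`** — pairwise predictor concordance on VUS
  reclassifications, Fisher-exact odds ratios with Woolf 95% CIs,
  mode-of-inheritance contrasts, and dataset summary tables.
- **`vusreclass.synthetic`** — a generator for study-shaped cohorts
  (majority-VUS evidence profiles, realistic PP3/BP4 usage, predictor scores
  correlated through a shared latent pathogenicity factor) so the whole
  pipeline is testable without clinical data.

## Worked example

```python
import vusreclass as vr
from vusreclass.synthetic import CohortConfig, generate_cohort

table = vr.default_calibration()
variants, _ = generate_cohort(CohortConfig(seed=7), table)

by_pred = {}
for pred in table.predictors:
    outcomes, _ = vr.reclassify_cohort(variants, pred, table)
    by_pred[pred] = outcomes
    print(f"{pred:13s} VUS reclassified: "
          f"{vr.reclassification_percentage(outcomes):.2f}%")

print("median over predictors:",
      round(vr.median_reclassification(
          [vr.reclassification_percentage(o) for o in by_pred.values()]), 2))
```

prints, for the tenth-scale synthetic preset (720 variants over seven
dataset labels):

```
REVEL         VUS reclassified: 6.10%
VARITY        VUS reclassified: 25.08%
AlphaMissense VUS reclassified: 3.05%
ESM1b         VUS reclassified: 6.44%
BayesDel      VUS reclassified: 11.19%
VEST4         VUS reclassified: 5.76%
PolyPhen-2    VUS reclassified: 1.36%
SIFT          VUS reclassified: 4.75%
median over predictors: 5.93
```

Each percentage is the share of eligible baseline-VUS variants (those whose
curated classification used PP3/BP4 and that carry a score for the
predictor) whose tier changed after the evidence swap. On real cohorts the
published recalibrations move only a few percent of VUS; the synthetic
generator reproduces that order of magnitude by construction, not the
clinical values themselves.

Association statistics work from plain 2×2 counts, e.g. the odds of a VUS
call in a genome-wide dataset versus pooled gene panels:

```python
res = vr.fisher_exact_or([[604, 206], [5138, 1273]])
# res.or_point -> 0.73, (res.ci_low, res.ci_high) -> (0.61, 0.86)
```

The same flows are available from a shell:

```sh
vusreclass simulate --seed 7 --out run/
vusreclass reclassify --variants run/variants.tsv --scores run/scores.tsv --out run/
vusreclass concord --outcomes run/outcomes.tsv --out run/
vusreclass summarize --variants run/variants.tsv --out run/
```

## Documentation

See `docs/methods.md` for the model, the configurable rule-gap decisions,
the synthetic-cohort design and known limitations.
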