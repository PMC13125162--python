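# Methods

## The classification engine

The ACMG/AMP 2015 framework classifies a variant by combining applied
evidence criteria. Each criterion has a polarity (pathogenic codes start
with P, benign with B) and a default strength implied by its prefix
(PVS → Very Strong, PS/BS → Strong, PM → Moderate, PP/BP → Supporting,
BA → Stand-alone). Laboratories may apply a criterion at a modified
strength; following standard practice for calibrated computational
evidence, the engine counts strengths *code-agnostically*: `PP3_Strong`
fills a strong-pathogenic slot exactly as PS1 would, and a criterion raised
to Very Strong fills the very-strong slot exactly as PVS1 would.

The pathogenic, likely-pathogenic, benign and likely-benign qualifying
combinations are transcribed from the published 2015 table. Combinations
the table leaves open are resolved as package policy, each testable and
(where reasonable) configurable:

- **Conflicting evidence → VUS.** Beyond the case where qualifying
  combinations fire on both polarities, strong-or-stronger evidence of the
  opposite polarity vetoes a call: `{PS1, BS1}` is uncertain. A lone
  moderate pathogenic criterion does *not* block a benign call, so a single
  BP4 upgrade over a `{PM2, BP4}` baseline legitimately reaches Likely
  Benign — the mechanism behind most VUS → LB transitions in this analysis.
- **Single strong benign criterion** (`single_bs_is_lb`, default on):
  one Strong benign item alone yields Likely Benign. The strict 2015 table
  leaves 1×BS unclassified; laboratory practice, and the VUS → LB flows a
  single strong BP4 produces, require this rule. Off, it falls through to
  VUS.
- **BA1 override** (`ba1_overrides`, default on): the stand-alone benign
  criterion classifies Benign regardless of pathogenic evidence.
- **No benign very-strong slot exists in 2015**; a benign criterion at Very
  Strong (e.g. calibrated `BP4_VeryStrong`) fills a strong-benign slot.
  Two or more pathogenic Very Strong items classify Pathogenic.
- **Duplicate codes replace**: re-adding a criterion replaces its previous
  strength, mirroring the evidence-swap semantics below.

`enumerate_rule_table` materializes the engine's decisions over all
per-polarity strength multisets up to a given size; the test suite checks
it exhaustively (≤ 6 items) against an independently transcribed rule
table, plus monotonicity properties (raising a pathogenic strength never
moves the call benign-ward, and symmetrically).

## Calibrated score thresholds

Each predictor's score range is partitioned into ordered intervals carrying
(PP3 | BP4 | no evidence) with a strength, validated for pairwise
disjointness, full coverage, and monotonicity along the deleterious
direction (benign evidence weakens, passes through the indeterminate gap,
then pathogenic evidence strengthens). Interval endpoints carry explicit
inclusivity flags; the shipped config makes thresholds inclusive on the
evidence-bearing side, because calibrations state thresholds as
"score ≥ t" / "score ≤ t".

The shipped `data/clingen_calibration.yaml` transcribes the ClinGen
recalibrations for the eight predictors analyzed here, with a provenance
string per predictor. Conventions worth noting:

- **SIFT** is the sole lower-is-deleterious predictor (pathogenic evidence
  at very low scores, benign at high scores).
- **ESM1b** raw scores are log-likelihood ratios where more negative means
  more damaging; the config stores the negated value (range 0–30) so all
  non-SIFT predictors share the higher-is-deleterious orientation.
- **PolyPhen-2** uses the HVAR classifier probabilities (`model_variant`
  config field; HDIV users can swap the block).
- REVEL and VARITY can reach Strong benign evidence; BayesDel, VEST4,
  PolyPhen-2, AlphaMissense and ESM1b top out at Moderate on the benign
  side, and SIFT at Supporting on the pathogenic side.

Missing scores exclude a variant from that predictor's denominator (never
counted as "unchanged"); the exclusion count is logged. Out-of-range scores
are reported and skipped the same way. No imputation is performed.
Coordinates are 1-based GRCh37/hg19 throughout; no liftover.

## The evidence swap

For one predictor, a variant's revised profile is its baseline profile with
any PP3/BP4 entries removed and, when the score maps to evidence, the
calibrated code inserted at its calibrated strength — so original
supporting-level in-silico usage is never stacked with the recalibrated
assignment, and PP3 and BP4 are never simultaneously present. When the
score falls in the indeterminate region the baseline PP3/BP4 is dropped
(the calibrated predictor supplies no evidence); `retain_baseline_on_none`
keeps it instead, since the laboratory convention is not documented. All
non-in-silico criteria pass through untouched (a tested locality
invariant).

Eligibility defaults to variants whose baseline classification already used
PP3 or BP4 (`BASELINE_INSILICO_ONLY`), matching the study design; `ALL`
mode is available for sensitivity analysis. Each predictor is evaluated
independently — no cross-predictor consensus evidence is ever formed. The
headline percentage is 100 × changed / eligible-scored, restricted to
baseline-VUS; transition matrices record all tiers. Curated labels that
disagree with the engine's reading of the recorded profile are kept as
reported and flagged (`as_reported`), and transitions are measured from the
curated label.

The ablation mode removes PP3/BP4 outright (ignoring scores), estimating
how much the original supporting-level in-silico evidence contributed to
baseline classifications.

## Statistics

- **Concordance** between two predictors, per dataset: among baseline-VUS
  variants reclassified by either, the percentage reclassified by both *to
  the same tier* (`destination_agnostic` relaxes this). Cells with an empty
  union are undefined — not 100% — and are excluded from medians and
  counted separately, since sparse cells otherwise dominate.
- **Odds ratios** are sample ORs (ad/bc) with Woolf logit 95% CIs
  (exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))) and exact two-sided Fisher
  p-values. The conditional-MLE OR is computed alongside for reference; the
  sample OR is reported because it is the flavor that matches the published
  2×2 summaries this package is designed to reproduce. Zero cells get the
  Haldane–Anscombe 0.5 correction for the OR/CI (flagged); the p-value
  stays exact.
- **Mode-of-inheritance contrast**: per predictor, the 2×2 of
  (AD changed, AD unchanged; AR changed, AR unchanged); X-linked and
  unknown MOI are excluded, and an empty autosomal stratum renders the
  predictor not-testable rather than producing a degenerate OR.
- Medians are standard (mean of the central pair for even counts),
  computed after dropping undefined entries. Machine output keeps 2
  decimals; the human-readable summary table rounds percentages to integers
  (half away from zero). Significance is two-sided α = 0.05 with no
  multiple-testing correction.

## Synthetic cohorts

No clinical cohort can ship with the package, so validation uses a
generative model with the minimal structure the analysis exercises:

- Each variant draws a latent state (pathogenic-like with probability
  π = 0.20) and a dataset label from presets sized at one tenth of the
  study-scale cohorts (full-size presets included).
- Baseline evidence is sampled from per-state emission probabilities chosen
  to yield a majority-VUS mix with small P/LP and LB/B tails. With
  probability 0.50 the baseline uses in-silico evidence at Supporting:
  PP3 with probability 0.90 (pathogenic-like) or 0.30 (benign-like), else
  BP4 — expected usage ≈ 21% PP3 / 29% BP4, inside the observed
  clinical bands. PP3 and BP4 are never co-emitted.
- Scores share one latent Gaussian factor:
  z = α(state) + ρ·g + √(1−ρ²)·ε with α = ±1.1 and ρ = 0.7, squashed
  through a logistic (scale 1.2) into each predictor's range, inverted for
  SIFT. The shared factor is what makes predictors agree on which variants
  to move, mimicking inter-predictor concordance.
- Streams are split per variant from a counter-based seed sequence, so
  enlarging a cohort never perturbs earlier variants, and identical
  config + seed reproduces the cohort byte-for-byte.

`expected_change_fraction` is a deliberately separate Monte-Carlo oracle:
it re-implements threshold lookup, evidence swap and rule combination
inline and the suite requires pipeline agreement within 3 binomial standard
errors. Test problem sizes are 2 000–12 000 variants, enough that binomial
noise is small next to the asserted margins while the whole suite stays
fast.

What passing synthetic tests shows — and what it does not: the pipeline's
bookkeeping, rule logic and statistics are correct on cohorts with the
right gross structure. The generator does not model real gene coordinates,
allele frequencies, gene-panel composition effects, per-gene score
idiosyncrasies, or the correlation structure of real predictor
disagreements, so clinical reclassification percentages and concordance
levels are not claims the synthetic results can support.

## Known limitations

- The numeric thresholds in the shipped calibration are transcriptions of
  the cited ClinGen recalibrations; users applying this to clinical data
  should verify the config against the primary calibration publications for
  their predictor versions (the YAML is designed to be audited and
  swapped).
- Evidence codes: some published descriptions of this workflow write
  "PP4/BP3" where the in-silico criteria PP3/BP4 are clearly meant (both
  names appear in the literature around the recalibration); this package
  uses PP3/BP4 throughout.
- The 2015 combining rules, not the newer Bayesian points-based system, are
  implemented; gene-specific VCEP rule specifications are out of scope.
- Which PolyPhen-2 classifier (HDIV/HVAR) and VEST4 aggregation a given
  laboratory used may differ from the defaults; both are config fields.
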