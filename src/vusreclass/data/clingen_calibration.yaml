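# Default calibration: ClinGen-recalibrated score thresholds mapping each
# predictor's score range to PP3/BP4 evidence intervals at ACMG strengths.
# Thresholds are inclusive on the evidence-bearing side (a score equal to a
# published threshold earns that strength).  Orientation: SIFT is
# lower-is-deleterious; all others higher-is-deleterious (ESM1b is stored as
# the negated log-likelihood ratio so that larger values are more damaging).

aliases:
  revel.score: REVEL
  revel.rankscore: REVEL
  varity_r.score: VARITY
  varity_r.varity_r: VARITY
  alphamissense.am_pathogenicity: AlphaMissense
  alphamissense.score: AlphaMissense
  esm1b.score: ESM1b
  bayesdel.bayesdel_noaf_score: BayesDel
  bayesdel.score: BayesDel
  vest.score: VEST4
  vest4.score: VEST4
  polyphen2.hvar_prob: PolyPhen-2
  polyphen2.score: PolyPhen-2
  sift.score: SIFT
  sift.prediction_score: SIFT

predictors:
  REVEL:
    orientation: higher_is_deleterious
    range: [0.0, 1.0]
    provenance: >-
      ClinGen SVI recalibration of REVEL (ensemble meta-predictor);
      pathogenic thresholds 0.644/0.773/0.932 (Sup/Mod/Str), benign
      thresholds 0.290/0.183/0.016 (Sup/Mod/Str).
    intervals:
      - {lo: 0.0, lo_incl: true, hi: 0.016, hi_incl: true, assign: BP4, strength: strong}
      - {lo: 0.016, lo_incl: false, hi: 0.183, hi_incl: true, assign: BP4, strength: moderate}
      - {lo: 0.183, lo_incl: false, hi: 0.290, hi_incl: true, assign: BP4, strength: supporting}
      - {lo: 0.290, lo_incl: false, hi: 0.644, hi_incl: false, assign: NONE}
      - {lo: 0.644, lo_incl: true, hi: 0.773, hi_incl: false, assign: PP3, strength: supporting}
      - {lo: 0.773, lo_incl: true, hi: 0.932, hi_incl: false, assign: PP3, strength: moderate}
      - {lo: 0.932, lo_incl: true, hi: 1.0, hi_incl: true, assign: PP3, strength: strong}

  VARITY:
    orientation: higher_is_deleterious
    range: [0.0, 1.0]
    provenance: >-
      ClinGen recalibration of VARITY_R; strong benign evidence for very low
      scores (<= 0.115), strong pathogenic evidence above 0.965.
    intervals:
      - {lo: 0.0, lo_incl: true, hi: 0.115, hi_incl: true, assign: BP4, strength: strong}
      - {lo: 0.115, lo_incl: false, hi: 0.163, hi_incl: true, assign: BP4, strength: moderate}
      - {lo: 0.163, lo_incl: false, hi: 0.251, hi_incl: true, assign: BP4, strength: supporting}
      - {lo: 0.251, lo_incl: false, hi: 0.674, hi_incl: false, assign: NONE}
      - {lo: 0.674, lo_incl: true, hi: 0.867, hi_incl: false, assign: PP3, strength: supporting}
      - {lo: 0.867, lo_incl: true, hi: 0.965, hi_incl: false, assign: PP3, strength: moderate}
      - {lo: 0.965, lo_incl: true, hi: 1.0, hi_incl: true, assign: PP3, strength: strong}

  AlphaMissense:
    orientation: higher_is_deleterious
    range: [0.0, 1.0]
    provenance: >-
      ClinGen recalibration of AlphaMissense pathogenicity probabilities.
    intervals:
      - {lo: 0.0, lo_incl: true, hi: 0.070, hi_incl: true, assign: BP4, strength: moderate}
      - {lo: 0.070, lo_incl: false, hi: 0.169, hi_incl: true, assign: BP4, strength: supporting}
      - {lo: 0.169, lo_incl: false, hi: 0.787, hi_incl: false, assign: NONE}
      - {lo: 0.787, lo_incl: true, hi: 0.906, hi_incl: false, assign: PP3, strength: supporting}
      - {lo: 0.906, lo_incl: true, hi: 0.990, hi_incl: false, assign: PP3, strength: moderate}
      - {lo: 0.990, lo_incl: true, hi: 1.0, hi_incl: true, assign: PP3, strength: strong}

  ESM1b:
    orientation: higher_is_deleterious
    range: [0.0, 30.0]
    provenance: >-
      ClinGen recalibration of ESM1b; scores stored as the negated
      log-likelihood ratio (raw ESM1b is more negative = more damaging).
    intervals:
      - {lo: 0.0, lo_incl: true, hi: 3.5, hi_incl: true, assign: BP4, strength: moderate}
      - {lo: 3.5, lo_incl: false, hi: 5.0, hi_incl: true, assign: BP4, strength: supporting}
      - {lo: 5.0, lo_incl: false, hi: 7.5, hi_incl: false, assign: NONE}
      - {lo: 7.5, lo_incl: true, hi: 10.0, hi_incl: false, assign: PP3, strength: supporting}
      - {lo: 10.0, lo_incl: true, hi: 30.0, hi_incl: true, assign: PP3, strength: moderate}

  BayesDel:
    orientation: higher_is_deleterious
    range: [-1.5, 1.0]
    provenance: >-
      ClinGen SVI recalibration of BayesDel (noAF); pathogenic thresholds
      0.13/0.27/0.50 (Sup/Mod/Str), benign thresholds -0.18/-0.36 (Sup/Mod).
    intervals:
      - {lo: -1.5, lo_incl: true, hi: -0.36, hi_incl: true, assign: BP4, strength: moderate}
      - {lo: -0.36, lo_incl: false, hi: -0.18, hi_incl: true, assign: BP4, strength: supporting}
      - {lo: -0.18, lo_incl: false, hi: 0.13, hi_incl: false, assign: NONE}
      - {lo: 0.13, lo_incl: true, hi: 0.27, hi_incl: false, assign: PP3, strength: supporting}
      - {lo: 0.27, lo_incl: true, hi: 0.50, hi_incl: false, assign: PP3, strength: moderate}
      - {lo: 0.50, lo_incl: true, hi: 1.0, hi_incl: true, assign: PP3, strength: strong}

  VEST4:
    orientation: higher_is_deleterious
    range: [0.0, 1.0]
    provenance: >-
      ClinGen SVI recalibration of VEST4; pathogenic thresholds 0.764/0.861
      (Sup/Mod), benign thresholds 0.449/0.302 (Sup/Mod).
    intervals:
      - {lo: 0.0, lo_incl: true, hi: 0.302, hi_incl: true, assign: BP4, strength: moderate}
      - {lo: 0.302, lo_incl: false, hi: 0.449, hi_incl: true, assign: BP4, strength: supporting}
      - {lo: 0.449, lo_incl: false, hi: 0.764, hi_incl: false, assign: NONE}
      - {lo: 0.764, lo_incl: true, hi: 0.861, hi_incl: false, assign: PP3, strength: supporting}
      - {lo: 0.861, lo_incl: true, hi: 1.0, hi_incl: true, assign: PP3, strength: moderate}

  PolyPhen-2:
    orientation: higher_is_deleterious
    range: [0.0, 1.0]
    model_variant: HVAR
    provenance: >-
      ClinGen SVI recalibration of PolyPhen-2 (HVAR model); pathogenic
      thresholds 0.978/0.999 (Sup/Mod), benign thresholds 0.113/0.009
      (Sup/Mod).
    intervals:
      - {lo: 0.0, lo_incl: true, hi: 0.009, hi_incl: true, assign: BP4, strength: moderate}
      - {lo: 0.009, lo_incl: false, hi: 0.113, hi_incl: true, assign: BP4, strength: supporting}
      - {lo: 0.113, lo_incl: false, hi: 0.978, hi_incl: false, assign: NONE}
      - {lo: 0.978, lo_incl: true, hi: 0.999, hi_incl: false, assign: PP3, strength: supporting}
      - {lo: 0.999, lo_incl: true, hi: 1.0, hi_incl: true, assign: PP3, strength: moderate}

  SIFT:
    orientation: lower_is_deleterious
    range: [0.0, 1.0]
    provenance: >-
      ClinGen SVI recalibration of SIFT (lower scores more damaging);
      pathogenic supporting at <= 0.001, benign supporting/moderate at
      >= 0.08 / >= 0.327.
    intervals:
      - {lo: 0.0, lo_incl: true, hi: 0.001, hi_incl: true, assign: PP3, strength: supporting}
      - {lo: 0.001, lo_incl: false, hi: 0.08, hi_incl: false, assign: NONE}
      - {lo: 0.08, lo_incl: true, hi: 0.327, hi_incl: false, assign: BP4, strength: supporting}
      - {lo: 0.327, lo_incl: true, hi: 1.0, hi_incl: true, assign: BP4, strength: moderate}
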