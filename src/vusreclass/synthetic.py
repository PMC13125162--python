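"""Synthetic cohorts with the statistical structure the analysis assumes.

Clinical curation data cannot be redistributed, so pipeline validation runs
on generated cohorts built from a two-state latent model: each variant is
pathogenic-like or benign-like; its baseline evidence profile is sampled
from per-state emission probabilities (yielding a majority-VUS mix with
realistic PP3/BP4 usage) and its predictor scores share a single latent
Gaussian factor, which induces the between-predictor correlation that a
common underlying pathogenicity signal produces in real score panels.

Scores: for variant i and predictor j,
``z_ij = alpha(state_i) + rho * g_i + sqrt(1 - rho^2) * eps_ij`` squashed
through a logistic and mapped into the predictor's score range (inverted
for SIFT, whose low scores are deleterious).  Random streams are split per
variant from a counter-based seed sequence, so enlarging a cohort never
perturbs earlier variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .acmg import (
    AppliedEvidence,
    Classification,
    EngineOptions,
    DEFAULT_OPTIONS,
    EvidenceProfile,
    EvidenceStrength,
    combine,
)
from .calibration import (
    CalibrationTable,
    HIGHER_IS_DELETERIOUS,
    default_calibration,
    map_score,
)
from .pipeline import VariantRecord

__all__ = [
    "CohortConfig",
    "LatentVariant",
    "generate_cohort",
    "expected_change_fraction",
    "SMALL_PRESET",
    "FULL_PRESET",
]

#: (n variants, gene-pool size) per dataset; small preset is one tenth of the
#: full cohort sizes used in the study tables.
FULL_PRESET: dict[str, tuple[int, int]] = {
    "GWS": (810, 550),
    "RD": (542, 41),
    "HL": (2472, 67),
    "AI": (717, 35),
    "CT": (1563, 79),
    "NS": (397, 15),
    "HSP": (720, 40),
}
SMALL_PRESET: dict[str, tuple[int, int]] = {
    ds: (max(2, n // 10), max(2, g // 10)) for ds, (n, g) in FULL_PRESET.items()
}

#: Per-latent-state emission probability of each non-in-silico criterion.
_DEFAULT_EMISSIONS: dict[str, dict[str, float]] = {
    "PATHOGENIC_LIKE": {
        "PM2": 0.70,
        "PM1": 0.30,
        "PM5": 0.10,
        "PP1": 0.25,
        "PP2": 0.20,
        "PS1": 0.12,
        "PS4": 0.08,
        "PVS1": 0.08,
        "PP5": 0.08,
    },
    "BENIGN_LIKE": {
        "PM2": 0.30,
        "BS1": 0.05,
        "BS2": 0.03,
        "BP1": 0.10,
        "BP5": 0.06,
        "BP7": 0.04,
        "PP1": 0.03,
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the documented study-like regime."""

    datasets: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(SMALL_PRESET)
    )
    moi_mix: tuple[float, float, float] = (0.45, 0.45, 0.03)  # AD, AR, XL; rest UNKNOWN
    pathogenic_fraction: float = 0.20  # latent pathogenic-like share (pi)
    emissions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_EMISSIONS.items()}
    )
    insilico_usage: float = 0.50  # chance the baseline used PP3 or BP4
    p_pp3_given_pathlike: float = 0.90
    p_pp3_given_benignlike: float = 0.30
    alpha_pathogenic: float = 1.1  # score-model state locations
    alpha_benign: float = -1.1
    rho: float = 0.7  # shared-factor loading, in [0, 1)
    logistic_scale: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if not 0.0 <= self.pathogenic_fraction <= 1.0:
            errors.append("pathogenic_fraction must be in [0, 1]")
        if not 0.0 <= self.insilico_usage <= 1.0:
            errors.append("insilico_usage must be in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            errors.append("rho must be in [0, 1)")
        for name in ("p_pp3_given_pathlike", "p_pp3_given_benignlike"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                errors.append(f"{name} must be in [0, 1]")
        if sum(self.moi_mix) > 1.0 + 1e-9 or any(p < 0 for p in self.moi_mix):
            errors.append("moi_mix proportions must be non-negative and sum <= 1")
        for state, probs in self.emissions.items():
            for code, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    errors.append(f"emission {state}/{code} must be in [0, 1]")
                if code in ("PP3", "BP4"):
                    errors.append(
                        "in-silico codes are controlled by insilico_usage, "
                        f"not emissions ({state}/{code})"
                    )
        if errors:
            raise ValueError("; ".join(errors))

    def replace(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class LatentVariant:
    """Hidden truth for one generated variant (validation only)."""

    key: tuple[str, int, str, str]
    true_state: str  # PATHOGENIC_LIKE | BENIGN_LIKE
    shared_factor: float


def _squash(z: float, scale: float) -> float:
    return 1.0 / (1.0 + math.exp(-scale * z))


def _score_from_unit(p: float, spec) -> float:
    lo, hi = spec.score_range
    if spec.orientation == HIGHER_IS_DELETERIOUS:
        return lo + p * (hi - lo)
    return hi - p * (hi - lo)


def _sample_profile(
    rng: np.random.Generator, config: CohortConfig, state: str
) -> EvidenceProfile:
    profile = EvidenceProfile()
    for code, p in config.emissions[state].items():
        if rng.random() < p:
            profile.add(AppliedEvidence.make(code))
    if rng.random() < config.insilico_usage:
        p_pp3 = (
            config.p_pp3_given_pathlike
            if state == "PATHOGENIC_LIKE"
            else config.p_pp3_given_benignlike
        )
        code = "PP3" if rng.random() < p_pp3 else "BP4"
        profile.add(AppliedEvidence.make(code, EvidenceStrength.SUPPORTING))
    return profile


def _variant_scores(
    rng: np.random.Generator,
    config: CohortConfig,
    table: CalibrationTable,
    state: str,
) -> tuple[dict[str, float], float]:
    alpha = (
        config.alpha_pathogenic if state == "PATHOGENIC_LIKE" else config.alpha_benign
    )
    g = float(rng.standard_normal())
    noise_w = math.sqrt(1.0 - config.rho**2)
    scores = {}
    for name in table.predictors:
        eps = float(rng.standard_normal())
        z = alpha + config.rho * g + noise_w * eps
        scores[name] = _score_from_unit(
            _squash(z, config.logistic_scale), table.spec(name)
        )
    return scores, g


def generate_cohort(
    config: CohortConfig,
    table: CalibrationTable | None = None,
    options: EngineOptions = DEFAULT_OPTIONS,
) -> tuple[list[VariantRecord], list[LatentVariant]]:
    """Generate a cohort; deterministic given config (including its seed).

    Returns the variant records and, separately, the hidden truth table
    (latent state and shared factor per variant) for validation only —
    pipeline inputs never include it.  Baseline classifications are computed
    by the combining engine from the sampled evidence profiles.
    """
    config.validate()
    if table is None:
        table = default_calibration()

    variants: list[VariantRecord] = []
    truth: list[LatentVariant] = []
    p_ad, p_ar, p_xl = config.moi_mix

    index = 0
    for ds, (n, gene_pool) in config.datasets.items():
        for i in range(n):
            # counter-based stream split: one child seed per variant
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
            )
            index += 1
            key = ("chrS", 1_000_000 + index, "A", "G")
            state = (
                "PATHOGENIC_LIKE"
                if rng.random() < config.pathogenic_fraction
                else "BENIGN_LIKE"
            )
            u = rng.random()
            moi = (
                "AD"
                if u < p_ad
                else "AR"
                if u < p_ad + p_ar
                else "XL"
                if u < p_ad + p_ar + p_xl
                else "UNKNOWN"
            )
            gene = f"{ds}G{int(rng.integers(gene_pool)) + 1}"
            profile = _sample_profile(rng, config, state)
            scores, g = _variant_scores(rng, config, table, state)
            variants.append(
                VariantRecord(
                    key=key,
                    gene=gene,
                    hgnc=f"HGNC:{90000 + index}",
                    transcript=f"NM_{index:06d}.1",
                    hgvs_c=f"c.{i + 1}A>G",
                    dataset=ds,
                    moi=moi,
                    baseline_profile=profile,
                    baseline_class=combine(profile, options),
                    scores=scores,
                )
            )
            truth.append(LatentVariant(key=key, true_state=state, shared_factor=g))
    return variants, truth


def expected_change_fraction(
    config: CohortConfig,
    table: CalibrationTable,
    n_mc: int,
    seed: int,
    predictor: str = "REVEL",
    *,
    single_bs_is_lb: bool = True,
) -> float:
    """Monte-Carlo oracle for the eligible-VUS change fraction.

    Simulates ``n_mc`` variants with the generator's sampling scheme and
    recomputes map → revise → combine *inline*, independently of the
    pipeline code path, so :func:`~vusreclass.pipeline.reclassify_cohort`
    can be validated against it within binomial error.  Returns NaN if no
    simulated variant is an eligible baseline-VUS.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    cfg = config.replace(datasets={"MC": (n_mc, 10)}, seed=seed)
    variants, _ = generate_cohort(cfg, table)

    n_eligible = n_changed = 0
    for v in variants:
        if v.baseline_class is not Classification.VUS:
            continue
        if "PP3" not in v.baseline_profile and "BP4" not in v.baseline_profile:
            continue
        score = v.scores.get(predictor)
        if score is None:
            continue
        n_eligible += 1

        # --- inline threshold lookup (linear scan over intervals) ---
        assign, strength = "NONE", None
        for iv in table.intervals(predictor):
            lo_ok = score > iv.lower or (iv.lower_inclusive and score == iv.lower)
            hi_ok = score < iv.upper or (iv.upper_inclusive and score == iv.upper)
            if lo_ok and hi_ok:
                assign, strength = iv.assignment, iv.strength
                break

        # --- inline evidence swap ---
        items = {e.code: e.strength for e in v.baseline_profile}
        items.pop("PP3", None)
        items.pop("BP4", None)
        if assign != "NONE":
            items[assign] = strength

        # --- inline 2015 combination on strength counts ---
        new_class = _classify_counts(items, single_bs_is_lb=single_bs_is_lb)
        if new_class is not Classification.VUS:
            n_changed += 1

    if n_eligible == 0:
        return float("nan")
    return n_changed / n_eligible


def _classify_counts(
    items: Mapping[str, EvidenceStrength], *, single_bs_is_lb: bool
) -> Classification:
    """Direct transcription of the 2015 combining table on strength counts
    (intentionally separate from the engine implementation)."""
    S = EvidenceStrength
    vs = s = m = p = ba = bs = bsup = 0
    for code, lvl in items.items():
        if code.startswith("P"):
            if lvl is S.VERY_STRONG:
                vs += 1
            elif lvl is S.STRONG:
                s += 1
            elif lvl is S.MODERATE:
                m += 1
            else:
                p += 1
        else:
            if lvl is S.STAND_ALONE:
                ba += 1
            elif lvl in (S.STRONG, S.VERY_STRONG):
                bs += 1
            else:
                bsup += 1
    if ba:
        return Classification.BENIGN
    path = (
        vs >= 2
        or (vs == 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    lp = (
        path
        or (vs == 1 and m == 1)
        or (s == 1 and m in (1, 2))
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    ben = bs >= 2
    lb = ben or (bs == 1 and bsup >= 1) or bsup >= 2 or (single_bs_is_lb and bs >= 1)
    if (lp and lb) or (lb and (vs + s) >= 1) or (lp and bs >= 1):
        return Classification.VUS
    if path:
        return Classification.PATHOGENIC
    if lp:
        return Classification.LIKELY_PATHOGENIC
    if ben:
        return Classification.BENIGN
    if lb:
        return Classification.LIKELY_BENIGN
    return Classification.VUS
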