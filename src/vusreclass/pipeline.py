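"""Per-predictor evidence-swap reclassification.

For each curated variant, the baseline laboratory evidence profile has its
in-silico criteria (PP3/BP4) replaced with the calibrated assignment derived
from one predictor's score; the ACMG 2015 combining rules are then re-run
and the classification transition recorded.  Eligibility follows the study
design: by default only variants whose baseline classification already used
PP3 or BP4 evidence are reclassified.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .acmg import (
    AppliedEvidence,
    Classification,
    EngineOptions,
    DEFAULT_OPTIONS,
    EvidenceProfile,
    EvidenceStrength,
    combine,
)
from .calibration import CalibrationTable, map_score

__all__ = [
    "VariantKey",
    "VariantRecord",
    "EligibilityMode",
    "ReclassificationOutcome",
    "TransitionMatrix",
    "revise_evidence",
    "reclassify_variant",
    "reclassify_cohort",
    "reclassification_percentage",
    "ablate_insilico",
    "UNDEFINED",
]

logger = logging.getLogger(__name__)

#: Marker returned for statistics with an empty denominator.
UNDEFINED = float("nan")

VariantKey = tuple[str, int, str, str]  # chrom, pos (1-based GRCh37), ref, alt

DATASET_LABELS = ("GWS", "RD", "HL", "AI", "CT", "NS", "HSP")
MOI_LABELS = ("AD", "AR", "XL", "UNKNOWN")


class EligibilityMode(Enum):
    """Which variants enter the reclassification denominator."""

    BASELINE_INSILICO_ONLY = "baseline-insilico"  # study default
    ALL = "all"

    @classmethod
    def parse(cls, text: str) -> "EligibilityMode":
        for mode in cls:
            if text in (mode.value, mode.name, mode.name.lower()):
                return mode
        raise ValueError(f"unknown eligibility mode {text!r}")


@dataclass
class VariantRecord:
    """One curated missense variant with baseline evidence and predictor scores."""

    key: VariantKey
    gene: str
    hgnc: str
    transcript: str
    hgvs_c: str
    dataset: str
    moi: str
    baseline_profile: EvidenceProfile
    baseline_class: Classification
    scores: dict[str, float] = field(default_factory=dict)
    as_reported: bool = False  # curated label disagrees with the engine

    def has_insilico(self) -> bool:
        return "PP3" in self.baseline_profile or "BP4" in self.baseline_profile

    def validate_baseline(self, options: EngineOptions = DEFAULT_OPTIONS) -> bool:
        """Check the curated label against the engine; flag the record when
        they disagree (the record keeps its curated label)."""
        engine_class = combine(self.baseline_profile, options)
        self.as_reported = engine_class is not self.baseline_class
        return not self.as_reported


@dataclass(frozen=True)
class ReclassificationOutcome:
    """Result of one (variant, predictor) evidence swap."""

    key: VariantKey
    predictor: str
    assignment: str  # PP3 / BP4 / NONE
    strength: EvidenceStrength | None
    old_class: Classification
    new_class: Classification
    changed: bool
    eligible: bool
    score_missing: bool = False
    dataset: str = ""
    moi: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if self.changed and self.old_class is self.new_class:
            raise ValueError("changed outcome with identical classes")
        if not self.eligible and self.changed:
            raise ValueError("ineligible outcome cannot be changed")

    @property
    def in_denominator(self) -> bool:
        """Counts toward reclassification percentages: eligible with a score."""
        return self.eligible and not self.score_missing


class TransitionMatrix:
    """Counts of (old tier → new tier) over eligible, scored variants."""

    def __init__(self) -> None:
        self.counts: Counter[tuple[Classification, Classification]] = Counter()

    def add(self, old: Classification, new: Classification) -> None:
        self.counts[(old, new)] += 1

    def __getitem__(self, key: tuple[Classification, Classification]) -> int:
        return self.counts[key]

    def row_sum(self, old: Classification) -> int:
        return sum(n for (o, _), n in self.counts.items() if o is old)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_rows(self) -> list[dict]:
        return [
            {"old_class": o.label, "new_class": n.label, "count": c}
            for (o, n), c in sorted(self.counts.items())
        ]


def revise_evidence(
    profile: EvidenceProfile,
    assignment: tuple[str, EvidenceStrength | None],
    *,
    retain_baseline_on_none: bool = False,
) -> EvidenceProfile:
    """Swap baseline in-silico evidence for the calibrated assignment.

    Existing PP3/BP4 entries are removed (never inflated by stacking) and,
    when the assignment is not NONE, the calibrated code is inserted at its
    calibrated strength.  All non-in-silico criteria pass through untouched.
    With ``retain_baseline_on_none`` the baseline PP3/BP4 survives an
    indeterminate score instead of being dropped.
    """
    code, strength = assignment
    revised = profile.copy()
    if code == "NONE":
        if not retain_baseline_on_none:
            revised.remove("PP3")
            revised.remove("BP4")
        return revised
    if code not in ("PP3", "BP4"):
        raise ValueError(f"invalid in-silico assignment {code!r}")
    if strength is None:
        raise ValueError("assignment requires a strength")
    revised.remove("PP3")
    revised.remove("BP4")
    revised.add(AppliedEvidence.make(code, strength))
    return revised


def reclassify_variant(
    variant: VariantRecord,
    predictor: str,
    table: CalibrationTable,
    mode: EligibilityMode = EligibilityMode.BASELINE_INSILICO_ONLY,
    options: EngineOptions = DEFAULT_OPTIONS,
    *,
    retain_baseline_on_none: bool = False,
) -> ReclassificationOutcome:
    """Apply the evidence swap for one predictor to one variant."""
    table.spec(predictor)  # raises KeyError for unknown predictors
    eligible = mode is EligibilityMode.ALL or variant.has_insilico()
    old = variant.baseline_class

    def unchanged(*, eligible: bool, score_missing: bool) -> ReclassificationOutcome:
        return ReclassificationOutcome(
            key=variant.key,
            predictor=predictor,
            assignment="NONE",
            strength=None,
            old_class=old,
            new_class=old,
            changed=False,
            eligible=eligible,
            score_missing=score_missing,
            dataset=variant.dataset,
            moi=variant.moi,
        )

    if not eligible:
        return unchanged(eligible=False, score_missing=predictor not in variant.scores)
    score = variant.scores.get(predictor)
    if score is None:
        return unchanged(eligible=True, score_missing=True)
    try:
        assignment, strength = map_score(predictor, score, table)
    except ValueError as exc:  # out-of-range score: skip for this predictor
        logger.warning("skipping %s for %s: %s", variant.key, predictor, exc)
        return unchanged(eligible=True, score_missing=True)

    revised = revise_evidence(
        variant.baseline_profile,
        (assignment, strength),
        retain_baseline_on_none=retain_baseline_on_none,
    )
    new = combine(revised, options)
    return ReclassificationOutcome(
        key=variant.key,
        predictor=predictor,
        assignment=assignment,
        strength=strength,
        old_class=old,
        new_class=new,
        changed=new is not old,
        eligible=True,
        score_missing=False,
        dataset=variant.dataset,
        moi=variant.moi,
    )


def reclassify_cohort(
    variants: Sequence[VariantRecord],
    predictor: str,
    table: CalibrationTable,
    mode: EligibilityMode = EligibilityMode.BASELINE_INSILICO_ONLY,
    options: EngineOptions = DEFAULT_OPTIONS,
    *,
    retain_baseline_on_none: bool = False,
) -> tuple[list[ReclassificationOutcome], TransitionMatrix]:
    """Run the evidence swap over a cohort; tally transitions of eligible,
    scored variants."""
    outcomes = []
    matrix = TransitionMatrix()
    n_missing = 0
    for v in variants:
        out = reclassify_variant(
            v,
            predictor,
            table,
            mode,
            options,
            retain_baseline_on_none=retain_baseline_on_none,
        )
        outcomes.append(out)
        if out.eligible and out.score_missing:
            n_missing += 1
        if out.in_denominator:
            matrix.add(out.old_class, out.new_class)
    if n_missing:
        logger.info(
            "%s: %d eligible variant(s) lacked a score and were excluded",
            predictor,
            n_missing,
        )
    return outcomes, matrix


def reclassification_percentage(
    outcomes: Iterable[ReclassificationOutcome],
    *,
    old_class: Classification | None = Classification.VUS,
    dataset: str | None = None,
    moi: str | None = None,
) -> float:
    """Percent of in-denominator outcomes in the stratum that changed class.

    The study's headline statistic restricts to baseline-VUS variants
    (``old_class=Classification.VUS``, the default); pass ``old_class=None``
    for an unrestricted percentage.  Returns NaN when the denominator is 0.
    """
    denom = changed = 0
    for out in outcomes:
        if not out.in_denominator:
            continue
        if old_class is not None and out.old_class is not old_class:
            continue
        if dataset is not None and out.dataset != dataset:
            continue
        if moi is not None and out.moi != moi:
            continue
        denom += 1
        changed += out.changed
    if denom == 0:
        return UNDEFINED
    return 100.0 * changed / denom


def ablate_insilico(
    variants: Sequence[VariantRecord],
    options: EngineOptions = DEFAULT_OPTIONS,
) -> list[ReclassificationOutcome]:
    """Reclassify with baseline PP3/BP4 simply removed (no predictor scores).

    Estimates the contribution of in-silico evidence under the original 2015
    supporting-level usage.  The outcome rows carry predictor name
    ``"ACMG2015-no-insilico"``.
    """
    outcomes = []
    for v in variants:
        eligible = v.has_insilico()
        if eligible:
            revised = v.baseline_profile.copy()
            revised.remove("PP3")
            revised.remove("BP4")
            new = combine(revised, options)
        else:
            new = v.baseline_class
        outcomes.append(
            ReclassificationOutcome(
                key=v.key,
                predictor="ACMG2015-no-insilico",
                assignment="NONE",
                strength=None,
                old_class=v.baseline_class,
                new_class=new,
                changed=eligible and new is not v.baseline_class,
                eligible=eligible,
                score_missing=False,
                dataset=v.dataset,
                moi=v.moi,
            )
        )
    return outcomes
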