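"""Calibrated predictor-score thresholds and the score → PP3/BP4 mapping.

ClinGen-style recalibration assigns, per variant effect predictor (VEP), a
partition of the score range into intervals carrying computational evidence:
benign (BP4) intervals at the tolerated end, an indeterminate gap, and
pathogenic (PP3) intervals at the deleterious end, each at an ACMG strength
(Supporting / Moderate / Strong / Very Strong).  The shipped default config
(``data/clingen_calibration.yaml``) transcribes the published ClinGen
recalibrations for REVEL, BayesDel, VEST4, PolyPhen-2, SIFT, VARITY,
AlphaMissense and ESM1b, with a provenance string per predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .acmg import EvidenceStrength

__all__ = [
    "Orientation",
    "PredictorSpec",
    "CalibrationInterval",
    "CalibrationTable",
    "ScoreAnnotation",
    "load_calibration",
    "default_calibration",
    "map_score",
    "annotate_scores",
]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG_RESOURCE = "clingen_calibration.yaml"

HIGHER_IS_DELETERIOUS = "higher_is_deleterious"
LOWER_IS_DELETERIOUS = "lower_is_deleterious"
Orientation = str  # one of the two constants above

_STRENGTH_NAMES = {
    "supporting": EvidenceStrength.SUPPORTING,
    "moderate": EvidenceStrength.MODERATE,
    "strong": EvidenceStrength.STRONG,
    "very_strong": EvidenceStrength.VERY_STRONG,
    "stand_alone": EvidenceStrength.STAND_ALONE,
}


@dataclass(frozen=True)
class PredictorSpec:
    """Identity and score conventions of one predictor."""

    name: str
    orientation: Orientation
    score_range: tuple[float, float]
    model_variant: str | None = None  # e.g. PolyPhen-2 HDIV vs HVAR

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER_IS_DELETERIOUS, LOWER_IS_DELETERIOUS):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        lo, hi = self.score_range
        if not lo < hi:
            raise ValueError(f"empty score range for {self.name}: {self.score_range}")


@dataclass(frozen=True)
class CalibrationInterval:
    """One score interval mapped to an evidence assignment.

    ``assignment`` is "PP3", "BP4" or "NONE"; ``strength`` is present iff the
    assignment is not "NONE".  Endpoints carry explicit inclusivity flags so
    that a score equal to a published threshold earns the evidence on the
    evidence-bearing side.
    """

    lower: float
    upper: float
    assignment: str
    strength: EvidenceStrength | None = None
    lower_inclusive: bool = True
    upper_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.assignment not in ("PP3", "BP4", "NONE"):
            raise ValueError(f"invalid assignment {self.assignment!r}")
        if (self.assignment == "NONE") != (self.strength is None):
            raise ValueError(
                f"strength must be absent iff assignment is NONE "
                f"(got {self.assignment} / {self.strength})"
            )
        if self.lower > self.upper:
            raise ValueError(f"inverted interval [{self.lower}, {self.upper}]")

    def contains(self, score: float) -> bool:
        lo_ok = score > self.lower or (self.lower_inclusive and score == self.lower)
        hi_ok = score < self.upper or (self.upper_inclusive and score == self.upper)
        return lo_ok and hi_ok


@dataclass
class CalibrationTable:
    """Per-predictor ordered calibration intervals with provenance."""

    entries: dict[str, tuple[PredictorSpec, list[CalibrationInterval]]]
    provenance: dict[str, str] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (spec, intervals) in self.entries.items():
            _validate_intervals(name, spec, intervals)

    @property
    def predictors(self) -> list[str]:
        return list(self.entries)

    def spec(self, predictor: str) -> PredictorSpec:
        return self._entry(predictor)[0]

    def intervals(self, predictor: str) -> list[CalibrationInterval]:
        return self._entry(predictor)[1]

    def _entry(self, predictor: str):
        try:
            return self.entries[predictor]
        except KeyError:
            raise KeyError(
                f"unknown predictor {predictor!r}; known: {sorted(self.entries)}"
            ) from None

    def canonical_name(self, column: str) -> str | None:
        """Map an annotation-tool column header to a canonical predictor name."""
        if column in self.entries:
            return column
        return self.aliases.get(column) or self.aliases.get(column.lower())


def _validate_intervals(
    name: str, spec: PredictorSpec, intervals: list[CalibrationInterval]
) -> None:
    if not intervals:
        raise ValueError(f"{name}: no calibration intervals")
    ivs = sorted(intervals, key=lambda iv: (iv.lower, iv.upper))
    lo, hi = spec.score_range
    # coverage of the lower edge
    first, last = ivs[0], ivs[-1]
    if first.lower > lo or (first.lower == lo and not first.lower_inclusive):
        raise ValueError(f"{name}: gap at lower range edge before {first}")
    if last.upper < hi or (last.upper == hi and not last.upper_inclusive):
        raise ValueError(f"{name}: gap at upper range edge after {last}")
    for a, b in zip(ivs, ivs[1:]):
        if a.upper > b.lower:
            raise ValueError(f"{name}: overlapping intervals {a} and {b}")
        if a.upper == b.lower:
            if a.upper_inclusive and b.lower_inclusive:
                raise ValueError(
                    f"{name}: overlapping intervals at shared endpoint {a.upper}: {a} / {b}"
                )
            if not a.upper_inclusive and not b.lower_inclusive:
                raise ValueError(
                    f"{name}: gap at shared endpoint {a.upper}: {a} / {b}"
                )
        else:
            raise ValueError(
                f"{name}: gap between intervals {a} and {b}"
            )
    _validate_monotone(name, spec, ivs)


def _validate_monotone(
    name: str, spec: PredictorSpec, ivs: list[CalibrationInterval]
) -> None:
    """Along the deleterious direction, evidence must run BP4-weakening →
    NONE → PP3-strengthening."""
    ordered = ivs if spec.orientation == HIGHER_IS_DELETERIOUS else ivs[::-1]
    # encode each interval on a single pathogenicity axis
    def key(iv: CalibrationInterval) -> int:
        if iv.assignment == "NONE":
            return 0
        sign = 1 if iv.assignment == "PP3" else -1
        return sign * int(iv.strength)

    keys = [key(iv) for iv in ordered]
    if any(b < a for a, b in zip(keys, keys[1:])):
        raise ValueError(
            f"{name}: evidence strengths not monotone along the deleterious direction"
        )


def load_calibration(source: str | Path | Mapping) -> CalibrationTable:
    """Load and validate a calibration config (YAML path or parsed mapping).

    Schema::

        aliases: {column_header: PredictorName, ...}   # optional
        predictors:
          NAME:
            orientation: higher_is_deleterious | lower_is_deleterious
            range: [lo, hi]
            model_variant: HVAR          # optional
            provenance: free text
            intervals:
              - {lo: ..., lo_incl: true, hi: ..., hi_incl: false,
                 assign: PP3|BP4|NONE, strength: strong}   # strength absent for NONE
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "predictors" not in doc:
        raise ValueError("calibration config must contain a 'predictors' mapping")

    entries: dict[str, tuple[PredictorSpec, list[CalibrationInterval]]] = {}
    provenance: dict[str, str] = {}
    for name, block in doc["predictors"].items():
        spec = PredictorSpec(
            name=name,
            orientation=block["orientation"],
            score_range=tuple(float(x) for x in block["range"]),
            model_variant=block.get("model_variant"),
        )
        intervals = []
        for iv in block["intervals"]:
            strength = iv.get("strength")
            intervals.append(
                CalibrationInterval(
                    lower=float(iv["lo"]),
                    upper=float(iv["hi"]),
                    assignment=iv["assign"],
                    strength=_STRENGTH_NAMES[strength.lower()] if strength else None,
                    lower_inclusive=bool(iv.get("lo_incl", True)),
                    upper_inclusive=bool(iv.get("hi_incl", False)),
                )
            )
        entries[name] = (spec, intervals)
        provenance[name] = str(block.get("provenance", ""))

    aliases = {str(k): str(v) for k, v in (doc.get("aliases") or {}).items()}
    return CalibrationTable(entries=entries, provenance=provenance, aliases=aliases)


def default_calibration() -> CalibrationTable:
    """The shipped ClinGen-recalibration config (eight predictors)."""
    ref = resources.files("vusreclass.data").joinpath(DEFAULT_CONFIG_RESOURCE)
    with resources.as_file(ref) as path:
        return load_calibration(path)


def map_score(
    predictor: str, score: float, table: CalibrationTable
) -> tuple[str, EvidenceStrength | None]:
    """Map a raw predictor score to its calibrated evidence assignment.

    Returns ``(assignment, strength)`` where assignment is "PP3", "BP4" or
    "NONE" and strength is None iff the assignment is "NONE".

    Raises
    ------
    KeyError
        Unknown predictor.
    ValueError
        Score outside the predictor's declared range.
    """
    spec = table.spec(predictor)
    lo, hi = spec.score_range
    if not (lo <= score <= hi):
        raise ValueError(
            f"{predictor} score {score} outside declared range [{lo}, {hi}]"
        )
    for iv in table.intervals(predictor):
        if iv.contains(score):
            return iv.assignment, iv.strength
    raise AssertionError(  # pragma: no cover - precluded by validation
        f"{predictor}: no interval contains in-range score {score}"
    )


@dataclass(frozen=True)
class ScoreAnnotation:
    """Precomputed predictor scores for one variant (hg19/GRCh37 key)."""

    key: tuple[str, int, str, str]  # chrom, pos (1-based), ref, alt
    scores: Mapping[str, float]


def annotate_scores(variants, annotations: Iterable[ScoreAnnotation]) -> list:
    """Left-join predictor scores onto variant records on (chrom, pos, ref, alt).

    Unmatched variants keep empty score maps.  Per-predictor missingness is
    logged.  Duplicate annotation keys are rejected.
    """
    by_key: dict[tuple, ScoreAnnotation] = {}
    for ann in annotations:
        if ann.key in by_key:
            raise ValueError(f"duplicate score annotation for variant key {ann.key}")
        by_key[ann.key] = ann

    predictors: set[str] = set()
    for ann in by_key.values():
        predictors.update(ann.scores)
    missing: dict[str, int] = {p: 0 for p in sorted(predictors)}

    variants = list(variants)
    for v in variants:
        ann = by_key.get(v.key)
        if ann is not None:
            v.scores = {p: s for p, s in ann.scores.items() if s is not None}
        else:
            v.scores = {}
        for p in missing:
            if p not in v.scores:
                missing[p] += 1
    for p, n in missing.items():
        if n:
            logger.info("annotate_scores: %s missing for %d/%d variants", p, n, len(variants))
    return variants
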