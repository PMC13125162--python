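"""Cohort summary statistics: reclassification rates, inter-predictor
concordance, Fisher-exact odds ratios and mode-of-inheritance comparisons.

Concordance between two predictors is measured over baseline-VUS variants
reclassified by either: the percentage reclassified by both *to the same
tier* out of the union (a destination-agnostic variant is available).  Odds
ratios are sample ORs with 95% Woolf (logit) confidence intervals and exact
two-sided Fisher p-values; the conditional-MLE OR is carried alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .acmg import Classification
from .pipeline import ReclassificationOutcome, UNDEFINED, VariantRecord

__all__ = [
    "ConcordanceCell",
    "ConcordanceReport",
    "OddsRatioResult",
    "MOIComparison",
    "pairwise_concordance",
    "concordance_matrix",
    "fisher_exact_or",
    "vus_likelihood_or",
    "median_reclassification",
    "moi_stratify",
    "build_summary",
]


def _is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass(frozen=True)
class ConcordanceCell:
    """Agreement between two predictors' VUS reclassifications in one dataset."""

    predictor_a: str
    predictor_b: str
    dataset: str
    n_concordant: int
    n_union: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_concordant <= self.n_union:
            raise ValueError("n_concordant must lie in [0, n_union]")

    @property
    def pct(self) -> float:
        if self.n_union == 0:
            return UNDEFINED
        return 100.0 * self.n_concordant / self.n_union


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 association: sample OR, Woolf 95% CI, exact p-value."""

    table: tuple[tuple[int, int], tuple[int, int]]
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    or_cmle: float = float("nan")  # conditional-MLE flavor, for reference
    haldane_corrected: bool = False


@dataclass(frozen=True)
class MOIComparison:
    """AD-vs-AR reclassification contrast for one predictor."""

    predictor: str
    ad_changed: int
    ad_unchanged: int
    ar_changed: int
    ar_unchanged: int
    testable: bool
    result: OddsRatioResult | None = None


def _changed_vus(outcomes: Iterable[ReclassificationOutcome]):
    """Map variant key -> destination tier, over changed baseline-VUS outcomes."""
    dest = {}
    keys = set()
    for out in outcomes:
        keys.add(out.key)
        if (
            out.in_denominator
            and out.old_class is Classification.VUS
            and out.changed
        ):
            dest[out.key] = out.new_class
    return dest, keys


def pairwise_concordance(
    outcomes_a: Sequence[ReclassificationOutcome],
    outcomes_b: Sequence[ReclassificationOutcome],
    *,
    dataset: str = "",
    destination_agnostic: bool = False,
) -> ConcordanceCell:
    """Concordance of VUS reclassifications between two predictors.

    The union counts variants reclassified by either predictor; concordant
    variants were reclassified by both to the same destination tier (or
    merely by both, when ``destination_agnostic``).  The two outcome sets
    must cover the same cohort.
    """
    dest_a, keys_a = _changed_vus(outcomes_a)
    dest_b, keys_b = _changed_vus(outcomes_b)
    if keys_a != keys_b:
        raise ValueError("outcome sets cover different cohorts")
    pred_a = outcomes_a[0].predictor if outcomes_a else "a"
    pred_b = outcomes_b[0].predictor if outcomes_b else "b"

    union = set(dest_a) | set(dest_b)
    both = set(dest_a) & set(dest_b)
    if destination_agnostic:
        concordant = both
    else:
        concordant = {k for k in both if dest_a[k] is dest_b[k]}
    return ConcordanceCell(
        predictor_a=pred_a,
        predictor_b=pred_b,
        dataset=dataset,
        n_concordant=len(concordant),
        n_union=len(union),
    )


@dataclass
class ConcordanceReport:
    """All pairwise cells plus per-predictor medians and 100%-cell counts."""

    cells: list[ConcordanceCell]
    predictor_medians: dict[str, float]
    n_cells: int
    n_full_concordance: int
    n_undefined: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "predictor_a": c.predictor_a,
                    "predictor_b": c.predictor_b,
                    "dataset": c.dataset,
                    "n_concordant": c.n_concordant,
                    "n_union": c.n_union,
                    "pct": round(c.pct, 2) if not _is_undefined(c.pct) else np.nan,
                }
                for c in self.cells
            ]
        )


def concordance_matrix(
    outcomes_by_predictor: Mapping[str, Sequence[ReclassificationOutcome]],
    datasets: Sequence[str] | None = None,
    *,
    destination_agnostic: bool = False,
) -> ConcordanceReport:
    """One concordance cell per unordered predictor pair per dataset.

    Cells with an empty union have undefined percentage; they are excluded
    from the per-predictor medians and counted separately.
    """
    predictors = list(outcomes_by_predictor)
    if len(predictors) < 2:
        raise ValueError("concordance requires at least two predictors")
    if datasets is None:
        seen = []
        for outs in outcomes_by_predictor.values():
            for out in outs:
                if out.dataset not in seen:
                    seen.append(out.dataset)
        datasets = seen

    cells: list[ConcordanceCell] = []
    for ds in datasets:
        per_pred = {
            p: [o for o in outs if o.dataset == ds]
            for p, outs in outcomes_by_predictor.items()
        }
        for a, b in itertools.combinations(predictors, 2):
            cell = pairwise_concordance(
                per_pred[a],
                per_pred[b],
                dataset=ds,
                destination_agnostic=destination_agnostic,
            )
            # pairwise_concordance infers names from rows; pin them explicitly
            cells.append(
                ConcordanceCell(
                    predictor_a=a,
                    predictor_b=b,
                    dataset=ds,
                    n_concordant=cell.n_concordant,
                    n_union=cell.n_union,
                )
            )

    medians: dict[str, float] = {}
    for p in predictors:
        vals = [
            c.pct
            for c in cells
            if p in (c.predictor_a, c.predictor_b) and not _is_undefined(c.pct)
        ]
        medians[p] = median(vals) if vals else UNDEFINED
    defined = [c for c in cells if not _is_undefined(c.pct)]
    return ConcordanceReport(
        cells=cells,
        predictor_medians=medians,
        n_cells=len(cells),
        n_full_concordance=sum(1 for c in defined if c.pct == 100.0),
        n_undefined=len(cells) - len(defined),
    )


def fisher_exact_or(
    table: Sequence[Sequence[int]] | np.ndarray,
) -> OddsRatioResult:
    """Two-sided Fisher exact test with sample OR and Woolf 95% CI.

    The p-value is the sum of hypergeometric probabilities not exceeding the
    observed table's.  With a zero cell the Haldane-Anscombe 0.5 correction
    is applied to the OR and CI (flagged); the p-value stays exact.
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        raise ValueError("both margins must be positive")
    _, p_value = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    or_point = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(or_point) - 1.959963984540054 * se)
    ci_high = math.exp(math.log(or_point) + 1.959963984540054 * se)
    or_cmle = sps.contingency.odds_ratio(
        [[a, b], [c, d]], kind="conditional"
    ).statistic
    return OddsRatioResult(
        table=((a, b), (c, d)),
        or_point=or_point,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p_value),
        or_cmle=float(or_cmle),
        haldane_corrected=corrected,
    )


def build_summary(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    """Dataset-level composition: n, unique genes, tier counts/percentages,
    PP3/BP4 usage.  Percentages are integer-rounded (half away from zero) in
    the ``*_pct`` columns, as in the human-readable cohort table."""
    rows = []
    datasets: list[str] = []
    for v in variants:
        if v.dataset not in datasets:
            datasets.append(v.dataset)
    for ds in datasets:
        sub = [v for v in variants if v.dataset == ds]
        n = len(sub)
        row: dict = {"dataset": ds, "n": n, "unique_genes": len({v.gene for v in sub})}
        for tier in Classification:
            count = sum(1 for v in sub if v.baseline_class is tier)
            row[f"{tier.label}_n"] = count
            row[f"{tier.label}_pct"] = _round_half_away(100.0 * count / n) if n else 0
        for code in ("PP3", "BP4"):
            count = sum(1 for v in sub if code in v.baseline_profile)
            row[f"{code}_n"] = count
            row[f"{code}_pct"] = _round_half_away(100.0 * count / n) if n else 0
        rows.append(row)
    return pd.DataFrame(rows)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def vus_likelihood_or(
    summary: pd.DataFrame,
    focal: str,
    comparison: Sequence[str],
) -> OddsRatioResult:
    """Odds of a VUS call in the focal dataset versus the pooled comparators.

    Builds the 2x2 (focal VUS, focal non-VUS; pooled VUS, pooled non-VUS)
    from a :func:`build_summary` frame and delegates to
    :func:`fisher_exact_or`.
    """
    if focal in comparison:
        raise ValueError("focal dataset cannot appear among the comparators")
    idx = summary.set_index("dataset")
    if not comparison:
        raise ValueError("empty comparison pool")
    vus_col = Classification.VUS.label + "_n"
    f_vus = int(idx.loc[focal, vus_col])
    f_non = int(idx.loc[focal, "n"]) - f_vus
    pool = idx.loc[list(comparison)]
    p_vus = int(pool[vus_col].sum())
    p_non = int(pool["n"].sum()) - p_vus
    return fisher_exact_or([[f_vus, f_non], [p_vus, p_non]])


def median_reclassification(values: Iterable[float]) -> float:
    """Median after removing undefined (NaN) entries; NaN when empty."""
    vals = [v for v in values if not _is_undefined(v)]
    if not vals:
        return UNDEFINED
    return float(median(vals))


def moi_stratify(
    outcomes_by_predictor: Mapping[str, Sequence[ReclassificationOutcome]],
    *,
    old_class: Classification | None = Classification.VUS,
) -> list[MOIComparison]:
    """AD-vs-AR change contrast per predictor; XL/UNKNOWN are excluded.

    A predictor is not testable when either autosomal stratum is empty
    (mirroring the insufficient-X-linked situation at the cohort level).
    """
    comparisons = []
    for predictor, outcomes in outcomes_by_predictor.items():
        counts = {("AD", True): 0, ("AD", False): 0, ("AR", True): 0, ("AR", False): 0}
        for out in outcomes:
            if not out.in_denominator or out.moi not in ("AD", "AR"):
                continue
            if old_class is not None and out.old_class is not old_class:
                continue
            counts[(out.moi, out.changed)] += 1
        ad_c, ad_u = counts[("AD", True)], counts[("AD", False)]
        ar_c, ar_u = counts[("AR", True)], counts[("AR", False)]
        testable = (ad_c + ad_u) > 0 and (ar_c + ar_u) > 0
        result = (
            fisher_exact_or([[ad_c, ad_u], [ar_c, ar_u]]) if testable else None
        )
        comparisons.append(
            MOIComparison(
                predictor=predictor,
                ad_changed=ad_c,
                ad_unchanged=ad_u,
                ar_changed=ar_c,
                ar_unchanged=ar_u,
                testable=testable,
                result=result,
            )
        )
    return comparisons
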