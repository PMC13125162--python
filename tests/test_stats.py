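"""Concordance, odds ratios, medians and cohort summaries."""

from __future__ import annotations

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from vusreclass.acmg import Classification, EvidenceProfile, EvidenceStrength
from vusreclass.pipeline import ReclassificationOutcome, VariantRecord
from vusreclass.stats import (
    ConcordanceCell,
    build_summary,
    concordance_matrix,
    fisher_exact_or,
    median_reclassification,
    moi_stratify,
    pairwise_concordance,
    vus_likelihood_or,
)

from conftest import COHORT_COMPOSITION

C = Classification


def outcome(pos, predictor, new_class=C.LIKELY_PATHOGENIC, changed=True,
            dataset="GWS", moi="AD", old_class=C.VUS, eligible=True):
    return ReclassificationOutcome(
        key=("1", pos, "A", "G"),
        predictor=predictor,
        assignment="PP3" if changed else "NONE",
        strength=EvidenceStrength.STRONG if changed else None,
        old_class=old_class,
        new_class=new_class if changed else old_class,
        changed=changed,
        eligible=eligible,
        dataset=dataset,
        moi=moi,
    )


def cohort_outcomes(predictor, changed_positions, destinations=None, n=50, dataset="GWS"):
    destinations = destinations or {}
    outs = []
    for pos in range(n):
        ch = pos in changed_positions
        outs.append(
            outcome(
                pos,
                predictor,
                new_class=destinations.get(pos, C.LIKELY_PATHOGENIC),
                changed=ch,
                dataset=dataset,
            )
        )
    return outs


class TestPairwiseConcordance:
    def test_identical_changed_sets_and_destinations_are_100(self):
        a = cohort_outcomes("A", {1, 2, 3})
        b = cohort_outcomes("B", {1, 2, 3})
        cell = pairwise_concordance(a, b)
        assert cell.pct == 100.0
        assert (cell.n_concordant, cell.n_union) == (3, 3)

    def test_disjoint_changed_sets_are_0(self):
        a = cohort_outcomes("A", {1, 2})
        b = cohort_outcomes("B", {3, 4})
        assert pairwise_concordance(a, b).pct == 0.0

    def test_printed_worked_example_27_of_28(self):
        a = cohort_outcomes("A", set(range(28)))
        b = cohort_outcomes("B", set(range(27)))
        cell = pairwise_concordance(a, b)
        assert (cell.n_concordant, cell.n_union) == (27, 28)
        assert round(cell.pct, 2) == 96.43

    def test_destination_disagreement_not_concordant(self):
        a = cohort_outcomes("A", {1, 2}, destinations={1: C.LIKELY_PATHOGENIC})
        b = cohort_outcomes("B", {1, 2}, destinations={1: C.LIKELY_BENIGN})
        strict = pairwise_concordance(a, b)
        assert (strict.n_concordant, strict.n_union) == (1, 2)
        agnostic = pairwise_concordance(a, b, destination_agnostic=True)
        assert agnostic.n_concordant == 2

    def test_symmetry(self):
        a = cohort_outcomes("A", {1, 2, 5})
        b = cohort_outcomes("B", {2, 5, 9})
        ab, ba = pairwise_concordance(a, b), pairwise_concordance(b, a)
        assert (ab.n_concordant, ab.n_union) == (ba.n_concordant, ba.n_union)

    def test_mismatched_cohorts_rejected(self):
        a = cohort_outcomes("A", {1}, n=10)
        b = cohort_outcomes("B", {1}, n=12)
        with pytest.raises(ValueError, match="cohort"):
            pairwise_concordance(a, b)

    def test_non_vus_baselines_excluded(self):
        a = cohort_outcomes("A", {1}) + [
            outcome(99, "A", old_class=C.LIKELY_PATHOGENIC, new_class=C.PATHOGENIC)
        ]
        b = cohort_outcomes("B", {1}) + [
            outcome(99, "B", old_class=C.LIKELY_PATHOGENIC, changed=False)
        ]
        cell = pairwise_concordance(a, b)
        assert cell.n_union == 1


class TestConcordanceMatrix:
    def test_8_predictors_7_datasets_yield_196_cells(self):
        preds = [f"P{i}" for i in range(8)]
        datasets = ["GWS", "RD", "HL", "AI", "CT", "NS", "HSP"]
        by_pred = {
            p: [
                o
                for ds in datasets
                for o in cohort_outcomes(p, {0, 1}, n=5, dataset=ds)
            ]
            for p in preds
        }
        report = concordance_matrix(by_pred, datasets)
        assert report.n_cells == 196
        assert report.n_full_concordance == 196

    def test_two_predictors_one_dataset(self):
        by_pred = {"A": cohort_outcomes("A", {1}), "B": cohort_outcomes("B", {1})}
        report = concordance_matrix(by_pred)
        assert report.n_cells == 1

    def test_per_predictor_median(self):
        # hand-built cells {100, 90, 80} for predictor A across three datasets
        datasets = ["D1", "D2", "D3"]
        a, b = [], []
        specs = {"D1": (10, 10), "D2": (9, 10), "D3": (8, 10)}
        for ds, (n_conc, n_union) in specs.items():
            a.extend(cohort_outcomes("A", set(range(n_union)), n=20, dataset=ds))
            b.extend(cohort_outcomes("B", set(range(n_conc)), n=20, dataset=ds))
        report = concordance_matrix({"A": a, "B": b}, datasets)
        assert report.predictor_medians["A"] == 90.0

    def test_empty_union_cells_undefined_and_counted(self):
        by_pred = {
            "A": cohort_outcomes("A", set(), n=5),
            "B": cohort_outcomes("B", set(), n=5),
        }
        report = concordance_matrix(by_pred)
        assert report.n_undefined == 1
        assert math.isnan(report.predictor_medians["A"])

    def test_requires_two_predictors(self):
        with pytest.raises(ValueError):
            concordance_matrix({"A": cohort_outcomes("A", {1})})


class TestFisherExactOr:
    def test_printed_vus_likelihood_or(self):
        res = fisher_exact_or([[604, 206], [5138, 1273]])
        assert round(res.or_point, 2) == 0.73
        assert round(res.ci_low, 2) == 0.61
        assert round(res.ci_high, 2) == 0.86
        assert res.p_value < 0.05
        assert not res.haldane_corrected

    def test_proportional_table_gives_or_1(self):
        res = fisher_exact_or([[12, 30], [24, 60]])
        assert res.or_point == pytest.approx(1.0)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_haldane_correction_on_zero_cell(self):
        res = fisher_exact_or([[1, 0], [0, 1]])
        assert res.haldane_corrected
        assert res.or_point == pytest.approx(9.0)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_or([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            fisher_exact_or([[-1, 2], [3, 4]])

    def test_p_value_matches_hypergeometric_enumeration(self):
        from oracles import fisher_p_two_sided

        tables = [
            (2, 8, 10, 5),
            (0, 10, 10, 0),
            (5, 5, 5, 5),
            (1, 14, 13, 2),
            (7, 3, 2, 9),
            (3, 0, 12, 15),
        ]
        for a, b, c, d in tables:
            res = fisher_exact_or([[a, b], [c, d]])
            assert res.p_value == pytest.approx(
                fisher_p_two_sided(a, b, c, d), rel=1e-9
            ), (a, b, c, d)

    def test_ci_brackets_point_estimate(self):
        for table in ([[3, 7], [9, 2]], [[20, 5], [8, 16]]):
            res = fisher_exact_or(table)
            assert res.ci_low <= res.or_point <= res.ci_high


def _cohort_composition_variants():
    """Materialize variants realizing the printed per-dataset counts."""
    variants = []
    pos = 0
    for ds, row in COHORT_COMPOSITION.items():
        tiers = (
            [C.BENIGN] * row["B"]
            + [C.LIKELY_BENIGN] * row["LB"]
            + [C.VUS] * row["VUS"]
            + [C.LIKELY_PATHOGENIC] * row["LP"]
            + [C.PATHOGENIC] * row["P"]
        )
        for i, tier in enumerate(tiers):
            pos += 1
            if i < row["PP3"]:
                evidence = "PM2,PP3"
            elif i < row["PP3"] + row["BP4"]:
                evidence = "PM2,BP4"
            else:
                evidence = "PM2"
            variants.append(
                VariantRecord(
                    key=("1", pos, "A", "G"),
                    gene=f"{ds}G{i % row['genes']}",
                    hgnc="HGNC:1",
                    transcript="NM_0.1",
                    hgvs_c="c.1A>G",
                    dataset=ds,
                    moi="AD",
                    baseline_profile=EvidenceProfile.parse(evidence),
                    baseline_class=tier,
                )
            )
    return variants


class TestBuildSummary:
    def test_reproduces_printed_cohort_percentages(self):
        summary = build_summary(_cohort_composition_variants()).set_index("dataset")
        gws = summary.loc["GWS"]
        assert gws["n"] == 810
        assert gws["VUS_n"] == 604 and gws["VUS_pct"] == 75
        assert gws["PP3_n"] == 303 and gws["PP3_pct"] == 37
        assert gws["unique_genes"] == 550
        hl = summary.loc["HL"]
        assert hl["VUS_pct"] == 86 and hl["PP3_pct"] == 34
        rd = summary.loc["RD"]
        assert rd["VUS_pct"] == 62 and rd["PP3_pct"] == 30

    def test_counts_sum_to_n(self):
        summary = build_summary(_cohort_composition_variants())
        tier_cols = [f"{t.label}_n" for t in C]
        assert (summary[tier_cols].sum(axis=1) == summary["n"]).all()

    def test_empty_cohort_gives_empty_frame(self):
        assert build_summary([]).empty


class TestVusLikelihoodOr:
    def test_gws_versus_pooled_panels(self):
        summary = build_summary(_cohort_composition_variants())
        panels = [ds for ds in COHORT_COMPOSITION if ds != "GWS"]
        res = vus_likelihood_or(summary, "GWS", panels)
        assert round(res.or_point, 2) == 0.73
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.61, 0.86)

    def test_pooling_order_invariance(self):
        summary = build_summary(_cohort_composition_variants())
        panels = [ds for ds in COHORT_COMPOSITION if ds != "GWS"]
        a = vus_likelihood_or(summary, "GWS", panels)
        b = vus_likelihood_or(summary, "GWS", panels[::-1])
        assert a.or_point == b.or_point and a.p_value == b.p_value

    def test_identical_fraction_gives_or_1(self):
        variants = [
            v
            for v in _cohort_composition_variants()
            if v.dataset in ("RD",)
        ]
        # compare RD against a copy of itself relabelled
        clones = []
        for v in variants:
            clones.append(
                VariantRecord(
                    key=("2", v.key[1], "A", "G"),
                    gene=v.gene,
                    hgnc=v.hgnc,
                    transcript=v.transcript,
                    hgvs_c=v.hgvs_c,
                    dataset="RD2",
                    moi=v.moi,
                    baseline_profile=v.baseline_profile,
                    baseline_class=v.baseline_class,
                )
            )
        summary = build_summary(variants + clones)
        res = vus_likelihood_or(summary, "RD", ["RD2"])
        assert res.or_point == pytest.approx(1.0)

    def test_focal_in_pool_rejected(self):
        summary = build_summary(_cohort_composition_variants())
        with pytest.raises(ValueError):
            vus_likelihood_or(summary, "GWS", ["GWS", "RD"])


class TestMedian:
    def test_odd_count(self):
        assert median_reclassification([3, 5, 7]) == 5

    def test_even_count_mean_of_central_pair(self):
        assert median_reclassification([90.68, 100]) == pytest.approx(95.34)

    def test_nan_entries_dropped(self):
        assert median_reclassification([float("nan"), 4.0, 6.0]) == 5.0

    def test_empty_is_undefined(self):
        assert math.isnan(median_reclassification([]))

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=20))
    def test_permutation_invariant_and_bounded(self, values):
        m = median_reclassification(values)
        assert min(values) <= m <= max(values)
        assert m == median_reclassification(sorted(values))


class TestMoiStratify:
    def _outcomes(self, ad_changed, ad_total, ar_changed, ar_total):
        outs = []
        pos = 0
        for moi, n_changed, n_total in (
            ("AD", ad_changed, ad_total),
            ("AR", ar_changed, ar_total),
        ):
            for i in range(n_total):
                outs.append(outcome(pos, "X", changed=i < n_changed, moi=moi))
                pos += 1
        return outs

    def test_equal_rates_give_or_1(self):
        comp = moi_stratify({"X": self._outcomes(5, 50, 5, 50)})[0]
        assert comp.testable
        assert comp.result.or_point == pytest.approx(1.0)

    def test_printed_style_arithmetic(self):
        comp = moi_stratify({"X": self._outcomes(10, 100, 5, 100)})[0]
        assert comp.result.or_point == pytest.approx((10 * 95) / (90 * 5))

    def test_empty_stratum_not_testable(self):
        comp = moi_stratify({"X": self._outcomes(3, 30, 0, 0)})[0]
        assert not comp.testable and comp.result is None

    def test_xl_and_unknown_excluded(self):
        outs = self._outcomes(5, 50, 5, 50)
        outs += [outcome(1000 + i, "X", changed=True, moi="XL") for i in range(10)]
        comp = moi_stratify({"X": outs})[0]
        assert comp.ad_changed + comp.ad_unchanged == 50
        assert comp.ar_changed + comp.ar_unchanged == 50
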