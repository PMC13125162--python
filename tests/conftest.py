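"""Shared fixtures: the shipped calibration, printed-table anchors and a
synthetic reconstruction of the six VUS-to-Benign variants."""

from __future__ import annotations

import pytest
from hypothesis import settings

from vusreclass.acmg import Classification, EvidenceProfile
from vusreclass.calibration import default_calibration
from vusreclass.pipeline import VariantRecord

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_table():
    return default_calibration()


#: Cohort composition as printed in the study's dataset-characteristics
#: table: n, unique genes, tier counts (B, LB, VUS, LP, P) and PP3/BP4 usage.
COHORT_COMPOSITION = {
    "GWS": dict(n=810, genes=550, B=1, LB=0, VUS=604, LP=122, P=83, PP3=303, BP4=173),
    "RD": dict(n=542, genes=41, B=88, LB=43, VUS=335, LP=66, P=10, PP3=165, BP4=122),
    "HL": dict(n=2472, genes=67, B=122, LB=141, VUS=2130, LP=57, P=22, PP3=849, BP4=445),
    "AI": dict(n=717, genes=35, B=61, LB=52, VUS=590, LP=11, P=3, PP3=136, BP4=235),
    "CT": dict(n=1563, genes=79, B=149, LB=92, VUS=1245, LP=48, P=29, PP3=438, BP4=310),
    "NS": dict(n=397, genes=15, B=52, LB=14, VUS=228, LP=28, P=75, PP3=174, BP4=29),
    "HSP": dict(n=720, genes=40, B=34, LB=39, VUS=610, LP=19, P=18, PP3=208, BP4=185),
}

#: The six printed (predictor, score) pairs behind the VUS-to-Benign rows.
BENIGN_RECLASS_SCORES = [
    ("REVEL", 0.014),
    ("VARITY", 0.032904),
    ("VARITY", 0.021316),
    ("VARITY", 0.020728),
    ("VARITY", 0.012199),
    ("VARITY", 0.019462),
]

_BENIGN_RECLASS_VARIANTS = [
    # gene, hgnc, chrom, pos, ref, alt, transcript, hgvs_c, predictor, score
    ("ADGRV1", "17416", "5", 89938764, "A", "G", "NM_032119.4", "c.2459A>G", "REVEL", 0.014),
    ("USH2A", "12601", "1", 216011445, "C", "T", "NM_206933.4", "c.9259G>A", "VARITY", 0.032904),
    ("WFS1", "12762", "4", 6279355, "C", "T", "NM_006005.3", "c.173C>T", "VARITY", 0.021316),
    ("GSDME", "2810", "7", 24784260, "C", "T", "NM_001127453.2", "c.325G>A", "VARITY", 0.020728),
    ("CHD7", "20626", "8", 61765978, "A", "G", "NM_017780.4", "c.6694A>G", "VARITY", 0.012199),
    ("MYH14", "23212", "19", 50783609, "C", "T", "NM_001145809.2", "c.4259C>T", "VARITY", 0.019462),
]

#: The 49 printed concordance percentages for the VARITY row block
#: (seven comparators x seven datasets).
VARITY_CONCORDANCE_PCTS = [
    96.43, 85.29, 90.68, 82.69, 97.5, 97.14, 91.18,   # vs AlphaMissense
    84.62, 81.48, 88.24, 79.49, 95.56, 96.15, 86.96,  # vs ESM1b
    95, 90, 92.17, 83.05, 97.01, 96.3, 93.1,          # vs REVEL
    88.24, 88.89, 91.09, 81.63, 96.97, 95.45, 91.67,  # vs VEST4
    94.44, 90.74, 90.65, 100, 96.92, 96, 92.31,       # vs BayesDel
    80, 86.67, 86.57, 75.76, 95.92, 93.75, 81.25,     # vs SIFT
    0, 75, 83.33, 71.43, 94.12, 85.71, 40,            # vs PolyPhen-2
]


@pytest.fixture(scope="session")
def benign_reclass_variants() -> list[VariantRecord]:
    """Synthetic reconstruction of the six hearing-loss VUS-to-Benign rows.

    The non-computational baseline evidence is not published; each record
    assumes a {BS1, BP4_Supporting} baseline with the curated VUS label kept
    as reported (so the curated label intentionally disagrees with the
    engine's reading of the assumed profile).
    """
    records = []
    for gene, hgnc, chrom, pos, ref, alt, tx, hgvs, pred, score in _BENIGN_RECLASS_VARIANTS:
        records.append(
            VariantRecord(
                key=(chrom, pos, ref, alt),
                gene=gene,
                hgnc=f"HGNC:{hgnc}",
                transcript=tx,
                hgvs_c=hgvs,
                dataset="HL",
                moi="AR",
                baseline_profile=EvidenceProfile.parse("BS1,BP4"),
                baseline_class=Classification.VUS,
                scores={pred: score},
            )
        )
    return records
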