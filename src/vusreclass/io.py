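"""Tabular round-tripping for variant tables, score tables and outcomes.

All tables are tab-separated UTF-8 with a header row; missing values are
empty cells.  Variant identity is the (chrom, pos, ref, alt) 4-tuple on
GRCh37; duplicate keys are allowed across datasets but rejected within one.
An optional VCF 4.2 reader accepts the same evidence payload through
``EVID``, ``DATASET``, ``MOI`` and ``BASECLASS`` INFO keys.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .acmg import Classification, EvidenceProfile
from .calibration import CalibrationTable, ScoreAnnotation
from .pipeline import ReclassificationOutcome, TransitionMatrix, VariantRecord

__all__ = [
    "read_variants",
    "write_variants",
    "read_variants_vcf",
    "read_scores",
    "write_scores",
    "write_outcomes",
    "read_outcomes",
    "write_transitions",
]

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "hgnc",
    "transcript",
    "hgvs_c",
    "dataset",
    "moi",
    "baseline_class",
    "evidence",
]


def _check_unique_within_dataset(records: Sequence[VariantRecord]) -> None:
    seen: set[tuple] = set()
    for v in records:
        item = (v.dataset, *v.key)
        if item in seen:
            raise ValueError(
                f"duplicate variant key {v.key} within dataset {v.dataset!r}"
            )
        seen.add(item)


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read the curated variant table (tab-separated, headered)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                key=(str(row.chrom), int(row.pos), row.ref, row.alt),
                gene=row.gene,
                hgnc=row.hgnc,
                transcript=row.transcript,
                hgvs_c=row.hgvs_c,
                dataset=row.dataset,
                moi=row.moi or "UNKNOWN",
                baseline_profile=EvidenceProfile.parse(row.evidence),
                baseline_class=Classification.from_label(row.baseline_class),
            )
        )
    _check_unique_within_dataset(records)
    return records


def write_variants(records: Sequence[VariantRecord], path: str | Path) -> None:
    _check_unique_within_dataset(records)
    rows = []
    for v in records:
        chrom, pos, ref, alt = v.key
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": v.gene,
                "hgnc": v.hgnc,
                "transcript": v.transcript,
                "hgvs_c": v.hgvs_c,
                "dataset": v.dataset,
                "moi": v.moi,
                "baseline_class": v.baseline_class.label,
                "evidence": v.baseline_profile.serialize(),
            }
        )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Read variants from VCF 4.2 with EVID/DATASET/MOI/BASECLASS INFO keys."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(
                        key=(rec.chrom, rec.pos, rec.ref, alt),
                        gene=str(_info_scalar(info, "GENE", "")),
                        hgnc=str(_info_scalar(info, "HGNC", "")),
                        transcript=str(_info_scalar(info, "TRANSCRIPT", "")),
                        hgvs_c=str(_info_scalar(info, "HGVSC", "")),
                        dataset=str(_info_scalar(info, "DATASET", "")),
                        moi=str(_info_scalar(info, "MOI", "UNKNOWN")),
                        baseline_profile=EvidenceProfile.parse(
                            str(_info_scalar(info, "EVID", ""))
                        ),
                        baseline_class=Classification.from_label(
                            str(_info_scalar(info, "BASECLASS", "VUS"))
                        ),
                    )
                )
    _check_unique_within_dataset(records)
    return records


def _info_scalar(info, key: str, default):
    try:
        val = info[key]
    except (KeyError, ValueError):  # absent, or not declared in the header
        return default
    if isinstance(val, tuple):
        val = ",".join(str(v) for v in val if v is not None)
    if val is None:  # flag-style or empty INFO entry
        return default
    return val


def read_scores(
    path: str | Path, table: CalibrationTable | None = None
) -> list[ScoreAnnotation]:
    """Read a per-variant score table (OpenCRAVAT-style tab-separated layout).

    Columns: ``chrom  pos  ref  alt`` then one column per predictor; blank
    cells are missing scores.  With a calibration table, tool-specific
    column headers are mapped to canonical predictor names via its alias
    map; unrecognized columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise ValueError(f"score table missing column {col!r}")
    score_cols: dict[str, str] = {}
    for col in df.columns:
        if col in ("chrom", "pos", "ref", "alt"):
            continue
        name = table.canonical_name(col) if table is not None else col
        if name is not None:
            score_cols[col] = name

    annotations = []
    seen = set()
    for _, row in df.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
        if key in seen:
            raise ValueError(f"duplicate score annotation for variant key {key}")
        seen.add(key)
        scores = {}
        for col, name in score_cols.items():
            cell = row[col]
            if cell != "":
                scores[name] = float(cell)
        annotations.append(ScoreAnnotation(key=key, scores=scores))
    return annotations


def write_scores(
    annotations: Sequence[ScoreAnnotation],
    path: str | Path,
    predictors: Sequence[str] | None = None,
) -> None:
    if predictors is None:
        names: list[str] = []
        for ann in annotations:
            for p in ann.scores:
                if p not in names:
                    names.append(p)
        predictors = names
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["chrom", "pos", "ref", "alt", *predictors])
        for ann in annotations:
            row = list(ann.key) + [
                repr(ann.scores[p]) if p in ann.scores else "" for p in predictors
            ]
            writer.writerow(row)


def write_outcomes(
    outcomes: Sequence[ReclassificationOutcome], path: str | Path
) -> None:
    rows = []
    for out in outcomes:
        chrom, pos, ref, alt = out.key
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "predictor": out.predictor,
                "dataset": out.dataset,
                "moi": out.moi,
                "assignment": out.assignment,
                "strength": out.strength.token if out.strength else "",
                "old_class": out.old_class.label,
                "new_class": out.new_class.label,
                "changed": int(out.changed),
                "eligible": int(out.eligible),
                "score_missing": int(out.score_missing),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_outcomes(path: str | Path) -> list[ReclassificationOutcome]:
    from .acmg import EvidenceStrength

    strengths = {s.token: s for s in EvidenceStrength}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    outcomes = []
    for row in df.itertuples(index=False):
        outcomes.append(
            ReclassificationOutcome(
                key=(str(row.chrom), int(row.pos), row.ref, row.alt),
                predictor=row.predictor,
                assignment=row.assignment,
                strength=strengths.get(row.strength) if row.strength else None,
                old_class=Classification.from_label(row.old_class),
                new_class=Classification.from_label(row.new_class),
                changed=bool(int(row.changed)),
                eligible=bool(int(row.eligible)),
                score_missing=bool(int(row.score_missing)),
                dataset=row.dataset,
                moi=row.moi,
            )
        )
    return outcomes


def write_transitions(
    matrices: dict[tuple[str, str], TransitionMatrix], path: str | Path
) -> None:
    """Write per-(dataset, predictor) transition tallies as a tidy table."""
    rows = []
    for (dataset, predictor), matrix in matrices.items():
        for r in matrix.to_rows():
            rows.append({"dataset": dataset, "predictor": predictor, **r})
    pd.DataFrame(
        rows, columns=["dataset", "predictor", "old_class", "new_class", "count"]
    ).to_csv(path, sep="\t", index=False)
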