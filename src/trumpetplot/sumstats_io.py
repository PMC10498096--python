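"""Read and write summary-statistics tables in common dialects.

Tab- or comma-delimited tables with a header row are accepted. Column names
vary wildly across GWAS pipelines; ``dialect="auto"`` resolves the common
synonyms (SNP/rsid/variant_id, A1/effect_allele, AF/EAF/freq, BETA/b/effect,
SE, P/pval, ...). A row that violates the record invariants is rejected and
reported — loading is total: every input row is either loaded or appears in
the rejection report.

Effect sizes must already be on the beta scale; odds ratios are expected to
be log-transformed upstream (this reader does not guess which scale a column
is on).
"""

from __future__ import annotations

import logging
import math
import os
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .model import (
    CANONICAL_COLUMNS,
    LoadReport,
    SumstatsTable,
    VariantAssociation,
)

logger = logging.getLogger(__name__)

#: smallest positive double; P = 0 in input is clamped here so that
#: -log10(p) stays finite
TINY_P = float(np.nextafter(0.0, 1.0))

MANDATORY = (
    "variant_id",
    "chrom",
    "pos_bp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
)

# lower-cased synonym -> canonical name
SYNONYMS: dict[str, str] = {}
for canonical, names in {
    "variant_id": ["variant_id", "snp", "rsid", "rs_id", "id", "variant", "markername"],
    "chrom": ["chrom", "chr", "chromosome", "#chrom"],
    "pos_bp": ["pos_bp", "pos", "bp", "position", "base_pair_location"],
    "effect_allele": ["effect_allele", "a1", "allele1", "ea", "alt"],
    "other_allele": ["other_allele", "a2", "allele2", "oa", "nea", "ref"],
    "eaf": ["eaf", "af", "freq", "frq", "a1freq", "effect_allele_frequency"],
    "beta": ["beta", "b", "effect", "es", "effect_size"],
    "se": ["se", "stderr", "standard_error", "sebeta"],
    "pvalue": ["pvalue", "p", "pval", "p_value"],
    "n": ["n", "n_samples", "sample_size", "neff"],
    "gene": ["gene", "gene_name", "nearest_gene"],
    "trait": ["trait", "phenotype"],
    "source": ["source"],
}.items():
    for name in names:
        SYNONYMS[name] = canonical


def resolve_dialect(
    columns: list[str], dialect: Union[str, Mapping[str, str]] = "auto"
) -> dict[str, str]:
    """Map canonical field names to actual column names.

    ``dialect`` may be ``"auto"`` (synonym table, case-insensitive) or an
    explicit mapping ``{canonical: actual}``. Raises ``ValueError`` naming the
    first mandatory field that cannot be resolved.
    """
    if dialect == "auto":
        mapping: dict[str, str] = {}
        for col in columns:
            canonical = SYNONYMS.get(col.strip().lower())
            if canonical is not None and canonical not in mapping:
                mapping[canonical] = col
    else:
        mapping = {k: v for k, v in dict(dialect).items() if v in columns}
        missing_cols = [v for v in dict(dialect).values() if v not in columns]
        if missing_cols:
            raise ValueError(f"dialect refers to absent columns: {missing_cols}")
    for field in MANDATORY:
        if field not in mapping:
            raise ValueError(
                f"mandatory column {field!r} could not be resolved from header {columns}"
            )
    return mapping


def _detect_sep(path: str) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_sumstats(
    path: Union[str, os.PathLike],
    dialect: Union[str, Mapping[str, str]] = "auto",
    *,
    trait_name: str = "",
    study_n: Optional[int] = None,
    trait_model: str = "quantitative",
    n_cases: Optional[int] = None,
    n_controls: Optional[int] = None,
) -> SumstatsTable:
    """Load, validate and sort a summary-statistics table.

    Rows violating record invariants are dropped and listed in the returned
    table's ``load_report`` (index + reason). If ``study_n`` is omitted it is
    inferred as the median of the per-variant ``n`` column; with neither
    available the load fails.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    mapping = resolve_dialect(list(df.columns), dialect)

    report = LoadReport(n_input=len(df))
    records: list[VariantAssociation] = []
    seen_ids: set[str] = set()
    col_idx = {canonical: df.columns.get_loc(col) for canonical, col in mapping.items()}
    for idx, row in enumerate(df.itertuples(index=False)):
        raw = {canonical: row[i] for canonical, i in col_idx.items()}
        try:
            pvalue = float(raw["pvalue"])
            if pvalue == 0.0:
                report.warnings.append(
                    f"row {idx}: pvalue 0 clamped to {TINY_P:g}"
                )
                pvalue = TINY_P
            n_raw = _opt_str(raw.get("n"))
            rec = VariantAssociation(
                variant_id=str(raw["variant_id"]).strip(),
                chrom=str(raw["chrom"]).strip(),
                pos_bp=int(float(raw["pos_bp"])),
                effect_allele=str(raw["effect_allele"]).strip().upper(),
                other_allele=str(raw["other_allele"]).strip().upper(),
                eaf=float(raw["eaf"]),
                beta=float(raw["beta"]),
                se=float(raw["se"]),
                pvalue=pvalue,
                n=int(float(n_raw)) if n_raw is not None else None,
                gene=_opt_str(raw.get("gene")),
                trait=_opt_str(raw.get("trait")),
                source=(_opt_str(raw.get("source")) or "gwas").lower(),
            )
        except (TypeError, ValueError) as exc:
            report.rejections.append((idx, f"unparseable field: {exc}"))
            continue
        errs = rec.validation_errors()
        if errs:
            report.rejections.append((idx, "; ".join(errs)))
            continue
        if rec.variant_id in seen_ids:
            report.rejections.append((idx, f"duplicate variant_id {rec.variant_id!r}"))
            continue
        seen_ids.add(rec.variant_id)
        records.append(rec)

    report.n_loaded = len(records)
    for warning in report.warnings:
        logger.warning("%s: %s", path, warning)
    for idx, reason in report.rejections:
        logger.warning("%s: rejected row %d: %s", path, idx, reason)
    if not records:
        raise ValueError(f"{path}: no valid rows after validation "
                         f"({report.n_rejected} rejected)")

    if study_n is None:
        ns = [r.n for r in records if r.n is not None]
        if not ns:
            raise ValueError(
                f"{path}: study_n not given and no per-variant n column available"
            )
        study_n = int(np.median(ns))

    table = SumstatsTable(
        records=records,
        trait_name=trait_name,
        study_n=study_n,
        trait_model=trait_model,
        n_cases=n_cases,
        n_controls=n_controls,
    )
    table.load_report = report
    return table


def write_sumstats(table: SumstatsTable, path: Union[str, os.PathLike]) -> None:
    """Write the canonical tab-delimited dialect.

    Optional fields that are absent are written as empty cells and re-read as
    absent, so ``read_sumstats(write_sumstats(t))`` is the identity on all
    canonical fields.
    """
    if len(table) == 0:
        raise ValueError("refusing to write a table with no records")
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in table.records:
            cells = [
                r.variant_id,
                r.chrom,
                str(r.pos_bp),
                r.effect_allele,
                r.other_allele,
                repr(r.eaf),
                repr(r.beta),
                repr(r.se),
                repr(r.pvalue),
                "" if r.n is None else str(r.n),
                r.gene or "",
                r.trait or "",
                r.source,
            ]
            fh.write("\t".join(cells) + "\n")
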