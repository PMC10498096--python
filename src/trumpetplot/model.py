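"""Core record and table types for GWAS/exome summary statistics.

A :class:`VariantAssociation` is one variant's association result as reported
by a single study: alleles, effect-allele frequency, per-allele effect on the
trait scale (log odds ratio for binary traits), its standard error and
P-value, plus optional provenance (gene, trait, ``gwas`` vs ``exome`` source).
A :class:`SumstatsTable` is an ordered collection of such records together
with study-level metadata (trait name, sample size, trait model).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

VALID_SOURCES = ("gwas", "exome")
VALID_TRAIT_MODELS = ("quantitative", "binary")

#: canonical column order for tabular round-trips
CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos_bp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "gene",
    "trait",
    "source",
)


@dataclass(frozen=True)
class VariantAssociation:
    """A single variant's association record.

    ``eaf`` is the frequency of ``effect_allele``; ``beta`` is the per-allele
    effect of that allele on the trait. Monomorphic frequencies (0 or 1) are
    invalid: downstream power and allele flipping are undefined when
    2f(1-f) = 0.
    """

    variant_id: str
    chrom: str
    pos_bp: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: Optional[int] = None
    gene: Optional[str] = None
    trait: Optional[str] = None
    source: str = "gwas"

    def validation_errors(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errs: list[str] = []
        if not (0.0 < self.eaf < 1.0):
            errs.append(f"eaf={self.eaf!r} not in open interval (0, 1)")
        if not (self.se > 0.0):
            errs.append(f"se={self.se!r} not > 0")
        if not (0.0 < self.pvalue <= 1.0):
            errs.append(f"pvalue={self.pvalue!r} not in (0, 1]")
        if not (self.pos_bp >= 1):
            errs.append(f"pos_bp={self.pos_bp!r} < 1")
        if self.effect_allele == self.other_allele:
            errs.append(f"effect_allele == other_allele ({self.effect_allele!r})")
        if not np.isfinite(self.beta):
            errs.append(f"beta={self.beta!r} not finite")
        if self.n is not None and self.n <= 0:
            errs.append(f"n={self.n!r} not positive")
        if self.source not in VALID_SOURCES:
            errs.append(f"source={self.source!r} not one of {VALID_SOURCES}")
        return errs

    def is_valid(self) -> bool:
        return not self.validation_errors()

    def replace(self, **changes) -> "VariantAssociation":
        return dataclasses.replace(self, **changes)


def _chrom_sort_key(chrom: str):
    """Numeric chromosomes before lexicographic ones (1..22 < X, Y, MT)."""
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class LoadReport:
    """Accounting of a table load: every input row is loaded or rejected."""

    n_input: int = 0
    n_loaded: int = 0
    #: (0-based data row index, reason)
    rejections: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


@dataclass
class SumstatsTable:
    """Ordered summary statistics plus study metadata.

    ``study_n`` is the study sample size used when a record carries no
    per-variant ``n``; for binary traits ``n_cases``/``n_controls`` refine it.
    Records are kept sorted by (chrom, pos_bp) and variant ids are unique.
    """

    records: list[VariantAssociation]
    trait_name: str = ""
    study_n: int = 0
    trait_model: str = "quantitative"
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    load_report: Optional[LoadReport] = None

    def __post_init__(self) -> None:
        if self.trait_model not in VALID_TRAIT_MODELS:
            raise ValueError(
                f"trait_model must be one of {VALID_TRAIT_MODELS}, got {self.trait_model!r}"
            )
        if self.study_n <= 0:
            raise ValueError(f"study_n must be a positive integer, got {self.study_n!r}")
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dups = []
            for i in ids:
                if i in seen:
                    dups.append(i)
                seen.add(i)
            raise ValueError(f"duplicate variant ids: {sorted(set(dups))[:5]}")
        self.sort()

    def sort(self) -> None:
        self.records.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.pos_bp, r.variant_id))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def n_for(self, record: VariantAssociation) -> int:
        """Per-variant sample size, falling back to the study N."""
        return record.n if record.n is not None else self.study_n

    def with_records(self, records: list[VariantAssociation]) -> "SumstatsTable":
        """A copy of this table carrying ``records`` (metadata preserved)."""
        return SumstatsTable(
            records=list(records),
            trait_name=self.trait_name,
            study_n=self.study_n,
            trait_model=self.trait_model,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(r, c) for c in CANONICAL_COLUMNS}
            for r in self.records
        ]
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        if len(df):
            df["pos_bp"] = df["pos_bp"].astype(np.int64)
        return df
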