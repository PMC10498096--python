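"""Canonical allele orientations for plotting.

Two conventions are supported:

``minor_allele_signed`` (the default and recommended one)
    Every record reports the minor allele, so frequencies live in (0, 0.5]
    and effects keep their sign (risk vs protective).

``positive_effect``
    Every record reports the trait-increasing allele, so effects are >= 0
    and frequencies span the full (0, 1) range.

Flipping a record to the other allele negates beta and replaces f by 1 - f;
se, pvalue and n are untouched, and the variance explained 2f(1-f)beta^2 is
invariant, so statistical power does not depend on the orientation chosen.
"""

from __future__ import annotations

from enum import Enum

from .model import SumstatsTable, VariantAssociation


class OrientationMode(str, Enum):
    MINOR_ALLELE_SIGNED = "minor_allele_signed"
    POSITIVE_EFFECT = "positive_effect"


def _flip(record: VariantAssociation) -> VariantAssociation:
    """Report the other allele: swap alleles, f -> 1-f, beta -> -beta."""
    return record.replace(
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        eaf=1.0 - record.eaf,
        beta=-record.beta,
    )


def to_minor_allele(record: VariantAssociation) -> VariantAssociation:
    """Orient the record to its minor allele (eaf <= 0.5, signed beta).

    eaf exactly 0.5 is a tie and is returned unchanged, so the transform is
    idempotent and deterministic.
    """
    if record.eaf > 0.5:
        return _flip(record)
    return record


def to_positive_effect(record: VariantAssociation) -> VariantAssociation:
    """Orient the record to its trait-increasing allele (beta >= 0).

    beta exactly 0 has no defined sign and is returned unchanged.
    """
    if record.beta < 0.0:
        return _flip(record)
    return record


_TRANSFORMS = {
    OrientationMode.MINOR_ALLELE_SIGNED: to_minor_allele,
    OrientationMode.POSITIVE_EFFECT: to_positive_effect,
}


def harmonize_table(table: SumstatsTable, mode: OrientationMode) -> SumstatsTable:
    """Apply the orientation transform to every record of a table."""
    mode = OrientationMode(mode)
    transform = _TRANSFORMS[mode]
    return table.with_records([transform(r) for r in table.records])
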