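"""Independent significant variants from summary statistics + an LD reference.

Two selection methods are provided. *Clumping* greedily picks the variant
with the strongest association as the lead of an LD cluster and absorbs all
significant variants that are both within a window of the lead and in LD
with it (r^2 above a threshold); the result partitions the significant set.
*Stepwise selection* approximates a conditional/joint analysis from summary
statistics: marginal effects are standardized to the correlation scale
(b = z / sqrt(n)), and variants are added one at a time by smallest
conditional P-value, conditioning on the current model through the LD
submatrix; joint effects and standard errors are back-transformed to the
input scale at the end.

The LD reference is a symmetric allelic correlation matrix keyed by variant
id with genomic positions, either given directly or derived from a small
genotype matrix (individuals x variants, dosages 0/1/2).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .model import SumstatsTable, VariantAssociation

logger = logging.getLogger(__name__)


@dataclass
class LDReference:
    """Symmetric allelic correlation matrix with positions.

    ``alleles``, when present, records the allele each row's correlations are
    signed with respect to (one allele per variant); stepwise selection uses
    it to align the sign of r with the summary-statistics effect allele.
    """

    variant_ids: list[str]
    pos_bp: np.ndarray
    R: np.ndarray
    chrom: Optional[list[str]] = None
    alleles: Optional[list[str]] = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        m = len(self.variant_ids)
        if self.R.shape != (m, m):
            raise ValueError(f"R shape {self.R.shape} does not match {m} ids")
        if len(set(self.variant_ids)) != m:
            raise ValueError("duplicate variant ids in LD reference")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.R) > 1.0 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")
        np.clip(self.R, -1.0, 1.0, out=self.R)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        missing = [v for v in ids if v not in self._index]
        if missing:
            raise KeyError(f"variants absent from LD reference: {missing[:10]}")
        return np.array([self._index[v] for v in ids], dtype=int)

    def r(self, a: str, b: str) -> float:
        return float(self.R[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2


def ld_from_genotypes(
    G: Union[np.ndarray, pd.DataFrame],
    variant_ids: Optional[Sequence[str]] = None,
    pos_bp: Optional[Sequence[int]] = None,
    chrom: Optional[Sequence[str]] = None,
    alleles: Optional[Sequence[str]] = None,
) -> LDReference:
    """Pearson correlation of dosage columns (individuals x variants)."""
    if isinstance(G, pd.DataFrame):
        if variant_ids is None:
            variant_ids = list(G.columns)
        G = G.to_numpy(dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("genotype matrix needs >= 2 individuals")
    m = G.shape[1]
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(m)]
    sd = G.std(axis=0)
    mono = [variant_ids[i] for i in np.flatnonzero(sd == 0.0)]
    if mono:
        raise ValueError(f"monomorphic variant(s) in LD genotypes: {mono[:10]}")
    R = np.corrcoef(G, rowvar=False)
    R = np.atleast_2d(R)
    if pos_bp is None:
        pos_bp = np.arange(1, m + 1)
    return LDReference(
        variant_ids=list(variant_ids),
        pos_bp=np.asarray(pos_bp),
        R=R,
        chrom=list(chrom) if chrom is not None else None,
        alleles=list(alleles) if alleles is not None else None,
    )


def read_ld_matrix(path: Union[str, os.PathLike]) -> LDReference:
    """Read a TSV correlation matrix: id header row, id first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if list(map(str, df.index)) != ids:
        raise ValueError("LD matrix row ids do not match column ids")
    return LDReference(variant_ids=ids, pos_bp=np.arange(1, len(ids) + 1),
                       R=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDReference, path: Union[str, os.PathLike]) -> None:
    pd.DataFrame(ld.R, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


@dataclass
class SelectionResult:
    """Leads plus, per method, absorbed members or joint estimates."""

    lead_ids: list[str]
    method: str
    membership: dict[str, list[str]] = field(default_factory=dict)
    joint_betas: dict[str, float] = field(default_factory=dict)
    joint_ses: dict[str, float] = field(default_factory=dict)
    joint_pvalues: dict[str, float] = field(default_factory=dict)
    n_candidates: int = 0

    def to_frame(self, table: SumstatsTable) -> pd.DataFrame:
        """Tabular view: one row per lead with marginal or joint estimates."""
        by_id = {r.variant_id: r for r in table.records}
        rows = []
        for vid in self.lead_ids:
            r = by_id[vid]
            rows.append(
                {
                    "variant_id": vid,
                    "chrom": r.chrom,
                    "pos_bp": r.pos_bp,
                    "beta": self.joint_betas.get(vid, r.beta),
                    "se": self.joint_ses.get(vid, r.se),
                    "pvalue": self.joint_pvalues.get(vid, r.pvalue),
                    "n_absorbed": len(self.membership.get(vid, [])),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["variant_id", "chrom", "pos_bp", "beta", "se", "pvalue", "n_absorbed"],
        )


def _maf(record: VariantAssociation) -> float:
    return min(record.eaf, 1.0 - record.eaf)


def _candidates(
    table: SumstatsTable, p_threshold: float, maf_min: float
) -> list[VariantAssociation]:
    return [
        r
        for r in table.records
        if r.pvalue < p_threshold and _maf(r) >= maf_min
    ]


def clump(
    table: SumstatsTable,
    ld: LDReference,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    window_bp: int = 100_000,
    maf_min: float = 0.01,
) -> SelectionResult:
    """Greedy LD clumping of significant variants.

    Repeatedly takes the unassigned variant with the smallest P-value as a
    lead and absorbs every unassigned variant on the same chromosome within
    ``window_bp`` of the lead AND with r^2 >= ``r2_threshold`` against it.
    The window is measured lead-to-candidate, not chained. Ties on P are
    broken by distance to the lead, then variant id.
    """
    if not (0.0 < p_threshold <= 1.0) or not (0.0 <= r2_threshold <= 1.0):
        raise ValueError("thresholds out of range")
    cands = _candidates(table, p_threshold, maf_min)
    if not cands:
        return SelectionResult(lead_ids=[], method="clump", n_candidates=0)
    missing = [r.variant_id for r in cands if r.variant_id not in ld]
    if missing:
        raise KeyError(f"clump candidates absent from LD reference: {missing[:10]}")

    # deterministic processing order: P ascending, then id
    remaining = sorted(cands, key=lambda r: (r.pvalue, r.variant_id))
    assigned: set[str] = set()
    lead_ids: list[str] = []
    membership: dict[str, list[str]] = {}
    for lead in remaining:
        if lead.variant_id in assigned:
            continue
        assigned.add(lead.variant_id)
        lead_ids.append(lead.variant_id)
        absorbed = [
            r
            for r in remaining
            if r.variant_id not in assigned
            and r.chrom == lead.chrom
            and abs(r.pos_bp - lead.pos_bp) <= window_bp
            and ld.r2(lead.variant_id, r.variant_id) >= r2_threshold
        ]
        absorbed.sort(key=lambda r: (abs(r.pos_bp - lead.pos_bp), r.variant_id))
        membership[lead.variant_id] = [r.variant_id for r in absorbed]
        assigned.update(r.variant_id for r in absorbed)
    return SelectionResult(
        lead_ids=lead_ids,
        method="clump",
        membership=membership,
        n_candidates=len(cands),
    )


def _align_signs(ld: LDReference, table: SumstatsTable, ids: list[str]) -> np.ndarray:
    """+1/-1 per variant aligning LD allele orientation to the effect allele."""
    if ld.alleles is None:
        return np.ones(len(ids))
    by_id = {r.variant_id: r for r in table.records}
    sign = np.ones(len(ids))
    for k, vid in enumerate(ids):
        ld_allele = ld.alleles[ld._index[vid]]
        rec = by_id[vid]
        if ld_allele == rec.other_allele:
            sign[k] = -1.0
        elif ld_allele != rec.effect_allele:
            logger.warning(
                "LD allele %s for %s matches neither study allele; sign kept",
                ld_allele, vid,
            )
    return sign


def stepwise_select(
    table: SumstatsTable,
    ld: LDReference,
    p_threshold: float = 5e-8,
    window_bp: int = 100_000,
    collinearity_r2_cap: float = 0.9,
    maf_min: float = 0.0,
    max_steps: int = 10_000,
) -> SelectionResult:
    """Forward stepwise conditional/joint selection from summary statistics.

    Works per chromosome on the standardized (correlation) scale where the
    marginal effect of variant j is b_j = z_j / sqrt(n_j). Conditioning uses
    the LD submatrix banded at ``window_bp`` (correlations between variants
    further apart are treated as zero). Candidates whose r^2 with the current
    model exceeds ``collinearity_r2_cap`` are skipped; a near-singular model
    matrix causes the offending candidate to be dropped with a warning.

    Unlike clumping, a variant need not be marginally significant to enter
    the model, only conditionally — this is what lets the joint model
    recover signals masked by opposite-sign LD partners. The candidate pool
    is every variant passing ``maf_min`` that the LD reference covers (a
    regional panel around the significant loci is enough); a *marginally
    significant* variant missing from the reference is an error. Selection
    starts from the smallest marginal P-value and stops when no conditional
    P-value clears ``p_threshold``.
    """
    pool = [r for r in table.records if _maf(r) >= maf_min]
    missing = [
        r.variant_id for r in pool
        if r.pvalue < p_threshold and r.variant_id not in ld
    ]
    if missing:
        raise KeyError(f"stepwise candidates absent from LD reference: {missing[:10]}")
    cands = [r for r in pool if r.variant_id in ld]
    if not cands or min(r.pvalue for r in cands) >= p_threshold:
        return SelectionResult(lead_ids=[], method="stepwise", n_candidates=0)
    for r in cands:
        if table.n_for(r) is None or table.n_for(r) <= 0:
            raise ValueError(f"per-variant sample size missing for {r.variant_id}")

    lead_ids: list[str] = []
    joint_betas: dict[str, float] = {}
    joint_ses: dict[str, float] = {}
    joint_pvalues: dict[str, float] = {}

    for chrom in sorted({r.chrom for r in cands}):
        recs = [r for r in cands if r.chrom == chrom]
        ids = [r.variant_id for r in recs]
        pos = np.array([r.pos_bp for r in recs])
        n = np.array([float(table.n_for(r)) for r in recs])
        z = np.array([r.beta / r.se for r in recs])
        scale = np.array([r.se * np.sqrt(table.n_for(r)) for r in recs])
        sign = _align_signs(ld, table, ids)
        idx = ld.index_of(ids)
        R = ld.R[np.ix_(idx, idx)] * np.outer(sign, sign)
        np.fill_diagonal(R, 1.0)
        # banded window: distant pairs contribute no conditioning
        band = np.abs(pos[:, None] - pos[None, :]) <= window_bp
        R = np.where(band, R, 0.0)
        b = z / np.sqrt(n)  # standardized marginal effects

        pvals = np.array([r.pvalue for r in recs])
        if pvals.min() >= p_threshold:
            continue  # no signal on this chromosome
        order0 = np.lexsort((np.array(ids), pvals))
        selected: list[int] = [int(order0[0])]
        active = set(range(len(recs))) - set(selected)
        for _ in range(max_steps):
            if not active:
                break
            S = np.array(selected, dtype=int)
            R_S = R[np.ix_(S, S)]
            try:
                R_S_inv = np.linalg.inv(R_S)
            except np.linalg.LinAlgError:  # pragma: no cover - guarded below
                break
            best = None
            for c in sorted(active):
                r_cS = R[c, S]
                if np.max(r_cS**2) > collinearity_r2_cap:
                    continue
                w = R_S_inv @ r_cS
                var_c = 1.0 - float(r_cS @ w)
                if var_c < 1e-8:
                    logger.warning(
                        "near-singular conditioning for %s; candidate dropped", ids[c]
                    )
                    continue
                z_cond = (z[c] - float(r_cS @ (R_S_inv @ z[S]))) / np.sqrt(var_c)
                p_cond = float(stats.chi2.sf(z_cond * z_cond, df=1))
                key = (p_cond, ids[c])
                if best is None or key < best[0]:
                    best = (key, c, p_cond)
            if best is None or best[2] >= p_threshold:
                break
            selected.append(best[1])
            active.discard(best[1])

        S = np.array(selected, dtype=int)
        R_S = R[np.ix_(S, S)]
        cond = np.linalg.cond(R_S)
        if cond > 1e8:
            logger.warning(
                "joint model on chrom %s ill-conditioned (cond=%.2g); "
                "dropping last-added variant", chrom, cond,
            )
            S = S[:-1]
            R_S = R[np.ix_(S, S)]
        R_S_inv = np.linalg.inv(R_S)
        bJ_std = R_S_inv @ b[S]
        se_std = np.sqrt(np.diag(R_S_inv) / n[S])
        zJ = bJ_std / se_std
        for k, j in enumerate(S):
            vid = ids[j]
            lead_ids.append(vid)
            joint_betas[vid] = float(bJ_std[k] * scale[j])
            joint_ses[vid] = float(se_std[k] * scale[j])
            joint_pvalues[vid] = float(stats.chi2.sf(zJ[k] * zJ[k], df=1))

    by_id = {r.variant_id: r for r in cands}
    lead_ids.sort(key=lambda v: (by_id[v].pvalue, v))
    return SelectionResult(
        lead_ids=lead_ids,
        method="stepwise",
        joint_betas=joint_betas,
        joint_ses=joint_ses,
        joint_pvalues=joint_pvalues,
        n_candidates=len(cands),
    )
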