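"""Simulated GWAS/exome summary statistics with a trumpet-shaped architecture.

The generator emulates a mixed architecture: many common, array-like variants
with small effects (organized into LD blocks) plus a tail of rare,
exome-like variants with large effects (LD-free, singleton-like, tagged
``source="exome"``). Causal effects follow the standard frequency-dependent
prior

    beta | causal  ~  Normal(0, tau^2 / (2 f (1-f))^gamma),  gamma in [0, 1]

so gamma = 0 gives frequency-independent effects and gamma = 1 gives equal
expected variance explained per causal variant; intermediate values produce
the trumpet: rare variants draw systematically larger effects.

Emitted marginal statistics follow the standard summary-statistics sampling
model on the standardized scale: within an LD block with correlation matrix
R the marginal expectation is R b_true and the sampling noise is
MVN(0, R/n); for LD-free variants this reduces to beta_hat = beta_true +
Normal(0, se^2) with se = 1 / sqrt(n 2f(1-f)). A matching individual-level
cohort (Gaussian-copula genotypes with Binomial(2, f) margins plus a
quantitative phenotype) is available at small n as an oracle substrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .ld_select import LDReference
from .model import SumstatsTable, VariantAssociation
from .sumstats_io import TINY_P

logger = logging.getLogger(__name__)

_WITHIN_BLOCK_SPACING = 10_000  # bp; a 10-variant block spans < 100 kb
_BETWEEN_BLOCK_GAP = 1_000_000  # bp


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror a large-biobank continuous-trait study: N = 351,550
    samples, ~20k variants of which 10% are rare exome-style records, LD
    blocks of 10 variants at r = 0.8, causal fraction 0.2 and effect scale
    tau = 0.05 phenotypic SD (so common-variant effects are a few hundredths
    of an SD while rare causal variants draw effects of order 0.1-1).
    """

    seed: int = 0
    n_gwas: int = 351_550
    m_common: int = 18_000
    m_rare: int = 2_000
    causal_fraction: float = 0.2
    tau: float = 0.05
    gamma: float = 0.5
    ld_blocks: Tuple[Tuple[int, float], ...] = ((10, 0.8),)
    n_individuals: int = 2_000
    common_log10f: Tuple[float, float] = (-2.0, -0.3)
    rare_log10f: Tuple[float, float] = (-5.0, -2.0)
    trait_name: str = "simulated_trait"

    def __post_init__(self) -> None:
        if self.m_common < 0 or self.m_rare < 0:
            raise ValueError("variant counts must be >= 0")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0,1], got {self.gamma}")
        if not (0.0 <= self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must be in [0,1]")
        for size, rho in self.ld_blocks:
            if size < 1 or not (0.0 <= rho < 1.0):
                raise ValueError(f"bad LD block ({size}, {rho})")
        for lo, hi in (self.common_log10f, self.rare_log10f):
            if not (-np.inf < lo < hi <= 0.0) or 10.0**lo <= 0 or 10.0**hi >= 1.0:
                raise ValueError("frequency bounds must lie inside (0,1)")
        if self.n_gwas <= 0:
            raise ValueError("n_gwas must be positive")


@dataclass
class Architecture:
    """True per-variant state shared by the sumstats and cohort generators."""

    variant_ids: list[str]
    chrom: list[str]
    pos_bp: np.ndarray
    freqs: np.ndarray
    beta_true: np.ndarray
    causal: np.ndarray
    #: (start, stop, rho) index ranges; rare variants are singleton blocks
    blocks: list[tuple[int, int, float]]
    source: list[str]
    gene: list[Optional[str]]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "eaf": self.freqs,
                "beta_true": self.beta_true,
                "causal": self.causal,
                "source": self.source,
            }
        )


def draw_architecture(config: SimConfig, rng: np.random.Generator) -> Architecture:
    """Frequencies, positions, LD-block layout and true causal effects."""
    freqs_c = 10.0 ** rng.uniform(*config.common_log10f, size=config.m_common)
    freqs_r = 10.0 ** rng.uniform(*config.rare_log10f, size=config.m_rare)
    freqs = np.concatenate([freqs_c, freqs_r])
    m = len(freqs)

    variant_ids, chrom, pos, source, gene = [], [], [], [], []
    blocks: list[tuple[int, int, float]] = []
    # common variants: chromosome 1, LD blocks cycling through config.ld_blocks
    i, b = 0, 0
    while i < config.m_common:
        size, rho = config.ld_blocks[b % len(config.ld_blocks)]
        size = min(size, config.m_common - i)
        start_bp = 1 + b * _BETWEEN_BLOCK_GAP
        blocks.append((i, i + size, rho))
        for k in range(size):
            variant_ids.append(f"1:{start_bp + k * _WITHIN_BLOCK_SPACING}:c{i + k}")
            chrom.append("1")
            pos.append(start_bp + k * _WITHIN_BLOCK_SPACING)
            source.append("gwas")
            gene.append(None)
        i += size
        b += 1
    # rare variants: chromosome 2, singleton-like, LD-free, exome-tagged
    for j in range(config.m_rare):
        p = 1 + j * _BETWEEN_BLOCK_GAP
        blocks.append((config.m_common + j, config.m_common + j + 1, 0.0))
        variant_ids.append(f"2:{p}:r{j}")
        chrom.append("2")
        pos.append(p)
        source.append("exome")
        gene.append(f"GENE{j % 500}")

    causal = rng.random(m) < config.causal_fraction
    v = 2.0 * freqs * (1.0 - freqs)
    sd = config.tau * v ** (-config.gamma / 2.0)
    beta_true = np.where(causal, rng.standard_normal(m) * sd, 0.0)
    return Architecture(
        variant_ids=variant_ids,
        chrom=chrom,
        pos_bp=np.asarray(pos, dtype=np.int64),
        freqs=freqs,
        beta_true=beta_true,
        causal=causal,
        blocks=blocks,
        source=source,
        gene=gene,
    )


def _block_R(size: int, rho: float) -> np.ndarray:
    R = np.full((size, size), rho)
    np.fill_diagonal(R, 1.0)
    return R


def _phi_corr(latent_rho: float, t1: float, t2: float, f1: float, f2: float) -> float:
    """Correlation of two Bernoulli indicators thresholded from a BVN."""
    p11 = float(
        stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, latent_rho], [latent_rho, 1.0]]
        ).cdf([-t1, -t2])
    )
    denom = np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
    return (p11 - f1 * f2) / denom


def _latent_rho_for_block(rho: float, thresholds: np.ndarray, freqs: np.ndarray) -> float:
    """Latent Gaussian correlation whose thresholded mean pair correlation
    matches the requested dosage correlation.

    Thresholding attenuates correlation (tetrachoric -> phi), so the latent
    value must exceed the target; for very asymmetric frequencies the target
    may be unreachable even at latent rho ~ 1, in which case the maximum
    feasible value is used (the caller warns about the achieved value).
    """
    # use pairs against the average threshold; exact per-pair matching is
    # impossible with a single exchangeable latent rho anyway
    pairs = [(i, j) for i in range(len(freqs)) for j in range(i + 1, len(freqs))]
    if len(pairs) > 12:  # subsample for big blocks; calibration is approximate
        pairs = pairs[:: max(1, len(pairs) // 12)]

    def mean_phi(lr: float) -> float:
        return float(
            np.mean(
                [
                    _phi_corr(lr, thresholds[i], thresholds[j], freqs[i], freqs[j])
                    for i, j in pairs
                ]
            )
        )

    lo, hi = rho, 0.999
    if mean_phi(hi) <= rho:
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if mean_phi(mid) < rho:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)


def simulate_sumstats(config: SimConfig) -> tuple[SumstatsTable, pd.DataFrame]:
    """Draw marginal summary statistics plus the true-effect table.

    Deterministic given ``config.seed``. Emitted (beta, se, p) are mutually
    consistent: p is the two-sided normal tail of beta/se (clamped to the
    smallest positive double when z is extreme).
    """
    rng = np.random.default_rng(config.seed)
    arch = draw_architecture(config, rng)
    n = float(config.n_gwas)
    f = arch.freqs
    v = 2.0 * f * (1.0 - f)
    b_std_true = arch.beta_true * np.sqrt(v)

    b_std = np.empty(len(f))
    chol_cache: dict[tuple[int, float], np.ndarray] = {}
    for start, stop, rho in arch.blocks:
        size = stop - start
        eps = rng.standard_normal(size)
        if size == 1 or rho == 0.0:
            b_std[start:stop] = b_std_true[start:stop] + eps / np.sqrt(n)
            continue
        key = (size, rho)
        if key not in chol_cache:
            chol_cache[key] = np.linalg.cholesky(_block_R(size, rho))
        R = _block_R(size, rho)
        L = chol_cache[key]
        b_std[start:stop] = R @ b_std_true[start:stop] + (L @ eps) / np.sqrt(n)

    beta = b_std / np.sqrt(v)
    se = 1.0 / np.sqrt(n * v)
    z2 = (beta / se) ** 2
    pvals = stats.chi2.sf(z2, df=1)
    n_clamped = int(np.sum(pvals <= 0.0))
    if n_clamped:
        logger.warning("%d p-values underflowed and were clamped", n_clamped)
    pvals = np.maximum(pvals, TINY_P)

    records = [
        VariantAssociation(
            variant_id=arch.variant_ids[i],
            chrom=arch.chrom[i],
            pos_bp=int(arch.pos_bp[i]),
            effect_allele="A",
            other_allele="G",
            eaf=float(f[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(pvals[i]),
            gene=arch.gene[i],
            trait=config.trait_name,
            source=arch.source[i],
        )
        for i in range(len(f))
    ]
    table = SumstatsTable(
        records=records,
        trait_name=config.trait_name,
        study_n=config.n_gwas,
        trait_model="quantitative",
    )
    return table, arch.truth_frame()


def simulate_cohort(
    config: SimConfig, architecture: Optional[Architecture] = None
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Individual-level genotypes and a quantitative phenotype.

    Genotypes are drawn per LD block with a Gaussian copula (two latent
    haplotype draws thresholded to the per-variant frequency, summed to a
    Binomial(2, f) margin). The achieved dosage correlation is below the
    latent rho for unequal or extreme frequencies; a warning reports blocks
    that fall well short. Intended for small variant counts (oracle tests),
    not biobank-scale m.

    Returns (genotype DataFrame [individuals x variants], phenotype, truth).
    """
    if config.n_individuals < 100:
        raise ValueError("n_individuals must be >= 100")
    rng = np.random.default_rng(config.seed)
    arch = architecture if architecture is not None else draw_architecture(config, rng)
    n = config.n_individuals
    m = len(arch.freqs)
    G = np.empty((n, m))
    thresholds = stats.norm.isf(arch.freqs)  # allele present when Z > isf(f)
    for start, stop, rho in arch.blocks:
        size = stop - start
        if size == 1 or rho == 0.0:
            G[:, start:stop] = rng.binomial(
                2, arch.freqs[start:stop], size=(n, size)
            )
            continue
        latent = _latent_rho_for_block(
            rho, thresholds[start:stop], arch.freqs[start:stop]
        )
        L = np.linalg.cholesky(_block_R(size, latent))
        hap = np.zeros((n, size))
        for _ in range(2):
            Z = rng.standard_normal((n, size)) @ L.T
            hap += Z > thresholds[start:stop]
        G[:, start:stop] = hap
        achieved = _mean_offdiag_corr(G[:, start:stop])
        if achieved is not None and achieved < rho - 0.15:
            logger.warning(
                "block [%d:%d): achieved dosage correlation %.2f below "
                "requested rho=%.2f", start, stop, achieved, rho,
            )

    genetic = G @ arch.beta_true
    var_gen = float(np.var(genetic))
    if var_gen >= 1.0:
        raise ValueError(
            f"genetic variance {var_gen:.3f} >= 1 under the unit-variance "
            "phenotype convention; lower tau or the causal fraction"
        )
    y = genetic + rng.standard_normal(n) * np.sqrt(1.0 - var_gen)
    Gdf = pd.DataFrame(G, columns=arch.variant_ids)
    return Gdf, y, arch.truth_frame()


def _mean_offdiag_corr(G: np.ndarray) -> Optional[float]:
    sd = G.std(axis=0)
    if np.any(sd == 0.0):
        return None
    R = np.corrcoef(G, rowvar=False)
    mask = ~np.eye(R.shape[0], dtype=bool)
    return float(R[mask].mean())


def marginal_sumstats(
    G: pd.DataFrame,
    y: np.ndarray,
    truth: pd.DataFrame,
    trait_name: str = "simulated_trait",
) -> SumstatsTable:
    """Per-variant OLS on a simulated cohort, as a GWAS would report it.

    Variants that are monomorphic in the cohort are skipped (no test).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = G.to_numpy(dtype=float)
    meta = truth.set_index("variant_id")
    records = []
    yc = y - y.mean()
    for j, vid in enumerate(G.columns):
        g = X[:, j]
        sxx = float(((g - g.mean()) ** 2).sum())
        if sxx == 0.0:
            continue
        bhat = float((g - g.mean()) @ yc) / sxx
        rss = float((yc - bhat * (g - g.mean())) @ (yc - bhat * (g - g.mean())))
        se = np.sqrt(rss / (n - 2) / sxx)
        z2 = (bhat / se) ** 2
        p = max(float(stats.chi2.sf(z2, df=1)), TINY_P)
        eaf = float(g.mean() / 2.0)
        if not (0.0 < eaf < 1.0):
            continue
        row = meta.loc[vid]
        records.append(
            VariantAssociation(
                variant_id=str(vid),
                chrom=str(row["chrom"]),
                pos_bp=int(row["pos_bp"]),
                effect_allele="A",
                other_allele="G",
                eaf=eaf,
                beta=bhat,
                se=float(se),
                pvalue=p,
                n=n,
                trait=trait_name,
                source=str(row["source"]),
            )
        )
    return SumstatsTable(
        records=records, trait_name=trait_name, study_n=n, trait_model="quantitative"
    )


def expected_ld(
    config: SimConfig,
    variant_ids: Optional[Sequence[str]] = None,
    architecture: Optional[Architecture] = None,
) -> LDReference:
    """The generator's block-diagonal LD matrix, optionally on a subset.

    This is the correlation structure the summary statistics were drawn
    with, so it is the exact LD reference for selection on simulated data.
    """
    arch = architecture
    if arch is None:
        arch = draw_architecture(config, np.random.default_rng(config.seed))
    ids = list(variant_ids) if variant_ids is not None else list(arch.variant_ids)
    index = {v: i for i, v in enumerate(arch.variant_ids)}
    missing = [v for v in ids if v not in index]
    if missing:
        raise KeyError(f"unknown simulated variants: {missing[:10]}")
    block_of = np.empty(len(arch.variant_ids), dtype=int)
    rho_of = np.empty(len(arch.variant_ids))
    for bi, (start, stop, rho) in enumerate(arch.blocks):
        block_of[start:stop] = bi
        rho_of[start:stop] = rho
    sel = np.array([index[v] for v in ids])
    same = block_of[sel][:, None] == block_of[sel][None, :]
    R = np.where(same, np.minimum.outer(rho_of[sel], rho_of[sel]), 0.0)
    np.fill_diagonal(R, 1.0)
    return LDReference(
        variant_ids=ids,
        pos_bp=np.array([arch.pos_bp[index[v]] for v in ids]),
        R=R,
        chrom=[arch.chrom[index[v]] for v in ids],
        alleles=["A"] * len(ids),
    )
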