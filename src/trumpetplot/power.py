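"""Analytic power for single-variant association tests and power curves.

The additive-model 1-df Wald/score test statistic is asymptotically
non-central chi-square with non-centrality

    quantitative:  lambda = n * 2f(1-f) * beta^2      (phenotype variance 1)
    binary:        lambda = 2f(1-f) * beta^2 * n_cases*n_controls / n

with beta on the log-odds scale for binary traits. Power at significance
threshold alpha is P(X > q) with X ~ chi2(1, lambda) and q the central
chi2(1) 1-alpha quantile. A power curve is the inverse: the minimum
detectable |beta| across the allele-frequency spectrum for a fixed sample
size, alpha and target power — obtained by solving for lambda* once per
(alpha, level) and mapping back through beta = sqrt(lambda* / (n_eff
2f(1-f))).

:func:`empirical_power` is a direct Monte-Carlo oracle that simulates
genotypes and phenotypes and runs the test per replicate; it exists to
validate the closed form, not to replace it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "PowerCurveSpec",
    "PowerCurve",
    "noncentrality",
    "analytic_power",
    "beta_for_power",
    "build_power_curves",
    "empirical_power",
]

DEFAULT_ALPHA = 5e-8
DEFAULT_LEVELS = (0.5, 0.7, 0.9)


@dataclass
class PowerCurveSpec:
    """Parameters of the power model and of the frequency grid.

    ``n`` is the study sample size (for binary traits give ``n_cases`` and
    ``n_controls``; ``n`` then defaults to their sum). The frequency grid is
    log-spaced on [f_min, f_max] so curves render smoothly on the log10 axis
    down to rare frequencies.
    """

    n: int = 0
    alpha: float = DEFAULT_ALPHA
    trait_model: str = "quantitative"
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    power_levels: Sequence[float] = DEFAULT_LEVELS
    f_min: float = 1e-5
    f_max: float = 0.5
    n_grid: int = 200

    def __post_init__(self) -> None:
        if self.trait_model == "binary":
            if self.n_cases is None or self.n_controls is None:
                raise ValueError("binary trait model needs n_cases and n_controls")
            if self.n <= 0:
                self.n = self.n_cases + self.n_controls
        if self.n <= 0:
            raise ValueError("sample size n must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not all(0.0 < p < 1.0 for p in self.power_levels):
            raise ValueError("power levels must be strictly inside (0,1)")
        if not (0.0 < self.f_min < self.f_max < 1.0):
            raise ValueError("frequency grid must lie strictly inside (0,1)")

    @property
    def effective_n(self) -> float:
        """Sample size entering lambda: n, or n_cases*n_controls/n (binary)."""
        if self.trait_model == "binary":
            return self.n_cases * self.n_controls / (self.n_cases + self.n_controls)
        return float(self.n)

    def freq_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.f_min), np.log10(self.f_max), self.n_grid)


@dataclass
class PowerCurve:
    """Minimum detectable effect across the frequency grid for one level."""

    level: float
    freqs: np.ndarray
    beta_min: np.ndarray
    mirrored: bool = False

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.freqs.tolist(), self.beta_min.tolist()))


def _check_freq(freq) -> np.ndarray:
    f = np.asarray(freq, dtype=float)
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise ValueError(f"frequency must be in open interval (0,1), got {freq!r}")
    return f


def noncentrality(freq, beta, spec: PowerCurveSpec):
    """Non-centrality lambda of the 1-df association test."""
    f = _check_freq(freq)
    b = np.asarray(beta, dtype=float)
    lam = spec.effective_n * 2.0 * f * (1.0 - f) * b * b
    return float(lam) if np.isscalar(freq) and np.isscalar(beta) else lam


@lru_cache(maxsize=128)
def _crit(alpha: float) -> float:
    return float(stats.chi2.isf(alpha, df=1))


def analytic_power(freq, beta, spec: PowerCurveSpec):
    """P(reject at alpha) under the non-central chi-square alternative."""
    lam = np.asarray(noncentrality(freq, beta, spec))
    q = _crit(spec.alpha)
    out = np.where(lam == 0.0, spec.alpha, stats.ncx2.sf(q, df=1, nc=np.maximum(lam, 1e-300)))
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=1024)
def lambda_for_power(alpha: float, level: float) -> float:
    """lambda* with ncx2(1, lambda*) tail mass `level` above the alpha cutoff.

    Monotone root-find bracketed from [0, 10q] and expanded if needed;
    bisection-safe via brentq, tolerance well below 1e-10 in power.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"power level must be in (0,1), got {level}")
    if level <= alpha:
        raise ValueError(
            f"target power {level} <= alpha {alpha}: below the null rejection rate"
        )
    q = _crit(alpha)

    def g(lam: float) -> float:
        return stats.ncx2.sf(q, df=1, nc=lam) - level if lam > 0 else alpha - level

    hi = 10.0 * q
    while g(hi) < 0.0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - unreachable for sane alpha/level
            raise RuntimeError("failed to bracket lambda*")
    return float(brentq(g, 0.0, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200))


def beta_for_power(freq, level: float, spec: PowerCurveSpec):
    """Minimum |beta| reaching `level` power at frequency `freq`."""
    f = _check_freq(freq)
    lam = lambda_for_power(spec.alpha, float(level))
    b = np.sqrt(lam / (spec.effective_n * 2.0 * f * (1.0 - f)))
    return float(b) if np.isscalar(freq) else b


def build_power_curves(spec: PowerCurveSpec, mirrored: bool = False) -> list[PowerCurve]:
    """One curve per power level over the spec's frequency grid.

    Higher levels give uniformly larger minimum effects, so curves never
    cross.
    """
    freqs = spec.freq_grid()
    return [
        PowerCurve(
            level=float(level),
            freqs=freqs,
            beta_min=np.asarray(beta_for_power(freqs, float(level), spec)),
            mirrored=mirrored,
        )
        for level in spec.power_levels
    ]


def _simulate_quantitative(rng, n, f, beta, replicates, chunk):
    """Per-replicate OLS Wald test on simulated genotype/phenotype data."""
    var_g = 2.0 * f * (1.0 - f)
    explained = var_g * beta * beta
    if explained >= 1.0:
        raise ValueError(
            f"2f(1-f)beta^2 = {explained:.3f} >= 1: effect explains the full "
            "phenotypic variance under the standardized convention"
        )
    resid_sd = np.sqrt(1.0 - explained)
    pvals = np.empty(replicates)
    done = 0
    while done < replicates:
        m = min(chunk, replicates - done)
        g = rng.binomial(2, f, size=(m, n)).astype(np.float64)
        y = beta * g + resid_sd * rng.standard_normal((m, n))
        sg = g.sum(axis=1)
        sy = y.sum(axis=1)
        sxx = (g * g).sum(axis=1) - sg * sg / n
        sxy = (g * y).sum(axis=1) - sg * sy / n
        syy = (y * y).sum(axis=1) - sy * sy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            bhat = sxy / sxx
            rss = syy - bhat * sxy
            sigma2 = rss / (n - 2)
            z2 = bhat * bhat * sxx / sigma2
        p = stats.chi2.sf(z2, df=1)
        p[~np.isfinite(p)] = 1.0  # monomorphic draw: no test, never rejects
        pvals[done : done + m] = p
        done += m
    return pvals


def _simulate_binary(rng, spec, f, beta, replicates, chunk):
    """Case-control sampling with the logistic score test per replicate."""
    n_cases, n_controls = spec.n_cases, spec.n_controls
    n = n_cases + n_controls
    # allele frequency in cases under a multiplicative (log-additive) model
    f_case = f * np.exp(beta) / (1.0 - f + f * np.exp(beta))
    ybar = n_cases / n
    pvals = np.empty(replicates)
    done = 0
    while done < replicates:
        m = min(chunk, replicates - done)
        g_case = rng.binomial(2, f_case, size=(m, n_cases)).astype(np.float64)
        g_ctrl = rng.binomial(2, f, size=(m, n_controls)).astype(np.float64)
        s1 = g_case.sum(axis=1)
        s_all = s1 + g_ctrl.sum(axis=1)
        ss_all = (g_case * g_case).sum(axis=1) + (g_ctrl * g_ctrl).sum(axis=1)
        gbar = s_all / n
        u = s1 - n_cases * gbar
        v = ybar * (1.0 - ybar) * (ss_all - n * gbar * gbar)
        with np.errstate(divide="ignore", invalid="ignore"):
            z2 = u * u / v
        p = stats.chi2.sf(z2, df=1)
        p[~np.isfinite(p)] = 1.0
        pvals[done : done + m] = p
        done += m
    return pvals


def empirical_power(
    freq: float,
    beta: float,
    spec: PowerCurveSpec,
    replicates: int = 10_000,
    seed: int = 0,
    chunk: int = 2_000,
) -> float:
    """Monte-Carlo power: fraction of simulated studies rejecting at alpha."""
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    f = float(_check_freq(freq))
    rng = np.random.default_rng(seed)
    if spec.trait_model == "binary":
        pvals = _simulate_binary(rng, spec, f, beta, replicates, chunk)
    else:
        pvals = _simulate_quantitative(rng, spec.n, f, beta, replicates, chunk)
    return float(np.mean(pvals < spec.alpha))
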