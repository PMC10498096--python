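# Methods

This note documents the statistical model behind the package, the design
choices that were genuinely open, the defaults and what they mean, and what
the synthetic-data generator does and does not emulate.

## Power model

The single-variant additive association test (score or Wald, 1 df) has an
asymptotic non-central χ² distribution. For a quantitative trait with
phenotype variance standardized to 1 and genotype coded 0/1/2 at effect
allele frequency f, the non-centrality is

    λ = n · 2f(1−f) · β²,

i.e. sample size times the variance explained by the variant. For binary
traits β is a log odds ratio and n is replaced by the effective sample size
n_cases·n_controls/(n_cases+n_controls), the standard consequence of the
log-OR variance approximation Var(β̂) ≈ [2f(1−f)]⁻¹ · n/(n_cases·n_controls).
Power at threshold α is P(χ²₁(λ) > q) with q the central χ²₁ 1−α quantile.

The minimum detectable effect — the quantity a power curve plots — inverts
this: λ*(α, p) is found once per (α, p) by a bracketed Brent root-find on
the non-central χ² survival function (bracket [0, 10q], expanded if needed;
xtol 10⁻¹², far below the 10⁻¹⁰-in-power target), then

    β_min(f) = sqrt(λ* / (n_eff · 2f(1−f))).

Two consequences used as internal checks: β_min scales exactly as n^(−1/2)
(quantitative), and at p = 0.5, λ* ≈ q (by the normal approximation
sqrt(χ²₁(λ)) ≈ N(sqrt(λ), 1)).

**Choices.** The trait-model formulation of a published power curve is often
unstated; the package defaults to the quantitative model and exposes the
binary one explicitly. The binary closed form is a small-log-OR
approximation: the Monte-Carlo oracle agrees within ~2 binomial SDs at
|β| ≤ 0.1 but drifts a few percent high by β ≈ 0.2 (retrospective sampling
concentrates information beyond the first-order formula). The quantitative
closed form is exact to Monte-Carlo resolution across the tested grid.

The frequency grid for curves is log-spaced (default 200 points,
f ∈ [10⁻⁵, 0.5]) to match the log₁₀ axis; power levels default to
0.5/0.7/0.9 and α to 5×10⁻⁸ (genome-wide significance).

`empirical_power` simulates genotypes Binomial(2, f) and phenotypes
β·g + N(0, 1 − 2f(1−f)β²) per replicate and runs the OLS Wald test
(vectorized in chunks); binary traits are simulated case-control with the
per-allele frequency shift f·e^β/(1−f+f·e^β) and tested with the logistic
score statistic. It exists purely as an oracle for the closed form.

## Allele orientation

Flipping a record to its other allele maps (f, β) → (1−f, −β) and swaps the
allele labels; se, P and n are untouched. Both canonical orientations are
idempotent transforms:

- *minor-allele signed* (default): flip iff f > 0.5. f = 0.5 is a tie and
  is left unchanged — deterministic and stable under re-application.
- *positive-effect*: flip iff β < 0. β = 0 has no defined sign and is kept.

2f(1−f)β², hence λ, hence power, is invariant — verified property-style
over random records. The minor allele is defined from the study's own
frequency, not a reference panel (single-study tool; a panel lookup would
drag in ancestry matching that is out of scope).

## Independent significant variants

**Clumping.** Candidates are variants with P below the significance
threshold and MAF ≥ maf_min (defaults 5×10⁻⁸ and 0.01). Greedy loop: take
the unassigned candidate with the smallest P as lead; absorb unassigned
candidates on the same chromosome with |Δpos| ≤ window (default 100 kb,
measured lead-to-candidate, not chained) AND r² ≥ threshold (default 0.1 —
exposed as a flag since published analyses often leave it unstated). Ties
on P break by distance-to-lead then id, so the result is independent of
input row order. The output partitions the candidate set, and leads
pairwise fail the joint window-and-r² condition; both facts are checked
exhaustively in tests rather than assumed.

**Stepwise conditional/joint selection.** An approximation of
conditional-and-joint analysis from summary statistics, per chromosome.
Marginal effects are standardized to the correlation scale, b = z/√n with
z = β̂/se. Given a selected set S with LD submatrix R_S:

- joint effects: b_J = R_S⁻¹ b_S, with SEs sqrt(diag(R_S⁻¹)/n), mapped back
  to the per-allele input scale through each variant's own se·√n factor;
- a candidate c's conditional z: (z_c − R_{c,S} R_S⁻¹ z_S) / sqrt(1 −
  R_{c,S} R_S⁻¹ R_{S,c}).

Selection starts at the smallest marginal P and adds the candidate with the
smallest conditional P while it clears the threshold. Candidates with
r² > 0.9 against the model are skipped (collinearity cap); a near-singular
R_S (condition number > 10⁸) drops the last-added variant with a warning.
LD between variants further apart than the window is treated as zero
(banded approximation). The candidate pool is every variant the LD
reference covers, not only marginally significant ones — conditioning can
unmask variants whose marginal signal is cancelled by an opposite-sign LD
partner, and restricting the pool would make that impossible. A marginally
significant variant missing from the LD reference is an error; providing a
regional panel around significant loci is sufficient and expected.

With identity LD the procedure reduces exactly to marginal thresholding
with joint = marginal estimates. Against individual-level multivariate
regression on simulated cohorts (2,000 individuals, 8-variant blocks at
r ≈ 0.5, two causal variants of opposite sign), joint betas agree well
within sampling error (observed max ≈ 0.08 SE over 20 cohorts).

LD references store signed allelic correlations with unit diagonal, either
given directly (TSV matrix) or computed from a small dosage matrix. When
the reference records which allele its correlations are signed to, stepwise
aligns signs to the summary-statistics effect alleles before conditioning;
clumping only uses r², which is orientation-free.

## Plotting

x = frequency on log₁₀ (ticks at powers of ten), y = β. Point area maps
|β| linearly between configurable bounds (area, not radius — size should be
perceptually proportional); color is −log₁₀(P) on viridis, capped at 50 by
default so that the astronomically significant hits of biobank GWAS do not
flatten the scale. The display filter `min_effect_display` drops |β|
strictly below the threshold — a record at exactly the threshold is kept —
and the dropped count is reported, so retained + dropped always equals the
input count. Variants rarer than the axis minimum are clipped to the edge
with a warning, never silently dropped: rare large-effect singletons are
the plot's subject. In signed mode the power curves are mirrored to ±β_min,
producing the two-sided trumpet.

The interactive output is a single self-contained HTML file written by the
package itself: an SVG whose circles carry the configured hover fields both
as native `<title>` tooltips and as `data-` attributes, serialized in
sorted variant order. No JavaScript framework or plotting service is
involved, which is what makes re-rendering byte-identical and the artifact
archivable. Static output goes through matplotlib with a fixed SVG hash
salt and no date metadata, for the same reason.

## Synthetic data

The generator emulates the mixed architecture the plot is designed to show:
m_common array-like variants (log₁₀ f uniform on [−2, −0.3]) arranged in
compound-symmetric LD blocks on one chromosome, plus m_rare exome-like
variants (log₁₀ f uniform on [−5, −2]) that are LD-free, singleton-like and
tagged `source=exome` with gene labels. Causal effects follow

    β | causal ~ N(0, τ² / (2f(1−f))^γ),  γ ∈ [0, 1],

the standard frequency-dependent architecture family: γ = 0 means
frequency-independent effects, γ = 1 equal expected variance explained per
causal variant. Defaults: N = 351,550 (a realistic median biobank GWAS
sample size), 18,000 common + 2,000 rare variants, causal fraction 0.2,
τ = 0.05 phenotypic SD, γ = 0.5, blocks of 10 at r = 0.8. With these
settings common causal effects are a few hundredths of an SD and rare
causal effects order 0.1–1 SD, which yields a clear two-sided trumpet among
significant variants without asserting any specific trait's genetics.

Emitted statistics follow the standard summary-statistics sampling model on
the standardized scale: within a block, E[b̂] = R·b_true and the noise is
MVN(0, R/n); per-variant se = 1/sqrt(n·2f(1−f)); P is the two-sided normal
tail of β̂/se (identically χ²₁ of z²), clamped to the smallest positive
double when z is extreme (at N = 351,550 genuine underflow is routine). For
LD-free variants this reduces to β̂ = β_true + N(0, se²). The LD-aware form
matters: without it, proxies of causal variants would show no marginal
signal and clumping on simulated data would have nothing to absorb.

The individual-level cohort generator (for oracle tests at small n) draws
two latent Gaussian haplotypes per person with a block correlation
calibrated so that the *thresholded* dosages achieve the requested
correlation (thresholding attenuates latent correlation; the calibration
solves for the latent value by bisection on the bivariate-normal orthant
probability, and warns when a target is infeasible for very asymmetric
frequencies). Phenotype is Σβ·g plus Gaussian noise scaled to unit total
variance; a genetic variance ≥ 1 is an error.

What the generator does **not** emulate: realistic haplotype structure or
recombination maps (compound-symmetric blocks only), allele-frequency
spectra from demography (uniform on log f by construction), binary-trait
liability, imputation error, winner's curse in the emitted effects, or
population stratification. Passing tests therefore demonstrate correctness
of the statistical machinery under a controlled architecture, not
robustness to every artifact of real cohort data.

## Numerical and interface choices

- P = 0 on input is clamped to the smallest positive double with a warning
  (−log₁₀ P must stay finite); eaf ∈ {0, 1} is rejected (2f(1−f) = 0 breaks
  both power and flipping).
- Odds ratios must be log-transformed upstream; the reader deliberately
  does not guess the scale of an effect column.
- Coordinates are 1-based point positions, the summary-statistics
  convention. Alleles are uppercased; no strand flipping or palindrome
  resolution is attempted (single-study tool, not a meta-analysis
  harmonizer).
- Chromosome sort order: numeric chromosomes first (1 < 2 < ... < 22), then
  lexicographic (MT, X, Y).
- All simulations take explicit seeds; pipeline artifacts (selection TSV,
  curve TSV, SVG, HTML, JSON report) are byte-reproducible for a fixed
  config and seed. The run report carries counts (input = retained +
  rejected), thresholds, seed and version, and never a timestamp, precisely
  so that two identical runs produce identical bytes.
- Test problem sizes (10,000-replicate Monte-Carlo cells, 20 oracle
  cohorts of 2,000 individuals, one 20,000-variant biobank-scale
  simulation) were chosen so the full suite exercises every claim in
  minutes on a laptop while keeping binomial/sampling error well below the
  tolerances being asserted.

## Known limitations

- The stepwise procedure is a desk-scale approximation of full
  conditional/joint analysis: forward-only (no backward elimination), exact
  LD assumed known (no reference-panel noise model), banded window.
- Binary-trait power is first-order in the log OR (see above); rare-variant
  binary power additionally suffers instabilities the model does not
  capture.
- The interactive HTML is intentionally minimal (native tooltips, no zoom
  or pan).
- No multi-ancestry support: one study, one frequency column.
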