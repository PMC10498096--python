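# trumpetplot

Tools for **trumpet plots**: the scatter of per-variant effect size (y)
against allele frequency (x, log₁₀ scale) used to summarize the genetic
architecture of a complex trait across the full frequency spectrum. Genetic
association results characteristically fan out into a trumpet shape — many
common variants with small effects, a thin tail of rare variants with large
effects — and overlaying analytic power curves shows which parts of that
space a study could actually detect.

The package is aimed at statistical geneticists working with GWAS and
exome-association summary statistics. It provides:

- **I/O** for tab/comma-delimited summary-statistics tables in common column
  dialects (`SNP`/`rsid`, `A1`/`effect_allele`, `AF`/`EAF`, `BETA`, `SE`,
  `P`, ...), with per-row validation and a load report.
- **Allele harmonization** to the two standard orientations: *minor-allele
  signed* (frequencies in (0, 0.5], signed effects — recommended) and
  *positive-effect* (effects ≥ 0, frequencies in (0, 1)).
- **Power curves.** For the 1-df additive association test the statistic is
  non-central χ² with non-centrality λ = n·2f(1−f)·β² (quantitative trait,
  unit phenotype variance; binary traits use the effective sample size
  n_cases·n_controls/n with β a log odds ratio). The minimum detectable
  effect at target power p and threshold α is

      β_min(f) = sqrt(λ*(α, p) / (n · 2f(1−f)))

  where λ* solves P(χ²₁(λ) > q_{1−α}) = p. A Monte-Carlo simulator
  (`empirical_power`) validates the closed form.
- **Independent significant variants** from summary statistics plus an LD
  reference: greedy clumping (lead = smallest P, absorb within a window and
  above an r² threshold) and forward stepwise conditional/joint selection
  with joint effect estimates (b_J = R_S⁻¹ b on the standardized scale).
- **Rendering**: static SVG/PNG/PDF via matplotlib and a dependency-free
  standalone interactive HTML with per-point hover payloads.
- **A synthetic-data generator** producing trumpet-shaped summary statistics
  (frequency-dependent effect prior β|causal ~ N(0, τ²/(2f(1−f))^γ), LD
  blocks, rare exome-like singletons) and matching individual-level cohorts
  for oracle testing.

## Worked example

Simulate a biobank-scale study (N = 351,550; 2,000 common variants in LD
blocks + 200 rare exome-like variants), then run the full pipeline —
harmonize, clump, power curves, plots:

```bash
cat > sim.yaml <<EOF
seed: 42
n_gwas: 351550
m_common: 2000
m_rare: 200
EOF
trumpet simulate --config sim.yaml --out sumstats.tsv --truth truth.tsv
# wrote 2200 simulated records to sumstats.tsv
```

An LD reference for the significant variants (here taken from the
generator's own block structure via `trumpetplot.expected_ld`; with real
data you would supply a correlation matrix or a small genotype panel):

```python
import trumpetplot as tp
from trumpetplot.ld_select import write_ld_matrix
cfg = tp.SimConfig(seed=42, n_gwas=351550, m_common=2000, m_rare=200)
table, _ = tp.simulate_sumstats(cfg)
sig = [r.variant_id for r in table.records
       if r.pvalue < 5e-8 and min(r.eaf, 1 - r.eaf) >= 0.01]
write_ld_matrix(tp.expected_ld(cfg, sig), "ld.tsv")
```

```bash
cat > run.yaml <<EOF
sumstats: sumstats.tsv
ld: ld.tsv
n: 351550
out_dir: out
method: clump
seed: 1
EOF
trumpet run --config run.yaml
# done: 2200 rows in, 2200 retained, 146 selected; artifacts in out
```

The run reduced 1,293 genome-wide-significant candidates (P < 5×10⁻⁸,
MAF > 0.01, within the GWAS stream) to 146 independent lead variants
(100-kb window, r² ≥ 0.1). `out/` contains `selected.tsv`,
`power_curves.tsv`, `trumpet.svg`, `trumpet.html` and `report.json`:

```
variant_id          chrom  pos_bp     beta     se      pvalue  n_absorbed
1:100000001:c1000   1      100000001  0.7965   0.0106  5e-324  9
1:105000001:c1050   1      105000001  -0.1590  0.0035  5e-324  9
...
```

and the report's counts are a complete audit of the run:

```json
"counts":    {"input_rows": 2200, "retained": 2200, "rejected": 0},
"selection": {"method": "clump", "n_candidates": 1293, "n_selected": 146},
"plot":      {"points_static": 146, "points_interactive": 114,
              "dropped_interactive": 32, ...}
```

The interactive plot drops the 32 selected variants with |β| < 0.05 (the
default display threshold for HTML output, keeping file sizes sensible);
the static SVG keeps all 146. Hovering a point shows the variant id,
effect size, gene (if any), P-value and trait.

Power curves alone, as a table:

```bash
trumpet power --n 351550 --alpha 5e-8 --levels 0.5,0.7,0.9 --fmin 1e-5
# level  freq      beta_min
# 0.5    1e-05     2.05586
# 0.5    1.056e-05 2.00073
# ...
```

Read: at frequency 10⁻⁵ and this sample size, a variant needs a per-allele
effect of about two phenotypic SDs to be detected half the time at genome-
wide significance — the rare edge of the trumpet.

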