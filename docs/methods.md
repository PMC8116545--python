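# Methods

## Scope and model

`methconsist` studies the agreement of differentially methylated gene (DMG)
calls across bisulfite-sequencing assays that cover different parts of the
genome. The package operates entirely at the level of per-site read counts:
read trimming, alignment, and strand handling are upstream of its inputs,
and non-CpG (CHG/CHH) contexts are out of scope. Coordinates are 0-based,
half-open everywhere, matching BED.

### Synthetic genome

The genome generator places, per chromosome of length `L`:

* **CpG islands** — intervals arriving as a Poisson process
  (`island_rate` per bp, default 3×10⁻⁵) with uniform lengths
  (500–2,000 bp); overlaps are merged.
* **CpG sites and CCGG motifs** — piecewise-homogeneous Poisson processes
  whose rates are higher inside islands (sites: 0.02 vs 0.005 per bp;
  CCGG: 0.0125 vs 0.0025 per bp, a 5:1 island enrichment). The CCGG
  densities were set so that the reduced-representation footprint measures
  roughly half of the genes, the regime reported for real RRBS cohorts
  relative to genome-wide assays.
* **Genes** — `n_genes` non-overlapping intervals (rejection sampling;
  a capacity error is raised when the request cannot be satisfied), lengths
  uniform in 1–3 kb. Gene placement is independent of islands.
* **Assay footprints** — a capture panel of `panel_size` genes (default 60
  of 100; capture designs typically target more genes than restriction
  digests reach), an array probe set (`probe_fraction` = 0.15 of sites), and
  2% of non-gene sites reserved as unmethylated spike-in controls for
  conversion-rate QC.

### Ground truth

Baseline per-site methylation is a bimodal beta mixture shared by all
samples: island sites ~ Beta(0.5, 5) (low mode) and non-island sites ~
Beta(5, 0.5) (high mode), the standard stylization of somatic methylomes.
Control sites are pinned to 0. Effect genes (default 50 hypo + 5 hyper,
a 10:1 hypo-dominant ratio chosen to emulate the direction imbalance
reported in liver-tumor methylome comparisons) shift the tumor-group mean of
every site in the gene by ±δ (default 0.3), clipped to [0, 1]; a warning is
emitted when clipping destroys an effect (e.g. a hyper effect on an
already-high gene). Because truth is shared within a group, cohorts of any
size can be subset from one draw.

### Read counts

Per covered site and sample, depth is negative-binomial
(var = μ + φμ², φ = 0.2) with assay-specific means — 30 (WGBS), 60 (RRBS),
100 (targeted) — reflecting that assays concentrating reads on fewer sites
run deeper. A read reports cytosine with probability
`p = m(1 − e_over) + (1 − m)(1 − conv)` and is flipped with probability
`seq_err`; defaults `conv` = 0.995, `e_over` = 0.005, `seq_err` = 0.001 are
typical published assay values. An optional beta overdispersion of the
per-cell methylation probability (`bb_phi`, default 0 = pure binomial) is
available but off, so that the count-based tests' sampling assumptions hold
under the default null (see *Calibration* below). The RRBS footprint is
computed from consecutive CCGG positions with the 40–220 bp retention
filter; the targeted footprint is the panel's gene intervals; the array
reports `clip(m + N(0, 0.05), 0, 1)` at probe sites without counts.

## Analysis choices

* **Levels** are stored as fractions in [0, 1]; the percentage convention is
  purely presentational. Default coverage filter `min_cov` = 4 — a common
  minimal-coverage convention, exposed in config.
* **Gene scores** are unweighted means of non-missing site levels inside the
  gene interval (weighting by coverage is deliberately not done; the
  contract is asserted by test). Fold change is computed on per-sample gene
  scores, `|mean_tumor − mean_normal|`, with hypo meaning lower in tumor;
  τ = 0.15 on the fraction scale.
* **Count-based tests** pool reads over the sites and samples of each group
  (the methylKit-style convention); tallying methylated/unmethylated
  *samples* instead is available via `count_unit="sample"` with a 0.5 level
  threshold. Fisher's two-sided p sums hypergeometric probabilities not
  exceeding the observed table's. The Poisson–Wald statistic is
  `z = (ln r₁ − ln r₂)/√(1/C₁ + 1/C₂)` on methylated-read rates, with a
  +0.5 continuity correction (flagged) when a group has zero methylated
  reads. The ratio tests use Welch's unequal-variance t (moderated t is out
  of scope) and one-way ANOVA. Multiple testing uses Benjamini–Hochberg.
* **Consistency** restricts every dataset to the shared universe (genes with
  a non-missing score in at least one sample of each group in *every*
  dataset) before calling DMGs, then computes intersections, exclusive sets
  (members of exactly one dataset's DMG set), sign concordance over the
  common set, and hypergeometric overlap p-values.
* **Semantic similarity** uses Wang's graph-based measure (max-product
  S-values up the DAG, is-a weight 0.8, part-of 0.6 on read-in DAGs) with
  best-match-average combination at both the gene and the set level; it is
  the de-facto standard where the measure is otherwise unspecified.
  "Transitivity" is the node-level local clustering coefficient; betweenness
  is exact Brandes accumulation, unnormalized. Cross-dataset edge counts
  classify each network edge by the *exclusive* memberships of its
  endpoints (off-diagonal), while diagonals count edges internal to a set.
* **Toy annotation/network**: the DAG is a root plus `n_branches` complete
  binary subtrees; each gene is annotated within one branch, and the
  pipeline assigns true hypo-effect genes to one branch (hyper to another)
  so that functional coherence of true DMG sets — the property real disease
  genes exhibit — is present in the synthetic world. The interaction
  network is a planted partition with the same communities.

## Calibration regimes

Pooling reads across sites whose true methylation differs (the bimodal
baseline) with random depth weights overdisperses the pooled group
proportion, so Fisher, chi-square and Poisson–Wald are *anticonservative*
under the default generator (~0.13 empirical type-I at α = 0.05). This is a
property of pooled count tests on heterogeneous regions, not an
implementation artifact. The calibration tests therefore run each test
under its own assumed sampling model:

* Fisher / chi-square: homogeneous baseline Beta(1000, 1000) — one common
  proportion per region, making pooled counts binomial;
* Poisson–Wald: homogeneous low baseline Beta(100, 900) (rate ≈ 0.1), where
  binomial methylated-read counts are Poisson-approximable — at high rates
  the binomial-vs-Poisson variance mismatch (var ln(C/n) ≈ (1 − p)/C vs the
  Wald's 1/C) makes the test arbitrarily conservative;
* Welch t: the default bimodal baseline, since the ratio test only needs
  iid per-sample scores.

Under these regimes all four tests sit in [0.03, 0.07] at α = 0.05 over
2,000 null regions.

## Problem sizes

Defaults were chosen so that every experiment runs in seconds to tens of
seconds on one CPU: 2 chromosomes × 1 Mb (~11,000 CpG sites, 100 genes) for
the standard study; 1 × 3 Mb with 500 genes × 4 replicates (2,000 null
regions) for calibration; 10 replicate seeds for recovery and cross-assay
experiments; a 1 × 40 kb "tiny" fixture (≈250 sites, 10 genes, 2v2) for
end-to-end determinism checks.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes —
bimodal methylation, island-enriched reduced-representation coverage,
footprint nesting, hypo-dominant effects, binomial conversion chemistry —
but not sequence-level realism: no read alignment errors, no strand or
M-bias artifacts, no correlated neighboring sites, no copy-number or purity
effects, and effect genes shift all their sites uniformly. Passing the
recovery and consistency tests shows the pipeline is correct and
well-calibrated under these conditions; it does not certify performance on
real cohorts, where region heterogeneity and overdispersion (see
*Calibration*) make pooled count tests optimistic. The headline gene counts
of any real multi-assay comparison depend on the accessions and
preprocessing of that study and are not targets of the synthetic runs.

## Known limitations

* Fisher's exact test relies on scipy's implementation; for margins in the
  thousands (pooled genes) p-values are effectively continuous.
* The Wang-similarity null for *sets* is computed by drawing two independent
  random sets of the observed sizes; BMA of sizable random sets is itself
  high (≈0.95+ on the toy DAG), so observed-vs-null comparisons should use
  the quantiles, not the absolute scores.
* `>4` datasets are supported, but Venn-style intersection tables grow
  combinatorially; pairwise overlap tables are the intended summary there.
* OBO parsing is out of scope; DAGs are supplied as (child, parent,
  relation) edge lists.
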