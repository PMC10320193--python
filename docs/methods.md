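# Methods

## The setting

An allotriploid *Brettanomyces bruxellensis* isolate carries two copies of
a primary genome (2n) and one copy of an acquired, highly divergent
haploid subgenome (1n). Competitive mapping of RNA-seq reads against the
concatenation of both references assigns each read to its subgenome of
origin, giving, for every 2n↔1n ortholog pair, two counts per sample.
`subbias` asks three questions of such data: is the 1n subgenome globally
over- or under-expressed relative to its one-in-three copy-number
expectation; which individual genes deviate from their sample's own
2n-vs-1n relationship, consistently across a population; and which genes
distinguish populations once homeolog counts are collapsed.

## Simulator

The generator emulates the structure of a six-population survey:
Teq/EtOH (9 allotriploid samples), Beer (30), Wine 1 (6), Wine 2
(9, autotriploid), Wine 3 (26, diploid) and Kombucha (7, diploid).

* **Gene universe and abundance.** `n_genes` primary genes with
  log-normal relative abundance (`baseline_log_mean = 4`,
  `baseline_log_sd = 1`, natural-log scale — roughly three decades of
  expression, typical of yeast mRNA). Abundances are normalized to
  proportions and scaled to `library_size` expected reads per sample,
  with log-normal per-sample depth jitter (`library_log_sd = 0.1`).
* **Ortholog loss.** Each primary gene is retained on a population's
  acquired subgenome independently with probability 0.88 (Teq/EtOH),
  0.70 (Beer) or 0.75 (Wine 1) — the observed transfer fractions of the
  emulated design. Independence is a simplification: real loss of
  heterozygosity removes correlated chromosomal tracts, and losses are
  partly shared between lineages, so the real shared ortholog core
  (2,819 of 5,206 genes) exceeds the independence expectation
  (0.88·0.70·0.75·5,206 ≈ 2,405). Analyses that depend only on the core's
  size scale accordingly; none depend on its genomic layout.
* **Counts.** A gene's total count is negative-binomial with mean λ and
  dispersion α (`variance = λ + αλ²`, default α = 0.05 — moderate
  biological replication noise for natural isolates). For allotriploid
  samples the total is thinned binomially with the gene's haploid
  allocation `p_g`: 1n ~ Binomial(total, p_g), 2n = total − 1n. This
  mirrors competitive read assignment and makes 2n + 1n = total exact.
  α = 0 switches to deterministic expectation mode (counts are rounded
  means, the split is exact) for arithmetic tests.
* **Truth.** `n_bias_genes` drawn from the shared core get allocation
  `bias_allocation` (default 0.6) instead of the 1/3 null;
  `n_de_genes` (disjoint from bias genes) get a ±`de_log2fc` expression
  shift in one population (populations cycled, signs alternated).
  The truth table records allocation, bias direction, DE population and
  per-population 1n presence for every gene.

The default scale (500 genes, 2×10⁵ reads) keeps test runs in seconds;
`SimulationConfig.full_scale()` switches to the 5,206-gene universe.
What the simulator does **not** model: mapping error between subgenomes,
gene-length-dependent detection bias, GC/positional biases, correlated
LOH tracts, and expression correlation between genes. Passing tests
therefore demonstrate correctness and calibration of the inference under
idealized assignment, not robustness to mapping artifacts.

## Haploid fraction and its test

For sample *s*, `f_s = Σ 1n / (Σ 1n + Σ 2n)` over ortholog pairs present
in both subgenomes. Equal per-copy expression implies `f = 1/3`. The
population-level test is a one-sample z across samples:
`z = (mean(f) − 1/3) / (sd(f)/√n)`, upper-tail normal p. A pooled-read
binomial z would treat reads as independent and wildly overstate
evidence; the across-sample form respects between-isolate variation. If
all fractions equal the expectation exactly (sd = 0), the statistic is
defined as z = 0, p = 0.5; sd = 0 elsewhere is an error.

## Per-sample regression and prediction outliers

Within each allotriploid sample, ordinary least squares of
`log2(1n + 1)` on `log2(2n + 1)` over ortholog pairs expressed in at
least one compartment (pairs at 0/0 are unexpressed and excluded; their
evaluability is tracked per gene). The log scale is the default because
raw-count OLS is dominated by the few highest expressors; `scale="raw"`
is available. Under the null the fitted line has slope ≈ 1 and intercept
≈ log2(1/2) = −1 (the single 1n copy yields half the reads of the two
2n copies).

A pair deviates when its observed 1n value falls outside the two-sided
prediction interval for a *new observation* at its 2n value:

    ŷ ± t_{1−(1−level)/2, n−2} · s · sqrt(1 + 1/n + (x − x̄)²/Sxx)

with `s² = RSS/(n−2)`. The default level 0.95 is a conventional choice;
under null simulations the empirical flag rate is ≈ 5% per sample
(slightly above, since log-count residuals are only approximately
normal), which the calibration tests pin down.

## Consistency calls and paired tests

Per population, a gene is consistently 1n-over (-under) expressed if it
deviates above (below) the interval in at least 25/30, 7/9 or 5/6
samples — the design's exact thresholds for those population sizes;
other sizes use `ceil(25/30 · n)`. Counting is direction-specific: 13
above plus 13 below out of 30 is *not* a call, because the target is
consistent over- or under-expression of one subgenome. Under the null
the probability of 25+ same-direction deviations at a 2.5% per-direction
rate is astronomically small, so the null consistent set is empty.

For visualization-grade effect sizes, each gene also gets a paired
t-test of 2n vs 1n expression across the population's samples, after
correcting each compartment by its library size computed over orthologs
present in both subgenomes (the same normalization base as the
regression rationale); p-values are Holm-adjusted within the population.
All-zero difference vectors return t = 0, p = 1; zero-variance nonzero
differences are an error. The paired test assumes one variance of
differences — a "paired Welch" variant is not meaningful.

## Collapsed counts and differential expression

For allotriploid samples, 1n counts are summed onto their primary
ortholog (genes without a retained ortholog keep their 2n count),
yielding a primary-genome gene universe comparable with diploid and
autotriploid samples.

DE is one population versus all others pooled, per gene, on collapsed
counts: median-of-ratios size factors (median over all-positive genes of
count/geometric-mean; factors on the natural ratio scale), gene-wise
dispersion by *within-group* method of moments on normalized counts
(`α = (var − μ)/μ²`, pooled across the two groups by df, floored at
1e−8 — within-group so a real contrast effect does not inflate
dispersion), then a two-group NB GLM with log link and size-factor
offsets (statsmodels IRLS). Wald z = log2FC/se, two-sided normal p, BH
across testable genes; all-zero genes are reported with missing
statistics outside the BH family. This is a deliberately minimal NB Wald
engine — no dispersion-trend shrinkage, no LFC shrinkage, no independent
filtering. With 87 samples the moment estimator is adequate, and the
engine is held to calibration tests (null raw-p uniformity, zero BH
discoveries) rather than to agreement with any richer implementation.

DE call: `padj < 0.05` and `|log2FC| > 1`. Signatures: within each
direction of the DE set, `|log2FC| > 1.6` and adjusted p *strictly*
below the direction's median adjusted p (ties at the median excluded, so
a single DE gene in a direction yields no signature). Adjusted p is used
for the top-half rule for internal consistency with the DE filter.

One subtlety the recovery tests respect: a gene truly DE in population P
also shifts the focal-vs-rest contrast of every other population
(the rest group contains P), so gene-level truth — DE in *some*
population — is the correct reference for empirical FDR.

## Enrichment and ordination

Per GO term (within BP/MF/CC separately): upper-tail hypergeometric p
for the DE-set overlap and the enrichment score
`(n_DE∧term/n_DE) / (n_universe∧term/n_universe)`; BH within category;
significant at adjusted p < 0.1. The test is a plain hypergeometric with
no gene-length weighting — appropriate here because the simulated data
carry no length-dependent detection bias; on real data with such bias a
length-aware method should replace it.

PCA treats samples as observations and genes as centered features
(typically of log2 CPM or shared-core-normalized counts); component
signs are fixed so each component's largest-magnitude loading is
positive. Spearman correlation uses average ranks for ties.

## Ortholog transfer filter

From BLAST tabular hits (`-outfmt 7`; the `query length` field is
required): keep hits with identity ≥ 85% and alignment length strictly
greater than 95% of the query length ("at least 85%" vs "above 95%" —
inclusive and strict bounds respectively); per query keep the best
surviving hit (highest bit score, ties to the lexicographically smaller
target); enforce injectivity on targets (higher bit score wins, ties to
the lexicographically smaller query; the loser is dropped, not
reassigned). Survival is monotone in both thresholds; the resolution
step is deterministic but not monotone — tightening a threshold can
remove a competitor and let a previously losing pair through, which is
inherent to any best-hit scheme. Expected upstream BLAST provenance
(e-value ≤ 1e−10, `-perc_identity 70`, `-max_target_seqs 3`) is
documented, not enforced.

## Numerical and interface choices

* Pseudocount 1 before log2 (zeros map to 0); CPM scale 10⁶. Ordination
  is invariant to the scalar.
* All thresholds (0.05, 1, 1.6, prediction level 0.95, consistency
  fractions, 85/95 transfer bounds) live in one pipeline config block
  with those defaults.
* One base seed drives everything; derived stage seeds are fixed
  offsets. Pipeline reruns are byte-identical; the manifest stores
  SHA-256 hashes of every artifact.
* Problem sizes in the test and acceptance runs (300–2,000 genes,
  2×10⁵–10⁶ reads) are reduced-scale choices that keep Monte-Carlo error
  small relative to the tested tolerances while completing in seconds to
  minutes.

## Known limitations

* Independent ortholog loss under-predicts correlated-LOH shared cores
  (see above).
* The minimal NB Wald engine has less power at small n than
  shrinkage-based engines; with ≤6 samples per group its dispersion
  estimates are noisy.
* The plain hypergeometric enrichment ignores gene-length bias.
* Multi-mapped-read rescue, mapping error and assembly quality are
  upstream of this package and outside its scope.
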