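# Methods

## Scope and model

`ruminet` reconstructs a classic small-cohort, two-condition transcriptomics
workflow — the kind used to contrast liver expression of goats on
high-concentrate (HC) versus low-concentrate (LC) diets with 4 and 3 arrays
respectively — as a tested, reusable pipeline over four analysis stages:

1. **Differential expression.** Input is a gene-by-sample matrix of
   normalized log2 intensities (normalization is upstream of this package:
   the generator emits already-normalized values, and real inputs are
   assumed normalized too). Per gene, the log2 fold change is the mean
   difference HC − LC; the per-gene test is Welch's two-sample t-test on the
   log2 values. Welch is our default because with n = 3 vs 4 an
   equal-variance assumption buys little and costs robustness; the test is
   a pluggable callable so an exact permutation test can substitute at tiny
   n. Raw p-values are adjusted by Benjamini–Hochberg (`statsmodels`), and a
   gene is selected iff FC = 2^|log2FC| ≥ `fc_threshold` (default 2) and
   adjusted FDR < `fdr_threshold` (default 0.05; 0.10 and an extra raw-p
   gate are configuration options, since workflows of this kind variously
   report FDR < 5%, FDR < 10% and adjusted p < 0.01 gene lists).

2. **Category enrichment.** Each annotated category yields a 2×2 table
   (nf flagged in category, n in category, Nf flagged in background, N
   background). Two statistics are computed per category: a two-sided
   Fisher exact p using the minimum-likelihood convention (sum of
   hypergeometric outcomes no more probable than the observed table — the
   same convention as SciPy and R; we state it because doubling the smaller
   tail is a genuinely different definition), and a Pearson χ² p on 1 df
   without continuity correction. Two error summaries are reported side by
   side and clearly labeled: the *empirical FDR* 1 − Nk/T, where Nk counts
   categories whose Fisher p falls below their χ² p among the T categories
   tested, and BH over the Fisher p-values (`fdr_bh`) as the practical
   per-category correction. The empirical FDR is a single global scalar
   attached to every record — the definition is only coherent as a global
   quantity, and we surface BH precisely because a per-category reading is
   what most users actually want. The enrichment ratio is
   Re = (nf/n)/(Nf/N). The background defaults to the annotated genes of
   the matrix and can be widened to all matrix genes; annotations are
   treated as flat sets (no ontology propagation).

3. **Co-expression networks.** For each condition separately, Pearson
   correlations are computed across that condition's samples over the
   selected gene set (any gene list can be supplied). An edge joins genes
   with |r| strictly greater than the threshold (default 0.999; ties at
   exactly 0.999 are excluded), carrying the signed r. Zero-variance genes
   are dropped before correlation with a logged warning. Hubs are
   summarized by raw degree ("link numbers"; a normalized degree/(|V|−1)
   column is also written) and by k-core decomposition (`networkx`
   `core_number`): a node's core index is the largest k such that it
   survives in the maximal subgraph of minimum internal degree k.

4. **Core regulators across conditions.** Every gene in either network gets
   degree_diff = degree_HC − degree_LC (absent nodes count 0); genes are
   ranked by |degree_diff| descending, ties broken by degree_HC then gene
   id, so condition-specific hubs rank first.

## The |r| > 0.999 rule at n = 3–4

This threshold looks stringent but is *permissive* at these sample sizes.
Under independence the null distribution of r on n points gives
P(|r| > 0.999) ≈ 2.9% at n = 3 (arcsine law) and exactly 0.1% at n = 4
(r is uniform on [−1, 1]). Consequently the 3-sample condition's network
carries a substantial load of chance edges: in a 149-node null network,
each node expects ~4 spurious neighbors on the 3-sample side. Two
consequences we deliberately surface rather than hide:

* condition-specific planted modules can pick up stray edges in their
  "inactive" condition, so a member's degree difference can fall slightly
  below the ideal m − 1;
* at large node counts, chance hubs on the 3-sample side can out-rank
  genuine condition-specific modules in the degree-difference table.

The threshold is a configuration value, never a constant, and reports
should be read with the group sizes in mind.

## Synthetic data generator

The generator emulates the study conditions every stage is tested under:
two conditions with unequal small n (3 LC vs 4 HC arrays), 10²–10⁴ genes
with baseline log2 intensities N(8, 2²), i.i.d. Gaussian noise on the log2
scale (sd 0.2 by default — the standard microarray log-intensity
assumption), planted DE genes at a signed log2FC of 2.0 (half up, half
down; condition HC shifted), planted correlation modules, and category
annotations that can over-sample the DE set.

Modules: each member gene is baseline + loading·z_s + residual, with one
latent factor z per sample (sd `latent_sd`), loadings ±1, and residual sd
`residual_sd`. Module variation *replaces* the global noise for member
genes, so `residual_sd = 0` makes every within-module pair exactly ±1 —
the limiting case that exercises the edge rule. `condition_specific`
modules receive independent same-scale noise in the inactive condition,
giving the degree-difference ranking a planted positive. Module genes are
drawn from the planted DE pool first so that modules survive DEG selection
and appear in the networks, mirroring a study that networks its DEGs; when
modules and DE coexist, keep `latent_sd` well below the planted log2FC or
module genes will rightly fail the FDR gate.

Annotations: `n_categories` categories with sizes uniform over
`category_size_range`; a `boosted_fraction` of them sample genes with odds
multiplied by `de_enrichment_boost` for DE genes (boost 1 ⇒ independence;
boost ∞ ⇒ DE-only categories). All randomness derives from one seed via
`numpy.random.SeedSequence` child streams; identical configurations are
byte-identical.

What the generator does **not** emulate: probe-level effects, array
normalization artifacts, correlated noise between genes outside planted
modules, heavy-tailed intensity distributions, or missing values. Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted structure under idealized noise — not
performance on raw array data.

## Numerical choices and degenerate inputs

* Welch p-values on rows with zero variance in both groups: p = 1 when the
  group means agree, p = 0 otherwise.
* Fisher p on tables with an empty margin: 1 (no information); same
  convention for χ². Near-ties in the minimum-likelihood sum are resolved
  with a 1e-9 relative tolerance, which for the universe sizes we verify
  exhaustively (N ≤ 30) provably separates exact ties from distinct
  probabilities.
* Hierarchical ordering for heatmap-style reports: average linkage on
  1 − Pearson distance, SciPy's deterministic tie-handling, zero-variance
  rows placed at a fixed distance 1 from everything.
* Empty graphs, empty DEG sets and empty annotation maps flow through every
  stage without error (reports render zero-count sections).
* The pipeline manifest records SHA-256 checksums of every artifact;
  determinism is asserted by re-running, not assumed.

## Problem sizes

The shipped configurations are sized for a laptop-class single CPU: the
demo pipeline uses 2,000 genes × 7 samples with 150 planted DEGs and four
modules of six genes; calibration checks use 50 null replicates of 2,000
genes; recovery checks use 20 replicates with 150 planted DEGs; oracle
equivalence checks enumerate all 46,375 contingency tables with N ≤ 30 and
200 random graphs of up to 12 nodes. The full test suite runs in well
under a minute.

## Known limitations

* The per-gene test and BH correction are standard choices for this design,
  not the only defensible ones; at n = 3 vs 4 a permutation test has very
  coarse granularity (35 distinct splits), which is why it is optional
  rather than default.
* The empirical FDR 1 − Nk/T is reproduced as defined; it is a global
  diagnostic of Fisher/χ² disagreement, not a per-category error rate, and
  should be read alongside `fdr_bh`.
* Degree-difference ranking inherits all the caveats of the 0.999 rule
  above; with 3 samples on one side it is best treated as a candidate
  screen, not an inference.
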