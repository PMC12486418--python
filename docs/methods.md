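# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Data model

All analyses consume a `CountTable` — a non-negative integer taxa × samples
matrix with duplicate-free identifiers. Rarefaction subsamples each sample
to a common depth **without replacement** (multivariate hypergeometric), so
a sample already at the target depth passes through unchanged and expected
proportions are unbiased; samples below the depth are dropped and logged
rather than silently padded. Relative abundances are column-closed
proportions validated to sum to 1 within 1e-9. Taxonomic aggregation sums
rows by rank label and pools lineages lacking the rank under
`norank_<parent>` sentinels, conserving the grand total exactly.

## Alpha diversity

Shannon entropy (natural log by default, base configurable), Simpson
**dominance** Σp² (higher = less diverse; chosen because the pond table
this toolchain mirrors lists its most diverse group with the smallest
Simpson value), bias-corrected Chao1 `S_obs + F1(F1−1)/(2(F2+1))` (well
defined at F2 = 0), classical ACE with rare/abundant cutoff 10, and Good's
coverage `1 − F1/N`. When every rare individual is a singleton the ACE
sample-coverage term is zero and the estimator is undefined; the function
falls back to bias-corrected Chao1 with a `RuntimeWarning` rather than
returning infinity.

## Beta diversity

Bray-Curtis dissimilarity `Σ|x−y| / Σ(x+y)`. PCoA eigendecomposes the
double-centered Gower matrix; negative eigenvalues (Bray-Curtis is
non-Euclidean) are reported raw, while coordinates and
`proportion_explained` use only the positive spectrum — stated here because
conventions differ and they change the printed "% variation explained".
PERMANOVA uses Anderson's pseudo-F on squared distances with free label
permutation and the `(1 + more-extreme) / (n_perm + 1)` rule; note that
with few samples the permutation group is small (4+4 labels admit only 70
distinct splits), so the attainable minimum p is bounded well above
1/(n_perm+1). UPGMA is implemented directly so that ties in the minimum
inter-cluster distance break deterministically by the lexicographically
smallest pair; the output newick is ultrametric with leaf heights d/2.

## Core microbiome

Core membership requires occurrence ≥ 80% of samples **and** mean relative
abundance ≥ 0.1%, both inclusive. The mean relative abundance is the
unweighted mean of per-sample proportions, not a pooled-count ratio — the
two differ when sample depths differ, and the unweighted form matches the
"average relative abundance" reading. Occurrence is evaluated within each
group by default (`core_by_group`), with the study-wide variant available
by calling `find_core` on the whole table.

## Sloan neutral community model

Local communities of size N assemble by drift plus immigration at rate m
from a metacommunity with taxon proportions p. The stationary local
relative abundance of a taxon is Beta(Nm·p, Nm(1−p)); its detection
probability is the beta survival mass beyond a detection limit d, and Nm is
fitted by bounded scalar least squares over log Nm ∈ [log 0.01N, log 1000N]
with three bracket restarts (SSE tolerance 1e-10). R² = 1 − SSE/SST with
SST centered on the mean observed frequency (the convention of the widely
used implementation; alternatives change R²). The 95% band is a Wilson
binomial interval around each predicted frequency with the sample count as
trials; taxa partition into above/within/below.

**Detection limit.** The conventional hard threshold is d = 1/N. Under
multinomial sequencing at depth N, however, a taxon of true relative
abundance q is detected (count ≥ 1) with probability 1 − (1−q)^N — a smooth
kernel whose median crossing is at q = ln2/N. The package therefore uses
**d = ln2/N** by default, which makes the hard-threshold model the unbiased
equivalent of the real detection process: in round-trip simulations
(S = 500, 24 samples, depth 30,000, m = 0.1) the median fitted m is within
1% of truth, versus +27% bias with d = 1/N. Pass
`fit_ncm(..., detection_limit=1/N)` for the conventional choice.

## Normalized stochasticity ratio

The null model preserves each sample's observed richness and total, draws
taxon identities with probability proportional to regional occurrence
frequency (Gumbel top-k weighted sampling without replacement), and assigns
abundances proportional to regional mean relative abundance with each
chosen taxon guaranteed one read and the remainder apportioned by largest
remainder — the "proportional-abundance, fixed-richness" null. The null is
built from the **whole table** (the regional pool); this is what lets the
index discriminate: a filtered group is far more internally similar than
null assemblies drawn from the mixed regional pool, while a neutral group
is not.

For each sample pair, with observed similarity C = 1 − D and null means
C̄ = 1 − D̄: a pair more similar than null scores selection strength
(C − C̄)/(1 − C̄), a pair more different scores (D − D̄)/(1 − D̄); the
pairwise NST is 1 minus that strength, capped to [0, 1], and the group NST
is the plain mean over within-group pairs (no bootstrap CI — the use case
reports point values). NST > 0.5 is labelled stochastic-dominated. The
formula sits behind `stochasticity_ratio` so alternative normalizations can
be swapped without touching the pipeline.

## Levins niche breadth

`B_j = 1/Σ_i P_ij²` with `P_ij` the share of taxon j's total abundance in
sample i, so B_j ∈ [1, N] with N samples, reaching N only for perfectly
even occupancy. `Bcom` per sample is the unweighted mean of B_j over taxa
**present** in the sample (an occupancy-weighted variant would up-weight
cosmopolitans; presence-mean matches "average B of all taxa in a single
community").

## Ensemble co-occurrence network

Association scores on the relative-abundance rows of the top-100 taxa:
Pearson r, Spearman ρ, Bray-Curtis similarity 1 − BC, and symmetrized KL
divergence on row-normalized profiles with a per-row pseudocount of half
the smallest nonzero value. The permutation null shuffles every taxon row
independently and then re-closes columns to sum 1 (ReBoot-style), so the
spurious covariance that closure induces lives inside the null instead of
being declared signal; p-values are two-sided around the null mean with the
+1 rule. Bootstrap restoration resamples samples with replacement; an edge
needs the null expectation outside its 95% percentile interval for at least
half the methods (`boot_min_frac = 0.5`). Per-method p-values merge by
Brown's method: the Fisher statistic −2Σln p is referred to a scaled
chi-square whose scale and df come from the empirical covariance of −2ln p
across the shared permutation replicates (perfectly correlated methods
collapse to the common p; independent methods recover Fisher). BH step-up
at q = 0.05 finishes the selection. Edge sign is the sign of the mean of
Pearson and Spearman; pairs where the two disagree in sign are discarded;
for similarity-only method sets the sign compares the observed score to the
null mean. Defaults: n_perm = 1000, n_boot = 100, q = 0.05, top-N = 100.

Topology follows the NetworkAnalyzer conventions: mean degree 2E/N, density
E/(N(N−1)) (back-calculation from published pond tables confirms this
denominator rather than the undirected-graph N(N−1)/2), mean local
clustering, and diameter on the largest connected component. The invariant
positive% + negative% = 100 is enforced over signed edges. One published
pond column sums its association percentages to 97; this package enforces
the 100% identity and does not replicate that discrepancy.

## Synthetic communities

The generators define the testing conditions at the scale of the motivating
study (4 ponds at 31/39/47/55 PSU, 6 samples per pond, 500 taxa, 30,000
reads per sample; a log-normal metacommunity with log-sd 2):

- **Neutral** — sample proportions are Dirichlet(N·m·p) with multinomial
  counts; the beta marginals are exactly the NCM's stationary distribution,
  so migration-rate recovery is a genuine round-trip, not a smoke test.
- **Filtered** — each taxon has a salinity optimum; group weights are
  p·exp(−(salinity−optimum)²/2σ²), renormalized. Optima are uniform over
  the salinity range padded by half a span on each side: without padding
  the end-of-gradient groups are artificially depauperate and host private
  taxa (an edge effect that inverts the niche-breadth trend). Per-group
  niche widths are supported for strength-gradient designs.
- **Gradient** — group g's pool is the metacommunity with its filter
  **tempered** by a mixing weight rising linearly from 0 to 0.9
  (`pool ∝ p·filter^w`), and samples assemble neutrally around that pool.
  The geometric mix keeps each sample a proper Dirichlet-multinomial draw;
  an arithmetic per-sample mixture of neutral and filtered proportions
  inflates richness at intermediate weights (reads spread over both
  components), which collapses null-model distances and produces a spurious
  non-monotone NST bump. With `diversity_decline` the niche width also
  shrinks by 0.7 per group, so Shannon diversity falls along the gradient.
- **Correlated** — a latent Gaussian copula plants target pairwise
  correlations before log-normal transformation and closure; non-planted
  taxa are latent-independent. Closure attenuates the realized correlation
  and couples abundant taxa through the shared denominator, so "latent
  independent" is not "compositionally independent" — network false
  discoveries are assessed on row-shuffled tables, which destroy all
  dependence.

What the generators do **not** emulate: sequencing error, chimeras,
OTU-clustering artifacts, overdispersion beyond the Dirichlet-multinomial,
phylogenetic signal, and real taxonomic structure. Passing tests therefore
demonstrate correctness of the estimators and the designed-in ecological
contrasts, not performance on raw sequencing data.

## Problem sizes and runtime

The test-suite and acceptance-script simulation sizes are chosen at desk
scale: NCM recovery uses 20 replicates of (S = 500, 24 samples, depth
30,000); NST checks use 10 replicates with 1000 null draws on (S = 300,
4 × 6 samples, depth 20,000); network calibration uses 20 signal-free runs
(n_perm = 200, n_boot = 50) plus one planted-recall run at full defaults;
PERMANOVA calibration uses 1000 structureless simulations at 199
permutations. A full acceptance run completes in about two minutes on one
CPU. Seeds expand deterministically (CRC32 of `seed:stage`) so stages are
independently reproducible.

## Known limitations

- The NST normalization is one member of a family; published
  implementations differ in null-model flavor and in how pairwise values
  aggregate. The 50% threshold is a convention, not an inference.
- Brown's merge relies on the empirical covariance of −2ln p across
  permutation replicates; below ~30 replicates it errors rather than
  guessing.
- The permutation p-value floor 1/(n_perm+1) means single-method edge
  selection cannot pass BH at 4950 candidate pairs; detection power comes
  from the merged statistic's continuous tail.
- BIOM support covers the JSON (1.0) dialect only, not HDF5.
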