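# halocline

Community-ecology analyses for microbiome studies along environmental
gradients, built around the question a salinity-gradient gut-microbiome
survey asks: **how much of community assembly is stochastic (drift,
dispersal) and how much is deterministic (environmental filtering)?**

The package takes an OTU/taxon count table (taxa × samples), a taxonomy
table and sample metadata, and provides the full downstream toolchain of a
16S amplicon study of shrimp culture ponds at salinities 31–55 PSU:

- **Diversity** — Shannon, Simpson dominance (Σp²), bias-corrected Chao1,
  ACE, Good's coverage, rarefaction curves; Bray-Curtis distances, PCoA,
  PERMANOVA, UPGMA clustering trees.
- **Core microbiome** — taxa present in ≥80% of samples at mean relative
  abundance ≥0.1%, per group and shared across groups.
- **Sloan neutral community model (NCM)** — occurrence frequency *f* of a
  taxon with mean relative abundance *p* is predicted by the stationary beta
  distribution of drift + immigration:
  `f(p) = 1 − I_d(Nm·p, Nm(1−p))`,
  with *N* reads per sample, migration rate *m*, detection limit *d*, and
  `I` the regularized incomplete beta function; *Nm* is fitted by nonlinear
  least squares and R² measures closeness to neutrality.
- **Normalized stochasticity ratio (NST)** — observed pairwise Bray-Curtis
  (or Jaccard) dissimilarity within a group compared against a
  fixed-richness, proportional-abundance null model; NST > 50% reads as
  stochastic-dominated assembly, < 50% as deterministic-dominated.
- **Levins niche breadth** — `B_j = 1 / Σ_i P_ij²` with `P_ij` the share of
  taxon *j*'s abundance in community *i*; `Bcom` is the community mean.
- **Ensemble co-occurrence networks (CoNet-style)** — Pearson, Spearman,
  Bray-Curtis similarity and symmetrized Kullback-Leibler scores on the top
  100 genera, a permutation null with compositional renormalization
  (ReBoot), bootstrap restoration, Brown's p-value merging, BH FDR, and
  NetworkAnalyzer-convention topology (mean degree 2E/N, density
  E/(N(N−1)), diameter on the largest component).
- **Synthetic communities** — generators for neutral, salinity-filtered and
  correlation-planted communities at the study's scale (4 ponds × 6
  samples, ~500 taxa, ~30k reads/sample), so every analysis is testable
  end-to-end without the original sequencing data.

## Worked example

Fit the neutral model to a simulated neutral community
(`examples/03_neutral_model.py`):

```python
from halocline import SyntheticSpec, fit_ncm, simulate_neutral

spec = SyntheticSpec(S=500, depth=30_000, m=0.1, seed=11)
fit = fit_ncm(simulate_neutral(spec, n_samples=24))
```

prints

```
fitted Nm = 3026  (N = 30000 reads/sample)
fitted migration rate m = 0.1009  (truth: 0.1)
R^2 of the frequency fit = 0.948
taxon partition vs the 95% band: {'within': 347, 'above': 127, 'below': 11}
```

The fitted migration rate recovers the generating value (m = 0.1), and the
high R² is the signature of stochastic assembly: occurrence is predicted by
abundance alone. On a filtered gradient
(`examples/04_stochasticity_and_niche.py`) the stochasticity ratio drops
from pond A to pond D:

```
  A: NST =  96.6%  -> stochastic-dominated
  B: NST =  16.5%  -> deterministic-dominated
  C: NST =   9.0%  -> deterministic-dominated
  D: NST =   5.5%  -> deterministic-dominated
```

mirroring the direction of the field observation that determinism grows
with salinity. The other examples cover diversity profiling, core-taxon
detection, network inference with planted associations, and the one-command
pipeline (`halocline run config.yaml`).

## Command line

```bash
halocline simulate --preset gradient --seed 1 -o data/
halocline rarefy data/counts.tsv --depth 35873 --seed 1 -o rarefied.tsv
halocline diversity rarefied.tsv -o alpha.tsv
halocline nst rarefied.tsv --metadata data/meta.tsv --draws 1000 --seed 1
halocline network rarefied.tsv --top 100 --q 0.05 --seed 1 -o net/
halocline run config.yaml
```

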