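# phylodissect

Phylogenomic supermatrix analysis at desk scale: supermatrix assembly
and completeness accounting, dissection of phylogenetic signal by gene
evolutionary rate, fixed-size amino-acid jackknife support, a finite-K
site-heterogeneous (CAT-style) Bayesian sampler with split-frequency
convergence diagnostics, and Dollo-parsimony mapping of marker-gene
losses — together with a synthetic-data generator that emulates the
structure of a transcriptome-derived phylogenomic dataset, so the whole
pipeline is exercised and tested without any external download.

It is written for molecular phylogeneticists who want the *analytical
protocol* of a large concatenated-alignment study as a reusable,
seeded, testable library: every stage that a phylogenomic paper chains
together by hand (concatenate → rank genes by rate → quartile →
re-infer → resample → compare chains → map character losses) is a
function here, with ground truth available for every simulated input.

## The models at the core

**Likelihood.** Sequences evolve by a reversible Markov process with
rate matrix `Q_ij = r_ij π_j` (i ≠ j), normalised so −Σᵢ πᵢ Q_ii = 1
(branch lengths are expected substitutions per site); exchangeabilities
`r_ij` are Poisson (uniform) or the empirical LG matrix, shipped as a
data file. Among-site rate variation is the discrete gamma: four
equal-weight categories whose rates are the exact conditional means of
a mean-one Gamma(α, α) over its quantile bins. Likelihoods are computed
by Felsenstein's pruning algorithm with pattern compression, per-node
rescaling (no underflow at 10⁵ columns), and an explicit missing state
that marginalises over all residues. ML trees come from NJ starts
(pairwise ML distances, scikit-bio NJ) refined by NNI hill-climbing
with exact single-branch Brent optimisation off cached inside/outside
partials.

**Site heterogeneity.** The Bayesian sampler is a working miniature of
the CAT-style profile-mixture approach: each column is allocated to one
of K amino-acid frequency profiles π⁽ᶜ⁾ (same exchangeabilities,
per-profile stationary frequencies), and Metropolis-within-Gibbs moves
sample allocations (Gibbs), profiles (Dirichlet proposals with exact
Hastings ratios), mixture weights (conjugate Gibbs), branch lengths and
α (log-scale multipliers), and topology (NNI), under iid exponential
branch-length (mean 0.1), exponential α (mean 1), flat Dirichlet and
uniform-topology priors. Convergence between chains is summarised by
MaxDiff/MeanDiff — the maximum and mean absolute difference in
bipartition frequencies over the union of observed splits.

**Signal dissection.** Each gene's rate is the optimised tree length of
the reference topology pruned to the gene's taxa; genes are sorted by
rate and cut into four column-balanced quartiles Q1 (slowest) … Q4
(fastest). Long-branch attraction (LBA) is diagnosed by disagreement
between the fast and slow quartiles, because LBA is exacerbated by
rapidly evolving genes.

**Gene loss.** Marker genes are detected per taxon by Smith–Waterman
local alignment (BLOSUM62, affine gaps 11/1) against reference
sequences, thresholded at the score a ≥35%-identity, ≥60-residue
alignment would achieve; undetected cells are mapped on the rooted
species tree by Dollo parsimony (single gain at the MRCA of the
detected taxa, minimal loss set below it). The stored state is
"undetected", never "absent": transcriptome evidence of absence is
weak.

## Worked example: quartile dissection in the Felsenstein zone

The `lba-demo` preset simulates a quartet whose true unrooted topology
is (A,C)|(B,D) with the two *non-sister* taxa A and B on long terminal
branches, under strongly site-heterogeneous profiles:

```python
from phylodissect import (lba_demo, simulate_supermatrix, poisson_model,
                          estimate_gene_rates, partition_quartiles,
                          nontrivial_splits, unroot)
from phylodissect.ml import MLPhylogeny

spec = lba_demo(seed=1)
matrix, truth = simulate_supermatrix(spec)
model = poisson_model(alpha=spec.alpha)          # site-homogeneous ML
full = MLPhylogeny(matrix, model).fit()
rates = estimate_gene_rates(matrix, full.tree, model)
split = partition_quartiles(matrix, rates)
for s in split.summaries:
    print(f"{s.name}: {len(s.gene_ids):2d} genes, {s.n_columns} columns, "
          f"relative rate {s.relative_rate:.2f}")
```

prints

```
Q1: 10 genes, 1765 columns, relative rate 0.12
Q2:  9 genes, 1535 columns, relative rate 0.64
Q3: 12 genes, 1670 columns, relative rate 1.13
Q4:  9 genes, 1470 columns, relative rate 2.16
```

and re-inferring each quartile with the same homogeneous model:

```
true tree splits: [['B', 'D']]
Q1 (slowest) splits: [['B', 'D']]
Q4 (fastest) splits: [['C', 'D']]
```

The slowest quartile recovers the generating topology; the fastest
unites the two long branches (the split {C,D} is the (A,B) grouping) —
the signature of a long-branch attraction artifact, visible only
because the genes were dissected by rate.

The full pipeline (simulate → completeness → rates → dissect →
jackknife → mixture MCMC → marker detection → Dollo losses) runs from
the shell and writes a manifest of content digests; identical seed and
configuration reproduce identical digests:

```sh
phylodissect run --preset flatworm-like --seed 1 --outdir run1
```

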