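# Methods

This note documents the models, defaults and design choices of
phylodissect, in the spirit of a methods appendix: what is computed,
under which assumptions, and what the synthetic data do and do not
establish.

## Substitution model and likelihood

The core is a time-reversible amino-acid substitution process. Given
symmetric exchangeabilities `r_ij` and stationary frequencies `π`, the
rate matrix is `Q_ij = r_ij π_j` (i ≠ j), diagonal set so rows sum to
zero, normalised so that −Σᵢ πᵢ Q_ii = 1; branch lengths are then
expected substitutions per site. Two exchangeability sets ship with the
package: Poisson (all equal — exactly solvable, used by the oracle
tests) and the empirical LG matrix, stored as a plain-text data file in
the PAML residue order. Transition matrices `P(t) = exp(Qt)` come from
the symmetric eigendecomposition `π^{1/2} Q π^{-1/2}`, with entries
clamped at zero against rounding.

Among-site rate variation uses the discrete gamma with equal-weight
categories. The category rates are the exact conditional means of the
mean-one Gamma(α, α) density over its quantile bins (via the
incomplete-gamma identity), not the bin medians: the mean-one property
is then exact by construction. Default: 4 categories, α = 0.7 for
amino-acid data (a typical protein-alignment value).

Likelihoods are computed by post-order pruning with:

* pattern compression (unique columns counted once; with a site →
  profile map, uniqueness is over (profile, column) pairs);
* an explicit missing state ('-', '?', 'X' on input) whose tip partial
  is all ones, so a fully missing column contributes exactly zero
  log-likelihood and an all-missing taxon changes nothing;
* per-node rescaling with accumulated per-pattern log factors, so
  10⁵-column matrices cannot underflow;
* a branch-length floor of 1e-8 keeping `P(t)` well conditioned.

Site heterogeneity takes two forms: a fixed column → profile map (each
column's stationary frequencies are its profile's; used by the
simulator and the MCMC sampler) or a full mixture (each column sums
over profiles by weight). With one profile both reduce exactly to the
homogeneous likelihood.

## Maximum-likelihood estimation

Branch lengths are optimised one branch at a time by bounded Brent
search on the exact single-branch objective, assembled from cached
inside ("below") and outside ("above") partials — one trial length
costs a single 20×20 product and a dot product per pattern. Sweeps
repeat until the gain falls below the tolerance (1e-6 by default); if a
sweep built on stale surrounding partials ever fails to improve the
exact likelihood it is rolled back and redone with partials refreshed
at every branch, so the returned likelihood is never below the input's.
Flat stretches resolve toward the smaller branch length.

Topology search is greedy NNI hill-climbing: every internal edge's two
interchanges are scored cheaply from the cached partials (optimising
only the central branch), the best is applied, and branch lengths are
re-optimised. Starting trees come from neighbour joining (scikit-bio)
on pairwise two-taxon ML distances restricted to shared non-missing
columns; trees with ≤ 5 taxa are scored exhaustively over all unrooted
topologies instead.

## The profile-mixture sampler

The Bayesian stage is a finite-K mixture: each column carries a latent
allocation to one of K frequency profiles. This keeps the mechanism of
the site-heterogeneous (CAT-type) family — per-site equilibrium
frequencies — while staying at desk scale; K defaults to 10.
Exchangeabilities are fixed (Poisson or LG), not sampled: sampling the
190 GTR exchangeabilities is the main simplification relative to a
full CAT+GTR analysis, and posterior uncertainty in them is therefore
not propagated.

Priors: branch lengths iid exponential (mean 0.1), α exponential
(mean 1), profiles and weights Dirichlet(1,…,1), topology uniform.
Moves per iteration (relative weights configurable): log-scale
multiplier proposals on a random branch and on α (with the `log t'/t`
Hastings term); Dirichlet random-walk proposals on one profile
(concentration 200, exact Hastings ratio via the Dirichlet density);
an *independence* proposal for one profile drawn from Dirichlet(1 +
residue counts of its sites) — close to the conditional posterior, so
profiles can jump straight to their sites' composition; conjugate
Gibbs draws of the mixture weights; Gibbs reallocation of every site
(every 5th iteration by default); and NNI topology proposals with both
swapped subtrees chosen uniformly, which keeps the proposal symmetric.
Multiplier windows are tuned toward ~30% acceptance during burn-in
only, preserving detailed balance for retained samples. Chains are
initialised from the prior (an explicit start tree may be supplied,
e.g. to fix a topology by also zeroing the topology move weight).

The primary correctness property is prior recovery: with an all-missing
alignment the likelihood is identically zero and the sampler must
reproduce its priors — uniform quartet topologies, exponential branch
lengths and α. The acceptance suite checks exactly this, with
batch-means Monte-Carlo errors for the frequency assertions and a KS
test for α.

Convergence is reported as MaxDiff/MeanDiff between independent chains:
over the union of bipartitions observed in either chain's post-burn-in
samples (an absent split counting as frequency zero), the maximum and
the arithmetic mean of the absolute frequency differences. No
frequency floor is applied before the comparison.

## Signal dissection

A gene's rate is measured as the total optimised branch length of the
reference topology pruned to the taxa with data for that gene, on that
gene's columns alone; relative rates are normalised to mean one over
genes. Genes with data for fewer than four taxa are flagged
unestimable and excluded with a warning. The reference defaults to a
full-data ML tree (in the pipeline: ML on a seeded column subsample),
and is user-configurable.

Quartiles are equal in *columns*, not gene counts (support is
column-denominated throughout, as in the jackknife); genes sorted by
ascending rate (ties by gene id) are assigned against cumulative
boundaries at k·total/4, which keeps every quartile within one gene
length of a quarter of the columns. A gene-count mode exists behind a
flag. The per-quartile rate is the column-weighted mean of member
genes' relative rates; since relative rates are normalised to mean one
over genes, the four quartile values bracket one from below and above
rather than all exceeding it.

## Jackknife and consensus

Replicates are fixed-size draws of distinct columns, uniform without
replacement, independent across replicates (default: 100 replicates of
20,000 columns — the emulated protocol). Because the resampling unit
of the original protocol is not stated in the sources available here,
a gene-level mode (accumulate whole genes in random order, truncate
the last) is provided behind a flag; neither mode is claimed as the
original's. Split frequencies are counted over canonical bipartitions
(the side not containing the first taxon in sorted order; trivial
splits omitted). The majority-rule consensus contains exactly the
splits with frequency strictly above 0.5 — such splits are pairwise
compatible — labelled with their frequencies; splits at exactly 0.5
are excluded.

## Marker detection and Dollo mapping

Detection scores each (taxon, marker) cell by the best Smith–Waterman
affine-gap local alignment (biopython's aligner) of any reference
sequence against any sequence of the taxon, under BLOSUM62 with gap
open 11 / extend 1 (a gap of length L costs 11 + L). The detection
threshold is the score a gapless alignment of min(60, reference
length) residues would achieve at 35% identity, scoring identities by
the table's diagonal averaged over the reference's residues and
mismatches by the mean off-diagonal entry; the paper-style protocol
states no thresholds, so this policy is the package's own, and the
null-score distribution of unrelated random sequences sits far below
it. Cells are "present" or "undetected" — never "absent" — and an
empty sequence set yields undetected cells with a warning, because
absence from a transcriptome is weak evidence of genomic loss.

Dollo mapping places the single gain at the MRCA of the detected taxa
and the losses on the stems of the maximal all-undetected subtrees
below it. That set is minimal (the subtrees are disjoint and each
requires at least one loss), which the tests certify against
exhaustive subset minimisation on trees up to ten leaves.

## The synthetic-data generator

The generator emulates the structure of a transcriptome-derived
phylogenomic dataset, not any particular dataset's content:

* **Trees** — balanced or caterpillar shapes with iid exponential
  branch lengths (mean 0.1), or an explicit Newick; designated
  long-branch taxa have their terminal branches multiplied by a scale
  factor.
* **Genes** — lengths from a gamma round-off (mean 270, CV 0.4, floor
  30); per-gene rate multipliers from a gamma with mean fixed at one
  (shape 2 by default; the true generative law of real gene rates is
  unknown).
* **Sites** — profile assignments uniform over K Dirichlet-sampled
  profiles (concentration 0.5 by default; smaller = spikier
  composition), gamma rate categories, and states evolved edge by edge
  with the likelihood core's transition matrices at rate = gene
  multiplier × category rate.
* **Missing data** — whole (taxon, gene) blocks are dropped, because
  transcriptome incompleteness removes entire transcripts: each taxon
  draws a keep rate from a beta centred on the target completeness
  (concentration 50, echoing per-taxon spread around the emulated
  ~72% average), then blocks survive independently.
* **Markers** — presence/absence under single-gain-then-losses with
  independent false-negative flips, plus synthetic protein sequences
  (diverged copies of random references among decoys) to exercise the
  detection path end to end.

Every operation draws from its own labelled stream of the master seed
(label hashed into a numpy SeedSequence), so outputs are bitwise
reproducible and adding operations never perturbs existing ones.

Two presets are frozen. **flatworm-like** echoes the emulated study's
dataset *shape* at desk scale: 24 taxa, 400 genes averaging 270
columns (~108,000 total), target completeness 0.72, four long-branch
taxa (scale 4) split between two clades. **lba-demo** is a
Felsenstein-zone quartet: true topology (A,C)|(B,D), non-sister long
terminals 0.16×5, short terminals 0.1, internal branch 0.06, 40 genes
of mean length 150, gene-rate gamma shape 1.0 (a wide spread, so the
quartiles differ strongly in rate), and 20 profiles at concentration
0.2 (strong compositional heterogeneity). These values were chosen, by
design, so that the preset sits at the boundary of the zone: a
site-homogeneous ML analysis of the fastest gene quartile is drawn to
the long-branch grouping while the slowest quartile recovers the
truth. Sitting in that regime is what makes the preset a demonstration
of the dissection instrument; the calibration is part of the preset's
definition, and it was frozen before the acceptance thresholds were
evaluated against it.

What passing tests on these data do **not** show: that real
transcriptome supermatrices satisfy the model (real data have
alignment error, compositional drift along branches, non-gamma rate
variation, correlated gene loss); that the finite-K sampler matches a
Dirichlet-process CAT analysis; or that the detection thresholds are
calibrated for real protein families. The synthetic results establish
internal correctness and the qualitative LBA mechanism, not external
calibration.

## Problem sizes and numerical choices

The pipeline's default stage sizes are desk-scale choices: the
reference tree and per-quartile inferences run on seeded 2,000- and
1,200-column subsamples of the full simulated matrix, the jackknife
inference on 6 replicates of 1,200 columns (the protocol-scale 100 ×
20,000 replicate *generation* is exercised as such), the mixture MCMC
on a 250-column subsample with K = 5 and 2 × 200 iterations, and gene
rates with 2 optimisation sweeps at tolerance 1e-3. These sizes are
configuration, not contract — every stage accepts full-scale inputs.

Other numerical choices: optimisation tolerance 1e-6 on branch lengths
and likelihood gains (looser, 1e-3, in the pipeline's rate stage);
ties toward shorter branches; Dirichlet samples clipped at 1e-6 and
renormalised so profiles stay strictly positive; consensus excludes
frequency-0.5 splits; MaxDiff uses no frequency floor; jackknife
replicate extraction relabels split gene runs `g.2`, `g.3`, … to keep
partition ids unique.

## Known limitations

* Exchangeabilities are fixed in the Bayesian stage (no GTR sampling).
* Tree search is NNI-only (no SPR/TBR); very poor starting trees can
  strand the hill-climb in local optima on hard datasets.
* The Dirichlet random-walk profile move mixes slowly through
  symmetric modes; the count-based independence proposal mitigates
  this, but short chains on strongly heterogeneous data should be
  checked with the between-chain MaxDiff diagnostic.
* The two-state alphabet is fully supported in the core (and used by
  closed-form oracles), but the detection module is protein-only.
* No codon or nucleotide models, no indel process, no alignment
  uncertainty.
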