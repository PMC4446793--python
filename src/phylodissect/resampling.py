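"""Jackknife resampling and bipartition support.

The support protocol of the emulated study: fixed-size amino-acid
jackknife replicates (100 datasets of 20,000 columns by default),
per-replicate tree inference, bipartition frequencies over the
replicate trees, strict-majority consensus, and the MaxDiff/MeanDiff
statistic comparing two support sets (used both for jackknife runs and
as the between-chain MCMC convergence diagnostic).

Splits are canonicalised as the bipartition side *not* containing the
reference taxon (first taxon in sorted order); trivial splits are
omitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import stream
from .supermatrix import Supermatrix, slice_columns
from .tree import Node, PhyloTree, canonical_split, nontrivial_splits

__all__ = [
    "JackknifeConfig",
    "SplitSupport",
    "jackknife_replicates",
    "split_frequencies",
    "majority_consensus",
    "chain_compare",
]


@dataclass(frozen=True)
class JackknifeConfig:
    """Replicate-generation settings (defaults: the study's protocol)."""

    replicate_columns: int = 20000
    n_replicates: int = 100
    seed: int = 0
    unit: str = "columns"  # or "genes": whole genes until the target, then truncate

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.replicate_columns < 1:
            raise ValueError("replicate_columns must be positive")
        if self.unit not in ("columns", "genes"):
            raise ValueError("unit must be 'columns' or 'genes'")


@dataclass(frozen=True)
class SplitSupport:
    """Canonical split -> frequency in [0, 1], over ``n_samples`` trees."""

    frequencies: dict  # frozenset[str] -> float
    n_samples: int
    taxa: frozenset

    def __post_init__(self):
        ref = min(self.taxa)
        for s, f in self.frequencies.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError("split frequency outside [0, 1]")
            if ref in s or not 1 < len(s) < len(self.taxa) - 1:
                raise ValueError("split not canonical/non-trivial")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#split_taxa\tfrequency\n")
            for s in sorted(self.frequencies, key=lambda s: (-self.frequencies[s],
                                                             sorted(s))):
                fh.write(",".join(sorted(s)) + f"\t{self.frequencies[s]:.6g}\n")


def jackknife_replicates(matrix: Supermatrix, config: JackknifeConfig,
                         ) -> list[Supermatrix]:
    """Fixed-size column (or gene) jackknife replicates.

    Column mode samples ``replicate_columns`` distinct column indices
    uniformly without replacement, independently per replicate. Gene
    mode accumulates whole genes in random order until the target is
    reached, truncating the last gene. Reproducible from the seed.
    """
    if config.replicate_columns > matrix.n_columns:
        raise ValueError("replicate_columns exceeds matrix width")
    out = []
    for r in range(config.n_replicates):
        rng = stream(config.seed, f"jackknife/{r}")
        if config.unit == "columns":
            cols = rng.choice(matrix.n_columns, size=config.replicate_columns,
                              replace=False)
        else:
            order = rng.permutation(len(matrix.partitions))
            cols_list: list[np.ndarray] = []
            n = 0
            for gi in order:
                p = matrix.partitions[gi]
                take = min(p.length, config.replicate_columns - n)
                cols_list.append(np.arange(p.start, p.start + take))
                n += take
                if n >= config.replicate_columns:
                    break
            cols = np.concatenate(cols_list)
        out.append(slice_columns(matrix, cols))
    return out


def split_frequencies(trees: Sequence[PhyloTree]) -> SplitSupport:
    """Fraction of trees containing each observed non-trivial split."""
    trees = list(trees)
    if not trees:
        raise ValueError("no trees given")
    taxa = frozenset(trees[0].taxa)
    counts: dict = {}
    for t in trees:
        if frozenset(t.taxa) != taxa:
            raise ValueError("trees have differing leaf sets")
        for s in nontrivial_splits(t, taxa):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    return SplitSupport(frequencies={s: c / n for s, c in counts.items()},
                        n_samples=n, taxa=taxa)


def majority_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Strict-majority-rule consensus with support labels.

    Contains exactly the splits at frequency > 0.5 (such splits are
    pairwise compatible); each internal node is labelled with its
    split's frequency. Splits at exactly 0.5 are excluded.
    """
    support = split_frequencies(trees)
    return consensus_from_support(support)


def consensus_from_support(support: SplitSupport) -> PhyloTree:
    taxa = sorted(support.taxa)
    majority = {s: f for s, f in support.frequencies.items() if f > 0.5}
    root = Node(None, 0.0)
    clade: dict[int, frozenset] = {}
    for t in taxa:
        leaf = root.add(Node(t, 0.0))
        clade[id(leaf)] = frozenset([t])
    for s in sorted(majority, key=len, reverse=True):
        # deepest current node whose clade contains s
        node = root
        node_clade = frozenset(taxa)
        descended = True
        while descended:
            descended = False
            for c in node.children:
                cc = clade.get(id(c), frozenset())
                if s <= cc:
                    node, node_clade, descended = c, cc, True
                    break
        group = [c for c in node.children if clade.get(id(c), frozenset()) <= s
                 and clade.get(id(c))]
        covered = frozenset().union(*(clade[id(c)] for c in group))
        assert covered == s, "majority splits must be compatible"
        new = Node(None, 0.0, label=f"{majority[s]:.6g}")
        for c in group:
            node.children.remove(c)
            new.add(c)
        node.add(new)
        clade[id(new)] = s
    return PhyloTree(root)


def chain_compare(a: SplitSupport, b: SplitSupport) -> tuple[float, float]:
    """MaxDiff / MeanDiff between two split support sets.

    Over the union of splits observed in either set (an absent split
    counts as frequency zero), the absolute frequency differences are
    taken; MaxDiff is their maximum and MeanDiff their arithmetic
    mean. Symmetric in (a, b); both values lie in [0, 1].
    """
    if a.taxa != b.taxa:
        raise ValueError("split supports are over different taxon sets")
    union = set(a.frequencies) | set(b.frequencies)
    if not union:
        return 0.0, 0.0
    diffs = [abs(a.frequencies.get(s, 0.0) - b.frequencies.get(s, 0.0))
             for s in union]
    return float(max(diffs)), float(np.mean(diffs))
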