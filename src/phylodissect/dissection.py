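"""Phylogenetic signal dissection by gene rate.

Long-branch attraction is exacerbated by rapidly evolving genes. The
dissection instrument ranks genes by evolutionary rate (per-gene tree
length on a fixed reference topology), splits the supermatrix into
four equal-sized quartile datasets Q1 (slowest) to Q4 (fastest), and
runs the configured inference independently on each so conflicting
splits between slow and fast quartiles can be flagged as candidate
artifacts.

"Equal-sized" means equal in amino-acid columns (quartile support is
column-denominated, as in jackknife resampling); a gene-count mode is
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .likelihood import LikelihoodEngine
from .ml import optimize_branch_lengths, unroot
from .substitution import SubstitutionModel
from .supermatrix import GenePartition, Supermatrix, completeness_stats, slice_columns
from .tree import PhyloTree, nontrivial_splits

__all__ = [
    "RateTable",
    "QuartileSummary",
    "QuartileSplit",
    "estimate_gene_rates",
    "partition_quartiles",
    "dissection_experiment",
    "DissectionResult",
]


@dataclass(frozen=True)
class RateTable:
    """Per-gene relative rates (normalised to mean one) and tree lengths."""

    relative_rate: dict[str, float]
    tree_length: dict[str, float]
    unestimable: tuple[str, ...] = ()

    def __post_init__(self):
        rates = np.array(list(self.relative_rate.values()))
        if rates.size == 0:
            raise ValueError("no estimable genes")
        if np.any(rates <= 0):
            raise ValueError("relative rates must be positive")
        if abs(rates.mean() - 1.0) > 1e-9:
            raise ValueError("relative rates must average to one")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#gene_id\trelative_rate\ttree_length\n")
            for g in sorted(self.relative_rate):
                fh.write(f"{g}\t{self.relative_rate[g]:.6g}\t{self.tree_length[g]:.6g}\n")


def _taxon_subset(matrix: Supermatrix, rows: np.ndarray) -> Supermatrix:
    return Supermatrix([matrix.taxa[i] for i in rows], matrix.data[rows],
                       matrix.partitions, matrix.alphabet)


def estimate_gene_rates(matrix: Supermatrix, reference_tree: PhyloTree,
                        model: SubstitutionModel, min_taxa: int = 4,
                        tol: float = 1e-4, max_sweeps: int = 5,
                        ) -> RateTable:
    """Per-gene rate = optimised tree length on the reference topology.

    For each gene, the reference tree is pruned to the taxa with data
    for that gene and its branch lengths are re-optimised on the gene's
    columns; the gene's tree length (sum of branch lengths) divided by
    the mean over genes is its relative rate. Genes with data for fewer
    than ``min_taxa`` taxa are flagged unestimable and excluded with a
    warning.
    """
    ref_taxa = set(reference_tree.taxa)
    if not set(matrix.taxa) <= ref_taxa:
        raise ValueError("reference tree does not span the matrix taxa")
    miss = matrix.alphabet.missing_code
    tree_lengths: dict[str, float] = {}
    unestimable: list[str] = []
    for p in matrix.partitions:
        block = matrix.data[:, p.start:p.end]
        rows = np.nonzero((block != miss).any(axis=1))[0]
        if rows.size < min_taxa:
            unestimable.append(p.gene_id)
            continue
        sub = Supermatrix([matrix.taxa[i] for i in rows], block[rows],
                          [GenePartition(p.gene_id, 0, p.length)], matrix.alphabet)
        pruned = unroot(reference_tree.prune_to(sub.taxa))
        engine = LikelihoodEngine(sub, model)
        opt, _ = optimize_branch_lengths(pruned, engine=engine, tol=tol,
                                         max_sweeps=max_sweeps)
        tree_lengths[p.gene_id] = opt.total_length()
    if unestimable:
        warnings.warn(f"{len(unestimable)} gene(s) with data for fewer than "
                      f"{min_taxa} taxa excluded from rate estimation")
    if not tree_lengths:
        raise ValueError("no gene had enough taxa for rate estimation")
    mean_tl = float(np.mean(list(tree_lengths.values())))
    rel = {g: tl / mean_tl for g, tl in tree_lengths.items()}
    return RateTable(relative_rate=rel, tree_length=tree_lengths,
                     unestimable=tuple(unestimable))


@dataclass(frozen=True)
class QuartileSummary:
    name: str
    gene_ids: tuple[str, ...]
    n_columns: int
    relative_rate: float      # column-weighted mean of member gene rates
    pct_missing: float


@dataclass(frozen=True)
class QuartileSplit:
    """Four datasets Q1 (slowest) .. Q4 (fastest) plus their summaries."""

    matrices: tuple[Supermatrix, ...]
    summaries: tuple[QuartileSummary, ...]

    def summary_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#quartile\tn_genes\tn_columns\trelative_rate\tpct_missing\n")
            for s in self.summaries:
                fh.write(f"{s.name}\t{len(s.gene_ids)}\t{s.n_columns}\t"
                         f"{s.relative_rate:.6g}\t{s.pct_missing:.6g}\n")


def partition_quartiles(matrix: Supermatrix, rates: RateTable,
                        mode: str = "columns") -> QuartileSplit:
    """Split genes into four rate quartiles of (nearly) equal size.

    Genes are sorted by ascending relative rate (ties broken by gene
    id) and assigned greedily: each of Q1..Q3 takes genes until its
    column count first reaches a quarter of the total; Q4 takes the
    rest. ``mode='genes'`` balances gene counts instead of columns.
    Genes without a rate (unestimable) are excluded.
    """
    if mode not in ("columns", "genes"):
        raise ValueError("mode must be 'columns' or 'genes'")
    rated = [p for p in matrix.partitions if p.gene_id in rates.relative_rate]
    if len(rated) < 4:
        raise ValueError("need at least 4 rated genes to form quartiles")
    order = sorted(rated, key=lambda p: (rates.relative_rate[p.gene_id], p.gene_id))
    if mode == "columns":
        total = sum(p.length for p in order)
        target = total / 4.0
    else:
        total = len(order)
        target = total / 4.0
    # cumulative boundaries at k * total/4 keep every quartile within one
    # gene length of total/4 (each boundary is crossed by one gene at most)
    groups: list[list[GenePartition]] = [[] for _ in range(4)]
    q, cum = 0, 0.0
    for p in order:
        groups[q].append(p)
        cum += p.length if mode == "columns" else 1
        if q < 3 and cum >= (q + 1) * target:
            q += 1
    if not all(groups):
        raise ValueError("too few genes to fill all four quartiles")
    matrices, summaries = [], []
    for qi, genes in enumerate(groups):
        cols = np.concatenate([np.arange(p.start, p.end) for p in genes])
        sub = slice_columns(matrix, cols)
        n_cols = sub.n_columns
        wrate = sum(rates.relative_rate[p.gene_id] * p.length for p in genes) / n_cols
        pct_missing = 100.0 - completeness_stats(sub).overall
        matrices.append(sub)
        summaries.append(QuartileSummary(
            name=f"Q{qi + 1}",
            gene_ids=tuple(p.gene_id for p in genes),
            n_columns=n_cols,
            relative_rate=wrate,
            pct_missing=pct_missing,
        ))
    mean_rates = [np.mean([rates.relative_rate[g] for g in s.gene_ids])
                  for s in summaries]
    assert all(a <= b + 1e-12 for a, b in zip(mean_rates, mean_rates[1:])), \
        "quartile mean rates must be non-decreasing"
    return QuartileSplit(matrices=tuple(matrices), summaries=tuple(summaries))


@dataclass(frozen=True)
class DissectionResult:
    split: QuartileSplit
    trees: tuple[PhyloTree, ...]
    differing_splits: dict  # (i, j) -> frozenset of splits unique to one side

    def report(self) -> str:
        lines = ["Signal dissection report", "=" * 32]
        for s in self.split.summaries:
            lines.append(f"{s.name}: {len(s.gene_ids)} genes, {s.n_columns} columns, "
                         f"relative rate {s.relative_rate:.3f}, "
                         f"{s.pct_missing:.1f}% missing")
        for (i, j), diff in sorted(self.differing_splits.items()):
            if diff:
                lines.append(f"Q{i + 1} vs Q{j + 1}: {len(diff)} conflicting split(s)")
                for s in sorted(diff, key=sorted):
                    lines.append("   {" + ",".join(sorted(s)) + "}")
            else:
                lines.append(f"Q{i + 1} vs Q{j + 1}: topologies agree")
        return "\n".join(lines)


def dissection_experiment(matrix: Supermatrix, rates: RateTable,
                          inference: Callable[[Supermatrix], PhyloTree],
                          mode: str = "columns") -> DissectionResult:
    """Infer a tree per quartile and compare their bipartitions.

    ``inference`` maps a quartile supermatrix to a tree (e.g. an
    :class:`~phylodissect.ml.MLPhylogeny` fit, or an MCMC consensus).
    The report marks, for every pair of quartiles, the symmetric
    difference of their non-trivial splits.
    """
    split = partition_quartiles(matrix, rates, mode=mode)
    trees = tuple(inference(m) for m in split.matrices)
    diffs = {}
    for i in range(4):
        for j in range(i + 1, 4):
            si = nontrivial_splits(trees[i])
            sj = nontrivial_splits(trees[j])
            diffs[(i, j)] = frozenset(si ^ sj)
    return DissectionResult(split=split, trees=trees, differing_splits=diffs)
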