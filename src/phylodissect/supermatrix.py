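"""Partitioned amino-acid supermatrices.

A :class:`Supermatrix` is the central container of the package: an
ordered set of taxa, a taxa x columns state matrix with an explicit
missing state, and an ordered partition map assigning every column to
exactly one gene. Concatenation of per-gene alignments, completeness
accounting and column slicing all live here; every downstream stage
(rate dissection, jackknife resampling, likelihood inference) consumes
this object.

Column coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS, Alphabet

__all__ = [
    "GenePartition",
    "CompletenessReport",
    "Supermatrix",
    "concatenate",
    "completeness_stats",
    "slice_columns",
]


@dataclass(frozen=True)
class GenePartition:
    """A gene's column interval ``[start, end)`` in the supermatrix."""

    gene_id: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty partition for {self.gene_id!r}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CompletenessReport:
    """Percent of positions with data present, overall / per taxon / per gene."""

    overall: float
    per_taxon: Mapping[str, float]
    per_gene: Mapping[str, float]


class Supermatrix:
    """Taxa x columns character matrix with a gene partition map.

    Parameters
    ----------
    taxa
        Ordered unique taxon identifiers, one per row.
    data
        uint8 array of shape (n_taxa, n_columns); values in
        ``[0, n_states]`` where ``n_states`` codes the missing state.
    partitions
        Ordered :class:`GenePartition` list tiling ``[0, n_columns)``
        exactly, without overlap.
    """

    def __init__(self, taxa: Sequence[str], data: np.ndarray,
                 partitions: Sequence[GenePartition],
                 alphabet: Alphabet = AMINO_ACIDS):
        taxa = list(taxa)
        data = np.asarray(data, dtype=np.uint8)
        if data.ndim != 2 or data.shape[0] != len(taxa):
            raise ValueError("data must be 2-D with one row per taxon")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon ids")
        if data.size and data.max(initial=0) > alphabet.missing_code:
            raise ValueError("state code out of range for alphabet")
        parts = list(partitions)
        pos = 0
        seen = set()
        for p in parts:
            if p.start != pos:
                raise ValueError(f"partitions do not tile columns: gap/overlap at {p.gene_id!r}")
            if p.gene_id in seen:
                raise ValueError(f"duplicate gene id {p.gene_id!r}")
            seen.add(p.gene_id)
            pos = p.end
        if pos != data.shape[1]:
            raise ValueError("partitions do not cover all columns")
        self.taxa = taxa
        self.data = data
        self.partitions = parts
        self.alphabet = alphabet

    # -- basic geometry -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return [p.gene_id for p in self.partitions]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def row_string(self, taxon: str, missing_char: str = "-") -> str:
        return self.alphabet.decode(self.row(taxon), missing_char)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_taxa, n_columns) array, True where data is missing."""
        return self.data == self.alphabet.missing_code

    def gene_matrix(self, gene_id: str) -> "Supermatrix":
        for p in self.partitions:
            if p.gene_id == gene_id:
                return Supermatrix(self.taxa, self.data[:, p.start:p.end].copy(),
                                   [GenePartition(gene_id, 0, p.length)], self.alphabet)
        raise KeyError(gene_id)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Supermatrix) and self.taxa == other.taxa
                and self.partitions == other.partitions
                and np.array_equal(self.data, other.data))

    def __repr__(self) -> str:
        return (f"<Supermatrix {self.n_taxa} taxa x {self.n_columns} columns, "
                f"{len(self.partitions)} genes>")

    # -- I/O -------------------------------------------------------------
    def to_fasta(self, path, missing_char: str = "-") -> None:
        records = [SeqRecord(Seq(self.row_string(t, missing_char)), id=t, description="")
                   for t in self.taxa]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def to_phylip(self, path, missing_char: str = "-") -> None:
        """Relaxed sequential PHYLIP (name, two spaces, full row)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {self.n_columns}\n")
            for t in self.taxa:
                fh.write(f"{t}  {self.row_string(t, missing_char)}\n")

    def write_partitions(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#gene_id\tstart\tend\n")
            for p in self.partitions:
                fh.write(f"{p.gene_id}\t{p.start}\t{p.end}\n")

    @classmethod
    def from_fasta(cls, path, partitions: Sequence[GenePartition] | None = None,
                   alphabet: Alphabet = AMINO_ACIDS) -> "Supermatrix":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(alphabet.encode(str(rec.seq)))
        if not rows:
            raise ValueError(f"no sequences in {path}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment in {path}")
        data = np.vstack(rows)
        if partitions is None:
            partitions = [GenePartition("all", 0, data.shape[1])]
        return cls(taxa, data, partitions, alphabet)

    @classmethod
    def from_phylip(cls, path, partitions: Sequence[GenePartition] | None = None,
                    alphabet: Alphabet = AMINO_ACIDS) -> "Supermatrix":
        with open(path) as fh:
            header = fh.readline().split()
            n_taxa, n_cols = int(header[0]), int(header[1])
            taxa, rows = [], []
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                name, seq = line.split(None, 1)
                seq = seq.replace(" ", "")
                taxa.append(name)
                rows.append(alphabet.encode(seq))
        if len(taxa) != n_taxa or any(len(r) != n_cols for r in rows):
            raise ValueError(f"PHYLIP header does not match body in {path}")
        if partitions is None:
            partitions = [GenePartition("all", 0, n_cols)]
        return cls(taxa, np.vstack(rows), partitions, alphabet)

    @staticmethod
    def read_partitions(path) -> list[GenePartition]:
        parts = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                gid, start, end = line.rstrip("\n").split("\t")
                parts.append(GenePartition(gid, int(start), int(end)))
        return parts


def concatenate(gene_alignments: Iterable[tuple[str, Mapping[str, str] | "Supermatrix"]],
                alphabet: Alphabet = AMINO_ACIDS) -> Supermatrix:
    """Concatenate per-gene alignments into a partitioned supermatrix.

    ``gene_alignments`` yields ``(gene_id, sequences)`` pairs where the
    sequences are a taxon -> string mapping (or a single-gene
    :class:`Supermatrix`). The taxon set of the result is the union over
    genes, in order of first appearance; a taxon absent from a gene gets
    the missing state across that gene's interval.
    """
    genes: list[tuple[str, dict[str, np.ndarray], int]] = []
    taxa: list[str] = []
    seen_genes: set[str] = set()
    for gene_id, seqs in gene_alignments:
        if gene_id in seen_genes:
            raise ValueError(f"duplicate gene_id {gene_id!r}")
        seen_genes.add(gene_id)
        if isinstance(seqs, Supermatrix):
            seqs = {t: seqs.row_string(t) for t in seqs.taxa}
        enc = {t: alphabet.encode(s) for t, s in seqs.items()}
        lengths = {len(v) for v in enc.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment for gene {gene_id!r}")
        for t in seqs:
            if t not in taxa:
                taxa.append(t)
        genes.append((gene_id, enc, lengths.pop()))
    if not genes:
        raise ValueError("no gene alignments given")
    total = sum(n for _, _, n in genes)
    data = np.full((len(taxa), total), alphabet.missing_code, dtype=np.uint8)
    partitions = []
    pos = 0
    for gene_id, enc, n in genes:
        for t, codes in enc.items():
            data[taxa.index(t), pos:pos + n] = codes
        partitions.append(GenePartition(gene_id, pos, pos + n))
        pos += n
    return Supermatrix(taxa, data, partitions, alphabet)


def completeness_stats(matrix: Supermatrix) -> CompletenessReport:
    """Percent of positions with data present, as the study reports it.

    Per-taxon percent is 100 x non-missing cells / n_columns for that
    row; overall is over all cells, i.e. the cell-weighted mean of the
    per-taxon values.
    """
    present = ~matrix.missing_mask()
    per_taxon = {t: 100.0 * present[i].mean() for i, t in enumerate(matrix.taxa)}
    per_gene = {p.gene_id: 100.0 * present[:, p.start:p.end].mean()
                for p in matrix.partitions}
    overall = 100.0 * present.mean()
    return CompletenessReport(overall=overall, per_taxon=per_taxon, per_gene=per_gene)


def slice_columns(matrix: Supermatrix, columns: Sequence[int]) -> Supermatrix:
    """Extract columns (in the given order) as a new supermatrix.

    The partition map of the result is recomputed as maximal contiguous
    runs of columns originating from the same source gene; runs from the
    same gene that are split apart get ``.1``, ``.2`` ... suffixes so
    gene ids stay unique.
    """
    cols = np.asarray(columns, dtype=np.intp)
    if cols.size == 0:
        raise ValueError("empty column selection")
    if cols.min() < 0 or cols.max() >= matrix.n_columns:
        raise IndexError("column index out of range")
    if np.unique(cols).size != cols.size:
        raise ValueError("duplicate column indices")
    data = matrix.data[:, cols]
    # map each selected column to its source gene index
    gene_of_col = np.empty(matrix.n_columns, dtype=np.intp)
    for gi, p in enumerate(matrix.partitions):
        gene_of_col[p.start:p.end] = gi
    src = gene_of_col[cols]
    partitions = []
    counts: dict[str, int] = {}
    run_start = 0
    for i in range(1, cols.size + 1):
        if i == cols.size or src[i] != src[run_start]:
            gid = matrix.partitions[src[run_start]].gene_id
            counts[gid] = counts.get(gid, 0) + 1
            label = gid if counts[gid] == 1 else f"{gid}.{counts[gid]}"
            partitions.append(GenePartition(label, run_start, i))
            run_start = i
    return Supermatrix(matrix.taxa, data, partitions, matrix.alphabet)
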