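"""Marker-gene detection and Dollo loss mapping.

Given per-taxon protein sequence sets and reference sequences for a
handful of marker genes (in the emulated study: the parahox gene
Cdx and the centrosomal genes SPD-2/Cep192, Nek2 and CCCAP), this
module scores each (taxon, marker) cell by the best Smith-Waterman
local alignment of any reference against any sequence of the taxon,
thresholds the scores into a presence/"undetected" matrix, and maps
the undetected cells onto a rooted species tree as Dollo losses
(single gain, any number of losses).

"Undetected" — never "absent" — is the stored state throughout:
transcriptome evidence of absence is weak, and an empty sequence set
simply yields undetected cells with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .tree import Node, PhyloTree

__all__ = [
    "ScoringScheme",
    "PresenceAbsenceMatrix",
    "DolloReconstruction",
    "local_align_score",
    "detect_presence",
    "dollo_map",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Protein scoring: substitution table plus affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend`` (conventional
    protein-search accounting; the defaults are the classic BLOSUM62 /
    11 / 1).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    _table: object = field(init=False, repr=False, compare=False, default=None)

    def table(self):
        if self._table is None:
            object.__setattr__(self, "_table",
                               substitution_matrices.load(self.matrix_name))
        return self._table

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = self.table()
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a


DEFAULT_SCORING = ScoringScheme()


def local_align_score(query: str, target: str,
                      scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Optimal Smith-Waterman local alignment score (affine gaps, >= 0)."""
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    score = scoring.aligner().score(query.upper(), target.upper())
    return max(float(score), 0.0)


@dataclass
class PresenceAbsenceMatrix:
    """Taxa x markers in {present, undetected}, with per-cell best scores."""

    taxa: list[str]
    markers: list[str]
    detected: np.ndarray  # bool (n_taxa, n_markers)
    scores: np.ndarray    # float (n_taxa, n_markers), >= 0

    def __post_init__(self):
        self.detected = np.asarray(self.detected, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)
        shape = (len(self.taxa), len(self.markers))
        if self.detected.shape != shape or self.scores.shape != shape:
            raise ValueError("matrix shapes do not match taxa/markers")
        if np.any(self.scores < 0):
            raise ValueError("scores must be non-negative")

    def state(self, taxon: str, marker: str) -> str:
        i, j = self.taxa.index(taxon), self.markers.index(marker)
        return "present" if self.detected[i, j] else "undetected"

    def present_taxa(self, marker: str) -> list[str]:
        j = self.markers.index(marker)
        return [t for i, t in enumerate(self.taxa) if self.detected[i, j]]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#taxon\tmarker\tstate\tbest_score\n")
            for i, t in enumerate(self.taxa):
                for j, m in enumerate(self.markers):
                    state = "present" if self.detected[i, j] else "undetected"
                    fh.write(f"{t}\t{m}\t{state}\t{self.scores[i, j]:.6g}\n")


def identity_threshold(reference: str, scoring: ScoringScheme = DEFAULT_SCORING,
                       min_identity: float = 0.35, window: int = 60) -> float:
    """Detection threshold for one reference sequence.

    The score a ``window``-residue gapless alignment would achieve with
    ``min_identity`` of its positions identical (scored by the table's
    diagonal, averaged over the reference's residues) and the rest
    mismatched (scored by the mean off-diagonal entry for the
    reference's residues). Short references use their own length.
    """
    table = scoring.table()
    alpha = table.alphabet
    res = [c for c in reference.upper() if c in alpha]
    if not res:
        raise ValueError("reference has no scorable residues")
    diag = np.mean([table[c, c] for c in res])
    off = np.mean([[table[c, d] for d in alpha if d != c and d.isalpha()]
                   for c in res])
    w = min(window, len(res))
    return max(float(w * (min_identity * diag + (1.0 - min_identity) * off)), 1.0)


def detect_presence(sequence_sets: Mapping[str, Sequence[str]],
                    markers: Mapping[str, Sequence[str]],
                    scoring: ScoringScheme = DEFAULT_SCORING,
                    thresholds: Mapping[str, float] | None = None,
                    ) -> PresenceAbsenceMatrix:
    """Score every taxon against every marker's references.

    A cell is present iff the best local score of any reference against
    any sequence of the taxon reaches the marker's threshold (default:
    the :func:`identity_threshold` minimum over the marker's
    references). Empty sequence sets yield undetected cells with a
    warning, since absence from a transcriptome is weak evidence.
    """
    taxa = list(sequence_sets)
    marker_ids = list(markers)
    for m, refs in markers.items():
        if not refs:
            raise ValueError(f"marker {m!r} has no reference sequence")
    if thresholds is None:
        thresholds = {m: min(identity_threshold(r, scoring) for r in refs)
                      for m, refs in markers.items()}
    detected = np.zeros((len(taxa), len(marker_ids)), dtype=bool)
    scores = np.zeros((len(taxa), len(marker_ids)))
    for i, t in enumerate(taxa):
        seqs = list(sequence_sets[t])
        if not seqs:
            warnings.warn(f"taxon {t!r} has no sequences; all markers undetected "
                          "(transcriptome absence, not genomic loss)")
            continue
        for j, m in enumerate(marker_ids):
            best = max(local_align_score(ref, s, scoring)
                       for ref in markers[m] for s in seqs)
            scores[i, j] = best
            detected[i, j] = best >= thresholds[m]
    return PresenceAbsenceMatrix(taxa=taxa, markers=marker_ids,
                                 detected=detected, scores=scores)


@dataclass
class DolloReconstruction:
    """Minimal Dollo loss sets per marker on a rooted tree."""

    losses: dict[str, tuple[str, ...]]   # marker -> loss branch names (child-end)
    origins: dict[str, str | None]       # marker -> gain node name (None: never seen)

    def loss_count(self, marker: str) -> int:
        return len(self.losses[marker])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#marker\torigin\tloss_branch\n")
            for m, branches in self.losses.items():
                origin = self.origins[m] or "-"
                if branches:
                    for b in branches:
                        fh.write(f"{m}\t{origin}\t{b}\n")
                else:
                    fh.write(f"{m}\t{origin}\t-\n")


def _leaves_below(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def dollo_map(tree: PhyloTree, matrix: PresenceAbsenceMatrix) -> DolloReconstruction:
    """Map each marker's undetected cells as Dollo losses.

    The single gain is placed at the most recent common ancestor of the
    marker's present taxa; losses are the stems of the maximal
    subtrees below it whose leaves are all undetected. That set is
    minimal: the maximal all-undetected subtrees are disjoint, each
    needs at least one loss, and one loss on each stem explains exactly
    the undetected taxa below the gain.
    """
    tree_taxa = set(tree.taxa)
    missing = set(matrix.taxa) - tree_taxa
    if missing:
        raise ValueError(f"matrix taxa not in tree: {sorted(missing)}")
    losses: dict[str, tuple[str, ...]] = {}
    origins: dict[str, str | None] = {}
    for j, marker in enumerate(matrix.markers):
        present = {t for i, t in enumerate(matrix.taxa) if matrix.detected[i, j]}
        if not present:
            losses[marker] = ()
            origins[marker] = None
            continue
        origin = tree.mrca(sorted(present))
        origins[marker] = origin.name
        branch_names: list[str] = []

        mat_taxa = set(matrix.taxa)

        def all_undetected(node: Node) -> bool:
            return all(l.name in mat_taxa and l.name not in present
                       for l in _leaves_below(node))

        def walk(node: Node):
            if node is not origin and all_undetected(node):
                branch_names.append(node.name)
                return
            for c in node.children:
                walk(c)

        walk(origin)
        losses[marker] = tuple(branch_names)
    return DolloReconstruction(losses=losses, origins=origins)
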