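"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own computational paths: the
likelihood oracle enumerates internal-state assignments; the Dollo
oracle searches loss-branch subsets in order of size; the alignment
oracle explores alignment paths recursively.
"""

from __future__ import annotations

import itertools

import numpy as np

from phylodissect.substitution import transition_probabilities
from phylodissect.tree import PhyloTree


def brute_force_loglik(tree: PhyloTree, matrix, model) -> float:
    """Sum over all enumerated internal-node state assignments, per site."""
    s = model.n_states
    pi = model.frequencies
    q = model.rate_matrix()
    rates, weights = model.category_rates, model.category_weights
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    idx = {n: i for i, n in enumerate(internal)}
    leaves = {n: matrix.taxa.index(n.name) for n in nodes if n.is_leaf}
    miss = matrix.alphabet.missing_code
    assigns = np.array(list(itertools.product(range(s), repeat=len(internal))),
                       dtype=np.intp)  # (A, m)
    total = 0.0
    for k, rate in enumerate(rates):
        p_edge = {n: transition_probabilities(q, pi, n.length * rate)
                  for n in nodes if n.parent is not None}
        site_l_k = np.zeros(matrix.n_columns)
        for col in range(matrix.n_columns):
            term = pi[assigns[:, idx[tree.root]]].copy()
            for n in nodes:
                if n.parent is None:
                    continue
                parent_states = assigns[:, idx[n.parent]]
                if n.is_leaf:
                    obs = matrix.data[leaves[n], col]
                    if obs == miss:
                        continue
                    term *= p_edge[n][parent_states, obs]
                else:
                    term *= p_edge[n][parent_states, assigns[:, idx[n]]]
            site_l_k[col] = term.sum()
        if k == 0:
            site_l = weights[k] * site_l_k
        else:
            site_l += weights[k] * site_l_k
    total = float(np.log(site_l).sum())
    return total


def dollo_min_losses(tree: PhyloTree, present: set[str],
                     scored: set[str]) -> int:
    """Minimal number of loss branches explaining the character.

    Gain at the MRCA of ``present``; candidate loss branches are all
    branches below it; subsets are searched in order of increasing
    size until one explains every scored taxon below the gain
    (present iff no loss on its root path).
    """
    if not present:
        return 0
    origin = tree.mrca(sorted(present))
    below = [n for n in tree.postorder()
             if n is not origin and _is_descendant(n, origin)]
    leaves_below = [n for n in below if n.is_leaf]

    def explains(loss_set) -> bool:
        for leaf in leaves_below:
            if leaf.name not in scored:
                continue
            lost = False
            n = leaf
            while n is not origin:
                if n in loss_set:
                    lost = True
                    break
                n = n.parent
            want_present = leaf.name in present
            if want_present == lost:
                return False
        return True

    for size in range(len(below) + 1):
        for combo in itertools.combinations(below, size):
            if explains(set(combo)):
                return size
    raise AssertionError("unreachable: full loss set always explains")


def _is_descendant(node, ancestor) -> bool:
    n = node
    while n is not None:
        if n is ancestor:
            return True
        n = n.parent
    return False


def local_align_bruteforce(q: str, t: str, table, gap_open: float,
                           gap_extend: float) -> float:
    """Best local alignment score by explicit path recursion.

    A gap of length L costs gap_open + L * gap_extend. Alignments may
    start and stop anywhere; the empty alignment scores 0.
    """
    nq, nt = len(q), len(t)

    def rec(i: int, j: int, state: str) -> float:
        best = 0.0
        if i < nq and j < nt:
            best = max(best, table[q[i], t[j]] + rec(i + 1, j + 1, "m"))
        if i < nq:
            cost = gap_extend if state == "qg" else gap_open + gap_extend
            best = max(best, -cost + rec(i + 1, j, "qg"))
        if j < nt:
            cost = gap_extend if state == "tg" else gap_open + gap_extend
            best = max(best, -cost + rec(i, j + 1, "tg"))
        return best

    best = 0.0
    for i in range(nq):
        for j in range(nt):
            best = max(best, rec(i, j, "m"))
    return best


def random_rooted_tree(taxa, rng, bl_mean=0.1) -> PhyloTree:
    """Random binary rooted tree by sequential joining."""
    from phylodissect.tree import Node

    nodes = [Node(t, float(rng.exponential(bl_mean))) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = Node(None, float(rng.exponential(bl_mean)))
        parent.add(a)
        parent.add(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    nodes[0].length = 0.0
    return PhyloTree(nodes[0])
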