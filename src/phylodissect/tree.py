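"""Phylogenetic trees.

A light rooted-node structure sized for likelihood work: parent/child
links, branch lengths in expected substitutions per site, and optional
internal-node labels (used for jackknife/posterior supports and for
naming branches in loss maps). Unrooted semantics — bipartitions,
likelihoods under reversible models — are obtained by treating the root
as an arbitrary basal node.

Newick parsing is delegated to dendropy; writing is our own and
byte-deterministic.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import dendropy

__all__ = ["Node", "PhyloTree", "canonical_split", "nontrivial_splits"]


class Node:
    __slots__ = ("name", "length", "children", "parent", "label")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 label: str | None = None):
        self.name = name          # leaf taxon id, or stable internal id
        self.length = length      # branch above this node
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label        # support value / annotation, written to Newick

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree container; the root branch length is ignored."""

    def __init__(self, root: Node):
        self.root = root
        self._assign_internal_names()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True,
                               suppress_internal_node_taxa=True)

        def build(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon is not None else None
            label = dnode.label if dnode.label and not dnode.is_leaf() else None
            if name is None and label is not None:
                name = label  # internal-node names double as branch ids
            node = Node(name=name, length=dnode.edge.length or 0.0, label=label)
            for c in dnode.child_nodes():
                node.add(build(c))
            return node

        return cls(build(dt.seed_node))

    @classmethod
    def from_newick_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, lengths: bool = True, labels: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if labels and node.label is not None:
                    s += str(node.label)
            if lengths and node.parent is not None:
                s += ":%.10g" % node.length
            return s

        return fmt(self.root) + ";"

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    def copy(self) -> "PhyloTree":
        def dup(n: Node) -> Node:
            m = Node(n.name, n.length, n.label)
            for c in n.children:
                m.add(dup(c))
            return m

        return PhyloTree(dup(self.root))

    # -- traversal ------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(name)

    def node_by_name(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def _assign_internal_names(self) -> None:
        """Stable postorder ids N0, N1, ... for unnamed internal nodes."""
        i = 0
        for n in self.postorder():
            if not n.is_leaf and n.name is None:
                n.name = f"N{i}"
            if not n.is_leaf:
                i += 1

    # -- editing --------------------------------------------------------
    def mrca(self, taxa: Sequence[str]) -> Node:
        want = set(taxa)
        below: dict[Node, set] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[n] = {n.name}
            else:
                below[n] = set().union(*(below[c] for c in n.children))
            if want <= below[n]:
                return n
        raise ValueError(f"taxa {sorted(want)} not all present in tree")

    def prune_to(self, keep: Sequence[str]) -> "PhyloTree":
        """Restrict to ``keep`` leaves, suppressing unifurcations and
        summing the lengths of merged branches."""
        keep_set = set(keep)
        missing = keep_set - set(self.taxa)
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")

        def rec(n: Node) -> Node | None:
            if n.is_leaf:
                return Node(n.name, n.length) if n.name in keep_set else None
            kids = [k for k in (rec(c) for c in n.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += n.length
                return kids[0]
            m = Node(n.name, n.length, n.label)
            for k in kids:
                m.add(k)
            return m

        new_root = rec(self.root)
        if new_root is None:
            raise ValueError("pruning removed every leaf")
        new_root.length = 0.0
        t = PhyloTree(new_root)
        return t

    def reroot_at_edge(self, child: Node) -> "PhyloTree":
        """Return a copy rerooted on the branch above ``child`` (split in half).

        Under a reversible model the likelihood is invariant to this.
        """
        if child.parent is None:
            return self.copy()
        # undirected adjacency over the existing nodes
        adj: dict[int, list[tuple[Node, float]]] = {}
        for n in self.postorder():
            adj.setdefault(id(n), [])
            if n.parent is not None:
                adj.setdefault(id(n.parent), [])
                adj[id(n)].append((n.parent, n.length))
                adj[id(n.parent)].append((n, n.length))
        half = child.length / 2.0
        parent = child.parent
        adj[id(child)] = [e for e in adj[id(child)] if e[0] is not parent]
        adj[id(parent)] = [e for e in adj[id(parent)] if e[0] is not child]

        def build(old: Node, came_from: Node | None, length: float) -> Node:
            n = Node(old.name if (old.is_leaf or not old.children) else None,
                     length, old.label)
            if old.is_leaf:
                n.name = old.name
            kids = [(o, l) for o, l in adj[id(old)]
                    if came_from is None or o is not came_from]
            for o, l in kids:
                n.add(build(o, old, l))
            return n

        new_root = Node(None, 0.0)
        new_root.add(build(child, parent, half))
        new_root.add(build(parent, child, half))
        return PhyloTree(_suppress_unifurcations(new_root))


def _suppress_unifurcations(root: Node) -> Node:
    def rec(n: Node) -> Node:
        n.children = [rec(c) for c in n.children]
        for c in n.children:
            c.parent = n
        if len(n.children) == 1 and n.parent is not None:
            c = n.children[0]
            c.length += n.length
            return c
        return n

    root = rec(root)
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = 0.0
    return root


def canonical_split(side: Sequence[str], taxa: Sequence[str]) -> frozenset[str]:
    """Canonicalize a bipartition side over the taxon universe.

    The stored side is the one *not* containing the reference taxon
    (first taxon in sorted order), so each bipartition has a unique key.
    """
    universe = frozenset(taxa)
    side = frozenset(side)
    if not side <= universe:
        raise ValueError("split side not within taxon universe")
    ref = min(universe)
    return universe - side if ref in side else side


def nontrivial_splits(tree: PhyloTree,
                      taxa: Sequence[str] | None = None) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted topology of ``tree``."""
    universe = frozenset(taxa if taxa is not None else tree.taxa)
    if frozenset(tree.taxa) != universe:
        raise ValueError("tree leaf set does not match taxon universe")
    n = len(universe)
    out: set[frozenset[str]] = set()
    below: dict[Node, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.name])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
        if node.parent is not None and 1 < len(below[node]) < n - 1:
            out.add(canonical_split(below[node], universe))
    return out
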