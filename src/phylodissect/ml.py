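"""Maximum-likelihood tree estimation.

Branch lengths are optimised one branch at a time with bounded Brent
searches against the exact single-branch objective, obtained from
cached inside ("below") and outside ("above") partials so that each
trial length costs one small matrix product rather than a full pruning
pass. Topology search is greedy hill-climbing over nearest-neighbour
interchanges (NNI), with candidates scored cheaply from the same cached
partials before the winning rearrangement is re-optimised in full.
Starting trees come from neighbour joining (scikit-bio) on pairwise
maximum-likelihood distances.

The user-facing entry point is :class:`MLPhylogeny`, whose ``fit()``
returns an :class:`MLResults`.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import LikelihoodEngine, _logsumexp0
from .substitution import SubstitutionModel
from .supermatrix import GenePartition, Supermatrix, slice_columns
from .tree import Node, PhyloTree, nontrivial_splits

__all__ = [
    "optimize_branch_lengths",
    "nni_search",
    "exhaustive_search",
    "nj_tree",
    "ml_pairwise_distance",
    "MLPhylogeny",
    "MLResults",
]

BRANCH_FLOOR = 1e-8
_TIE_TOL = 1e-12


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a degree-2 root into a trifurcation (unrooted form)."""
    t = tree.copy()
    root = t.root
    if len(root.children) != 2:
        return t
    internal = next((c for c in root.children if not c.is_leaf), None)
    if internal is None:  # two-leaf tree
        return t
    other = root.children[0] if root.children[1] is internal else root.children[1]
    other.length += internal.length
    new_root = Node(internal.name, 0.0, internal.label)
    for c in internal.children:
        new_root.add(c)
    new_root.add(other)
    return PhyloTree(new_root)


class _Workspace:
    """Inside/outside partials of one tree under one engine.

    Only engines with disjoint pattern classes (homogeneous model or a
    fixed site -> profile map) are supported; the mixture-likelihood
    mode has no single outside pass.
    """

    def __init__(self, engine: LikelihoodEngine, tree: PhyloTree):
        if engine.mixture:
            raise ValueError("outside pass not defined for mixture likelihoods")
        self.engine = engine
        self.tree = tree
        self.logw = np.log(engine.model.category_weights)
        self.groups = engine.groups
        # per group: dict node -> arrays
        self.f, self.slf, self.m = [], [], []
        self.a, self.sla, self._bctx = [], [], []
        for gi, (prof, rows) in enumerate(self.groups):
            f, slf = engine._below(tree, prof, rows, gi)
            eigen = engine.model.eigen(prof)
            m = {}
            for node in tree.postorder():
                if node.parent is not None:
                    p = engine._edge_p(eigen, node.length, prof)
                    m[node] = np.matmul(f[node], p.transpose(0, 2, 1))
            a, sla = self._above(tree, prof, rows, f, slf, m)
            self.f.append(f)
            self.slf.append(slf)
            self.m.append(m)
            self.a.append(a)
            self.sla.append(sla)
            self._bctx.append(self._last_b)

    def _above(self, tree, prof, rows, f, slf, m):
        eigen = self.engine.model.eigen(prof)
        pi = self.engine.model.profile_frequencies(prof)
        k = self.engine.model.n_categories
        n = rows.size
        s = pi.size
        a = {tree.root: np.broadcast_to(pi, (k, n, s))}
        sla = {tree.root: np.zeros((k, n))}
        bctx: dict[Node, tuple] = {}
        for u in tree.preorder():
            if u.is_leaf:
                continue
            for v in u.children:
                b = np.array(a[u], copy=True)
                sl = sla[u].copy()
                for w in u.children:
                    if w is not v:
                        b = b * m[w]
                        sl = sl + slf[w]
                scale = b.max(axis=2)
                np.maximum(scale, 1e-300, out=scale)
                b /= scale[:, :, None]
                sl = sl + np.log(scale)
                # pre-edge context, a function of the parent's state
                bctx[v] = (b, sl)
                p = self.engine._edge_p(eigen, v.length, prof)
                a[v] = np.matmul(b, p)
                sla[v] = sl
        self._last_b = bctx
        return a, sla

    # -- single-branch objective ---------------------------------------
    def branch_objective(self, v: Node):
        """Return f(t): exact lnL as a function of the length of the
        branch above ``v``, all other lengths fixed as cached."""
        counts = self.engine.class_counts
        parts = []
        for gi, (prof, rows) in enumerate(self.groups):
            eigen = self.engine.model.eigen(prof)
            b, slb = self._bctx[gi][v]
            fv = self.f[gi][v]
            base = slb + self.slf[gi][v]  # (K, n)
            parts.append((prof, eigen, b, fv, base, rows))

        def f(t: float) -> float:
            total = 0.0
            for prof, eigen, b, fv, base, rows in parts:
                p = self.engine._edge_p(eigen, t, prof)
                mv = np.matmul(fv, p.transpose(0, 2, 1))
                val = np.einsum("kns,kns->kn", b, mv)
                with np.errstate(divide="ignore"):
                    per = np.log(val) + base + self.logw[:, None]
                ll = _logsumexp0(per)
                total += float(ll @ counts[rows])
            return total

        return f

    # -- NNI candidate scoring ------------------------------------------
    def nni_objective(self, u: Node, v: Node, stay: Node, move_in: Node):
        """lnL(t_v) for the NNI that makes ``v``'s children
        {``stay``, sibling ``move_in``} and promotes the displaced child
        to ``u``. ``move_in`` must be a child of ``u``."""
        counts = self.engine.class_counts
        displaced = next(c for c in v.children if c is not stay)
        parts = []
        for gi, (prof, rows) in enumerate(self.groups):
            eigen = self.engine.model.eigen(prof)
            m = self.m[gi]
            slf = self.slf[gi]
            b_u = self.a[gi][u]
            sl = self.sla[gi][u].copy()
            for w in u.children:
                if w is v or w is move_in:
                    continue
                b_u = b_u * m[w]
                sl = sl + slf[w]
            ctx = b_u * m[displaced]
            sl = sl + slf[displaced]
            fv = m[stay] * m[move_in]
            slv = slf[stay] + slf[move_in]
            parts.append((prof, eigen, ctx, fv, sl + slv, rows))

        def f(t: float) -> float:
            total = 0.0
            for prof, eigen, ctx, fv, base, rows in parts:
                p = self.engine._edge_p(eigen, t, prof)
                mv = np.matmul(fv, p.transpose(0, 2, 1))
                val = np.einsum("kns,kns->kn", ctx, mv)
                with np.errstate(divide="ignore"):
                    per = np.log(val) + base + self.logw[:, None]
                ll = _logsumexp0(per)
                total += float(ll @ counts[rows])
            return total

        return f


def _workspace(engine: LikelihoodEngine, tree: PhyloTree) -> _Workspace:
    return _Workspace(engine, tree)


def _brent_branch(f, t0: float, tol: float = 1e-6) -> tuple[float, float, float]:
    """Maximise f over branch length; returns (t_best, f_best, f_at_t0)."""
    f0 = f(t0)
    hi = max(10.0, 3.0 * t0)
    res = minimize_scalar(lambda t: -f(t), bounds=(BRANCH_FLOOR, hi),
                          method="bounded", options={"xatol": tol})
    t1, f1 = float(res.x), -float(res.fun)
    # prefer the floor on flat likelihoods (ties toward smaller length)
    f_floor = f(BRANCH_FLOOR)
    if f_floor >= f1 - _TIE_TOL:
        t1, f1 = BRANCH_FLOOR, f_floor
    if f1 <= f0 + _TIE_TOL and t1 >= t0:
        return t0, f0, f0
    return t1, f1, f0


def optimize_branch_lengths(tree: PhyloTree, matrix: Supermatrix | None = None,
                            model: SubstitutionModel | None = None, *,
                            engine: LikelihoodEngine | None = None,
                            tol: float = 1e-6, max_sweeps: int = 50,
                            ) -> tuple[PhyloTree, float]:
    """Iterative per-branch optimisation; sweeps until lnL gain < tol.

    The returned lnL is never below the input tree's. Within a sweep
    the surrounding partials are held fixed (and refreshed between
    sweeps); if a sweep ever fails to improve the exact likelihood it
    is rolled back and redone with partials refreshed at every branch.
    """
    if engine is None:
        engine = LikelihoodEngine(matrix, model)
    tree = tree.copy()
    for n in tree.postorder():
        if n.parent is not None and n.length < BRANCH_FLOOR:
            n.length = BRANCH_FLOOR
    cur = engine.log_likelihood(tree)
    for _ in range(max_sweeps):
        saved = {n: n.length for n in tree.postorder() if n.parent is not None}
        ws = _workspace(engine, tree)
        for node in tree.postorder():
            if node.parent is None:
                continue
            t1, _, _ = _brent_branch(ws.branch_objective(node), node.length, tol)
            node.length = t1
        new = engine.log_likelihood(tree)
        if new < cur - 1e-9:
            # stale-context sweep hurt: roll back, redo exactly
            for n, t in saved.items():
                n.length = t
            for node in tree.postorder():
                if node.parent is None:
                    continue
                ws = _workspace(engine, tree)
                t1, f1, f0 = _brent_branch(ws.branch_objective(node), node.length, tol)
                if f1 > f0:
                    node.length = t1
            new = engine.log_likelihood(tree)
        gain = new - cur
        cur = max(new, cur)
        if gain < tol:
            break
    return tree, cur


def _nni_candidates(tree: PhyloTree):
    """(u, v, stay, move_in) tuples for every internal edge and both swaps."""
    for v in tree.postorder():
        if v.is_leaf or v.parent is None or len(v.children) != 2:
            continue
        u = v.parent
        z = next((c for c in u.children if c is not v), None)
        if z is None:
            continue
        x, y = v.children
        yield (u, v, y, z)  # move x up, bring z down next to y
        yield (u, v, x, z)


def _apply_nni(u: Node, v: Node, stay: Node, move_in: Node, t_central: float):
    displaced = next(c for c in v.children if c is not stay)
    v.children.remove(displaced)
    u.children.remove(move_in)
    u.add(displaced)
    v.add(move_in)
    v.length = max(t_central, BRANCH_FLOOR)


def nni_search(start: PhyloTree, matrix: Supermatrix | None = None,
               model: SubstitutionModel | None = None, *,
               engine: LikelihoodEngine | None = None,
               tol: float = 1e-6, max_rounds: int = 100,
               opt_sweeps: int = 50) -> tuple[PhyloTree, float]:
    """Greedy NNI hill-climb with branch re-optimisation.

    Terminates when no interchange improves lnL by more than ``tol``;
    the returned lnL is >= that of the (optimised) starting tree.
    """
    if engine is None:
        engine = LikelihoodEngine(matrix, model)
    if len(start.taxa) < 4:
        raise ValueError("NNI search needs at least 4 leaves")
    tree = unroot(start)
    tree, cur = optimize_branch_lengths(tree, engine=engine, tol=tol,
                                        max_sweeps=opt_sweeps)
    for _ in range(max_rounds):
        ws = _workspace(engine, tree)
        best = None
        for u, v, stay, move_in in _nni_candidates(tree):
            f = ws.nni_objective(u, v, stay, move_in)
            t1, f1, _ = _brent_branch(f, v.length, tol)
            if best is None or f1 > best[0]:
                best = (f1, u, v, stay, move_in, t1)
        if best is None or best[0] <= cur + tol:
            break
        _, u, v, stay, move_in, t1 = best
        _apply_nni(u, v, stay, move_in, t1)
        tree = PhyloTree(tree.root)
        tree, new = optimize_branch_lengths(tree, engine=engine, tol=tol,
                                            max_sweeps=opt_sweeps)
        if new <= cur + tol:
            break
        cur = new
    return tree, cur


def enumerate_topologies(taxa) -> list[PhyloTree]:
    """All unrooted binary topologies over ``taxa`` (use only for small n)."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def grow(trees, name):
        out = []
        for t in trees:
            edges = [n for n in t.postorder() if n.parent is not None]
            for i in range(len(edges)):
                t2 = t.copy()
                edges2 = [n for n in t2.postorder() if n.parent is not None]
                target = edges2[i]
                parent = target.parent
                parent.children.remove(target)
                mid = Node(None, 0.1)
                mid.add(target)
                mid.add(Node(name, 0.1))
                parent.add(mid)
                out.append(PhyloTree(t2.root))
        return out

    root = Node(None, 0.0)
    for n in taxa[:3]:
        root.add(Node(n, 0.1))
    trees = [PhyloTree(root)]
    for name in taxa[3:]:
        trees = grow(trees, name)
    return trees


def exhaustive_search(matrix: Supermatrix, model: SubstitutionModel, *,
                      engine: LikelihoodEngine | None = None,
                      tol: float = 1e-6) -> tuple[PhyloTree, float]:
    """Score every unrooted topology (small taxon counts only)."""
    if engine is None:
        engine = LikelihoodEngine(matrix, model)
    best = None
    for top in enumerate_topologies(matrix.taxa):
        t, lnl = optimize_branch_lengths(top, engine=engine, tol=tol)
        if best is None or lnl > best[1]:
            best = (t, lnl)
    return best


def ml_pairwise_distance(matrix: Supermatrix, model: SubstitutionModel,
                         taxon_a: str, taxon_b: str) -> float:
    """Two-taxon ML distance on shared non-missing columns."""
    ia, ib = matrix.taxa.index(taxon_a), matrix.taxa.index(taxon_b)
    miss = matrix.alphabet.missing_code
    shared = np.nonzero((matrix.data[ia] != miss) & (matrix.data[ib] != miss))[0]
    if shared.size == 0:
        raise ValueError(f"no overlapping columns between {taxon_a!r} and {taxon_b!r}")
    sub = slice_columns(matrix, shared)
    pair = Supermatrix([taxon_a, taxon_b], sub.data[[ia, ib]],
                       [GenePartition("pair", 0, sub.n_columns)],
                       matrix.alphabet)
    engine = LikelihoodEngine(pair, model)
    root = Node(None, 0.0)
    root.add(Node(taxon_a, 0.0))
    root.add(Node(taxon_b, 0.1))
    tree = PhyloTree(root)

    def neg(t):
        tree.root.children[1].length = t
        return -engine.log_likelihood(tree)

    res = minimize_scalar(neg, bounds=(BRANCH_FLOOR, 30.0), method="bounded",
                          options={"xatol": 1e-8})
    if neg(BRANCH_FLOOR) <= res.fun:
        return BRANCH_FLOOR
    return float(res.x)


def nj_tree(matrix: Supermatrix, model: SubstitutionModel) -> PhyloTree:
    """Neighbour joining (scikit-bio) on pairwise ML distances.

    Negative NJ branch lengths are clamped to zero (the floor).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    taxa = matrix.taxa
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ml_pairwise_distance(matrix, model, taxa[i], taxa[j])
    tree = _nj(DistanceMatrix(d, ids=taxa))
    out = PhyloTree.from_newick(str(tree))
    for node in out.postorder():
        if node.parent is not None and node.length < 0:
            node.length = BRANCH_FLOOR
    return unroot(out)


class MLResults:
    """Fitted maximum-likelihood phylogeny.

    Attributes
    ----------
    tree : PhyloTree
        Optimised topology and branch lengths.
    loglik : float
        Maximised log likelihood.
    """

    def __init__(self, model: "MLPhylogeny", tree: PhyloTree, loglik: float,
                 method: str):
        self.model = model
        self.tree = tree
        self.loglik = loglik
        self.method = method

    def splits(self):
        return nontrivial_splits(self.tree)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Maximum-likelihood phylogeny",
            "=" * 34,
            f"Taxa:              {m.matrix.n_taxa}",
            f"Columns:           {m.matrix.n_columns}",
            f"Model:             {type(m.submodel).__name__} "
            f"(alpha={m.submodel.alpha:.4g}, {m.submodel.n_categories} rate categories)",
            f"Search:            {self.method}",
            f"log likelihood:    {self.loglik:.6f}",
            f"Tree length:       {self.tree.total_length():.6f}",
            f"Tree:              {self.tree.to_newick()}",
        ]
        return "\n".join(lines)


class MLPhylogeny:
    """Homogeneous-model ML tree inference on a supermatrix.

    Parameters
    ----------
    matrix
        The alignment.
    submodel
        :class:`SubstitutionModel` (site-homogeneous; a fixed site ->
        profile map is also accepted via ``site_profile_map``).

    ``fit()`` runs NJ + NNI by default, or exhaustive topology scoring
    for small taxon sets, and returns :class:`MLResults`.
    """

    def __init__(self, matrix: Supermatrix, submodel: SubstitutionModel,
                 site_profile_map: np.ndarray | None = None):
        self.matrix = matrix
        self.submodel = submodel
        self.engine = LikelihoodEngine(matrix, submodel, site_profile_map)

    def fit(self, start: PhyloTree | None = None, method: str = "auto",
            tol: float = 1e-6, opt_sweeps: int = 50) -> MLResults:
        if method == "auto":
            method = "exhaustive" if self.matrix.n_taxa <= 5 else "nni"
        if method == "exhaustive":
            tree, lnl = exhaustive_search(self.matrix, self.submodel,
                                          engine=self.engine, tol=tol)
        elif method == "nni":
            if start is None:
                start = nj_tree(self.matrix, self.submodel)
            tree, lnl = nni_search(start, engine=self.engine, tol=tol,
                                   opt_sweeps=opt_sweeps)
        elif method == "fixed":
            if start is None:
                raise ValueError("method='fixed' needs a start tree")
            tree, lnl = optimize_branch_lengths(start, engine=self.engine,
                                                tol=tol, max_sweeps=opt_sweeps)
        else:
            raise ValueError(f"unknown method {method!r}")
        return MLResults(self, tree, lnl, method)
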