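"""Pruning-algorithm likelihoods.

Felsenstein's post-order pruning over a :class:`Supermatrix`, with

* alignment-pattern compression (unique columns, counted once),
* discrete-gamma rate categories, vectorised as a batch axis,
* an explicit missing state contributing all-ones partials,
* per-node rescaling with accumulated log factors, so 1e5-column
  matrices cannot underflow,
* optional site heterogeneity: either a fixed column -> profile map
  (each site's stationary frequencies are its profile's) or a full
  mixture over profiles (sites sum over profiles by weight).

The engine also exposes the inside/outside ("below"/"above") partials
that per-branch optimisation and NNI candidate scoring reuse; those
consumers live in :mod:`phylodissect.ml`.
"""

from __future__ import annotations

import numpy as np

from .substitution import SubstitutionModel
from .supermatrix import Supermatrix
from .tree import Node, PhyloTree

__all__ = ["LikelihoodEngine", "log_likelihood"]


def _logsumexp0(a: np.ndarray) -> np.ndarray:
    """logsumexp over axis 0, tolerating -inf columns."""
    m = a.max(axis=0)
    safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        return safe + np.log(np.exp(a - safe).sum(axis=0))


class LikelihoodEngine:
    """Likelihood calculator bound to one matrix + model (+ site map).

    Parameters
    ----------
    matrix
        Character matrix; taxa must match the trees scored later.
    model
        Substitution model. If it carries profiles and
        ``site_profile_map`` is None, the likelihood is the weighted
        mixture over profiles; with a map, each column uses its
        assigned profile's frequencies.
    site_profile_map
        Optional (n_columns,) integer array of profile indices.
    """

    def __init__(self, matrix: Supermatrix, model: SubstitutionModel,
                 site_profile_map: np.ndarray | None = None):
        if matrix.alphabet.n_states != model.n_states:
            raise ValueError("matrix and model alphabets differ")
        self.matrix = matrix
        self.model = model
        s = model.n_states
        self._tip = np.vstack([np.eye(s), np.ones(s)])  # state code -> partial row

        cols = matrix.data.T  # (n_columns, n_taxa)
        if site_profile_map is not None:
            site_profile_map = np.asarray(site_profile_map, dtype=np.intp)
            if site_profile_map.shape != (matrix.n_columns,):
                raise ValueError("site_profile_map length must equal n_columns")
            if model.profiles is None:
                raise ValueError("site_profile_map given but model has no profiles")
            key = np.concatenate([site_profile_map[:, None], cols], axis=1)
        else:
            key = cols
        uniq, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                          return_counts=True)
        self.site_to_class = inverse            # column -> class row
        self.class_counts = counts.astype(float)
        if site_profile_map is not None:
            self.class_profile = uniq[:, 0].astype(np.intp)
            self.class_patterns = uniq[:, 1:].astype(np.uint8)
        else:
            self.class_profile = None
            self.class_patterns = uniq.astype(np.uint8)
        self.n_classes = self.class_patterns.shape[0]
        self.mixture = site_profile_map is None and model.profiles is not None
        self._site_profile_map = site_profile_map
        if self.class_profile is not None:
            self.groups = [(int(c), np.nonzero(self.class_profile == c)[0])
                           for c in np.unique(self.class_profile)]
        else:
            self.groups = [(None, np.arange(self.n_classes))]
        self._tip_cache: dict = {}
        self._p_cache: dict = {}

    def with_model(self, model: SubstitutionModel) -> "LikelihoodEngine":
        """Same compressed patterns, different model parameters.

        Valid as long as the alphabet and (if mapped) the number of
        profiles are unchanged — used by the MCMC sampler so parameter
        moves do not recompress the alignment.
        """
        if model.n_states != self.model.n_states:
            raise ValueError("alphabet size changed")
        new = LikelihoodEngine.__new__(LikelihoodEngine)
        new.matrix = self.matrix
        new.model = model
        new._tip = self._tip
        new.site_to_class = self.site_to_class
        new.class_counts = self.class_counts
        new.class_profile = self.class_profile
        new.class_patterns = self.class_patterns
        new.n_classes = self.n_classes
        new.mixture = self.mixture
        new._site_profile_map = self._site_profile_map
        new.groups = self.groups
        new._tip_cache = self._tip_cache  # patterns unchanged
        new._p_cache = {}
        return new

    # ------------------------------------------------------------------
    def _taxon_rows(self, tree: PhyloTree) -> dict[str, int]:
        idx = {t: i for i, t in enumerate(self.matrix.taxa)}
        missing = [l.name for l in tree.leaves() if l.name not in idx]
        if missing:
            raise ValueError(f"tree leaves not in matrix: {sorted(missing)}")
        return idx

    def _edge_p(self, eigen, t: float, profile_index: int | None = None,
                ) -> np.ndarray:
        """(K_cat, S, S) transition matrices for one branch."""
        key = (profile_index, float(t))
        hit = self._p_cache.get(key)
        if hit is not None:
            return hit
        rates = self.model.category_rates
        e = np.exp(np.outer(rates, eigen.lam) * max(t, 0.0))  # (K, S)
        p = (eigen.u[None, :, :] * e[:, None, :]) @ eigen.v
        np.maximum(p, 0.0, out=p)
        if len(self._p_cache) > 20000:
            self._p_cache.clear()
        self._p_cache[key] = p
        return p

    def _leaf_tip(self, pats: np.ndarray, col: int, cache_key) -> np.ndarray:
        if cache_key is None:
            return self._tip[pats[:, col]]
        hit = self._tip_cache.get((cache_key, col))
        if hit is None:
            hit = self._tip[pats[:, col]]
            self._tip_cache[(cache_key, col)] = hit
        return hit

    def _below(self, tree: PhyloTree, profile_index: int | None,
               rows: np.ndarray, cache_key=None) -> tuple[dict, dict]:
        """Inside partials per node over the class rows given.

        Returns (F, slog): F[node] has shape (K_cat, n_rows, S) =
        P(data below node | state at node), slog[node] the accumulated
        per-(cat,row) log scale factors.
        """
        eigen = self.model.eigen(profile_index)
        k = self.model.n_categories
        taxon_row = self._taxon_rows(tree)
        pats = self.class_patterns[rows]
        f: dict[Node, np.ndarray] = {}
        slog: dict[Node, np.ndarray] = {}
        n = pats.shape[0]
        for node in tree.postorder():
            if node.is_leaf:
                tip = self._leaf_tip(pats, taxon_row[node.name], cache_key)
                f[node] = np.broadcast_to(tip, (k, n, tip.shape[1]))
                slog[node] = np.zeros((k, n))
            else:
                acc = None
                sl = np.zeros((k, n))
                for c in node.children:
                    p = self._edge_p(eigen, c.length, profile_index)  # (K,S,S)
                    m = np.matmul(f[c], p.transpose(0, 2, 1))  # (K,n,S)
                    acc = m if acc is None else acc * m
                    sl += slog[c]
                scale = acc.max(axis=2)
                np.maximum(scale, 1e-300, out=scale)
                acc = acc / scale[:, :, None]
                f[node] = acc
                slog[node] = sl + np.log(scale)
        return f, slog

    def _class_loglik_profile(self, tree: PhyloTree, profile_index: int | None,
                              rows: np.ndarray, cache_key=None) -> np.ndarray:
        """Per-class log likelihood under one profile (n_rows,)."""
        f, slog = self._below(tree, profile_index, rows, cache_key)
        pi = self.model.profile_frequencies(profile_index)
        root_l = f[tree.root] @ pi  # (K, n)
        with np.errstate(divide="ignore"):
            per_cat = np.log(root_l) + slog[tree.root]
        logw = np.log(self.model.category_weights)
        return _logsumexp0(per_cat + logw[:, None])

    def class_log_likelihoods(self, tree: PhyloTree) -> np.ndarray:
        """(n_classes,) per-pattern-class log likelihoods."""
        if self.class_profile is not None:
            out = np.empty(self.n_classes)
            for gi, (c, rows) in enumerate(self.groups):
                out[rows] = self._class_loglik_profile(tree, c, rows, gi)
            return out
        all_rows = self.groups[0][1]
        if self.mixture:
            ps = self.model.profiles
            per = np.stack([self._class_loglik_profile(tree, c, all_rows, 0)
                            for c in range(ps.n_profiles)])
            return _logsumexp0(per + np.log(ps.weights)[:, None])
        return self._class_loglik_profile(tree, None, all_rows, 0)

    def log_likelihood(self, tree: PhyloTree) -> float:
        """Total log likelihood of the matrix on ``tree``."""
        ll = float(self.class_log_likelihoods(tree) @ self.class_counts)
        if not np.isfinite(ll):
            bad = np.nonzero(~np.isfinite(self.class_log_likelihoods(tree)))[0]
            col = int(np.nonzero(np.isin(self.site_to_class, bad))[0][0])
            raise FloatingPointError(f"non-finite likelihood at column {col}")
        return ll

    def site_log_likelihoods(self, tree: PhyloTree) -> np.ndarray:
        """(n_columns,) per-site log likelihoods."""
        return self.class_log_likelihoods(tree)[self.site_to_class]

    def site_loglik_by_profile(self, tree: PhyloTree) -> np.ndarray:
        """(K_profiles, n_columns) per-site log likelihood under each profile.

        Used by the Gibbs reallocation move of the mixture sampler; the
        profile map (if any) is ignored — every site is scored under
        every profile.
        """
        if self.model.profiles is None:
            raise ValueError("model has no profiles")
        # compress raw columns only (profile key irrelevant here)
        cols = self.matrix.data.T
        uniq, inverse = np.unique(cols, axis=0, return_inverse=True)
        sub = LikelihoodEngine.__new__(LikelihoodEngine)
        sub.matrix = self.matrix
        sub.model = self.model
        sub._tip = self._tip
        sub.class_patterns = uniq.astype(np.uint8)
        sub.n_classes = uniq.shape[0]
        sub.class_profile = None
        sub.mixture = False
        sub.groups = [(None, np.arange(sub.n_classes))]
        sub._tip_cache = {}
        sub._p_cache = {}
        rows = sub.groups[0][1]
        out = np.stack([
            sub._class_loglik_profile(tree, c, rows, 0)[inverse]
            for c in range(self.model.profiles.n_profiles)])
        return out


def log_likelihood(tree: PhyloTree, matrix: Supermatrix, model: SubstitutionModel,
                   site_profile_map: np.ndarray | None = None) -> float:
    """One-shot pruning log likelihood (see :class:`LikelihoodEngine`)."""
    return LikelihoodEngine(matrix, model, site_profile_map).log_likelihood(tree)
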