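"""Bayesian phylogenetics under a finite profile mixture.

A desk-scale working miniature of site-heterogeneous (CAT-style)
Bayesian inference: each alignment column is allocated to one of K
amino-acid frequency profiles; exchangeabilities are fixed (Poisson or
LG) while profiles, their weights, the column allocations, branch
lengths, the gamma shape and the topology are sampled by
Metropolis-within-Gibbs:

(i)   Gibbs reallocation of each site to a profile, with probability
      proportional to weight x site likelihood under that profile;
(ii)  per-profile frequency updates through Dirichlet proposals
      (with the exact Hastings ratio);
(iii) conjugate Gibbs updates of the mixture weights;
(iv)  log-scale multiplier proposals on branch lengths and alpha;
(v)   NNI topology proposals.

Priors: branch lengths iid exponential (mean 0.1), alpha exponential
(mean 1), profiles and weights Dirichlet(1, ..., 1), topology uniform.
Proposal windows are tuned during burn-in only, preserving detailed
balance for retained samples.

Entry point: :class:`ProfileMixturePhylogeny` with ``fit()`` returning
:class:`MCMCResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import dirichlet as _dirichlet

from ._rng import stream
from .likelihood import LikelihoodEngine
from .ml import BRANCH_FLOOR, unroot
from .resampling import SplitSupport, chain_compare, consensus_from_support, \
    split_frequencies
from .substitution import ProfileSet, SubstitutionModel, poisson_model
from .supermatrix import Supermatrix
from .tree import Node, PhyloTree

__all__ = [
    "MCMCConfig",
    "ChainSample",
    "mcmc_run",
    "posterior_supports",
    "convergence_report",
    "ProfileMixturePhylogeny",
    "MCMCResults",
]


@dataclass(frozen=True)
class MCMCConfig:
    n_profiles: int = 10
    n_iterations: int = 2000
    burnin_fraction: float = 0.25
    sample_thinning: int = 10
    n_chains: int = 2
    seed: int = 0
    # move weights: relative frequency of each move per iteration
    move_weights: dict = field(default_factory=lambda: {
        "branch": 4, "alpha": 1, "profile": 2, "profile_ind": 1,
        "weights": 1, "topology": 2,
    })
    start_tree: str | None = None        # Newick; None draws from the prior
    realloc_every: int = 5           # Gibbs site reallocation interval
    branch_prior_mean: float = 0.1
    alpha_prior_mean: float = 1.0
    profile_proposal_conc: float = 200.0
    n_categories: int = 4
    exchangeabilities: str = "poisson"  # or "lg"
    tune_interval: int = 50

    def __post_init__(self):
        if not (0.0 <= self.burnin_fraction < 1.0):
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.n_profiles < 1:
            raise ValueError("need at least one profile")
        if self.sample_thinning < 1 or self.n_iterations < 1:
            raise ValueError("iteration counts must be positive")


@dataclass
class ChainSample:
    iteration: int
    tree: PhyloTree
    alpha: float
    profiles: ProfileSet
    site_allocations: np.ndarray
    loglik: float
    logprior: float


def _random_topology(taxa, rng, bl_mean) -> PhyloTree:
    """Uniform random unrooted binary topology (sequential leaf addition),
    branch lengths iid exponential."""
    taxa = list(taxa)
    root = Node(None, 0.0)
    for t in taxa[:3]:
        root.add(Node(t, float(rng.exponential(bl_mean))))
    tree = PhyloTree(root)
    for name in taxa[3:]:
        edges = [n for n in tree.postorder() if n.parent is not None]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        parent.children.remove(target)
        mid = Node(None, float(rng.exponential(bl_mean)))
        mid.add(target)
        mid.add(Node(name, float(rng.exponential(bl_mean))))
        parent.add(mid)
        tree = PhyloTree(tree.root)
    return tree


class _ChainState:
    def __init__(self, matrix: Supermatrix, config: MCMCConfig,
                 rng: np.random.Generator):
        self.matrix = matrix
        self.config = config
        self.rng = rng
        base = (poisson_model(n_categories=config.n_categories,
                              alphabet=matrix.alphabet)
                if config.exchangeabilities == "poisson" else None)
        if base is None:
            from .substitution import lg_model
            base = lg_model(n_categories=config.n_categories)
        self.exch = base.exchangeabilities
        k = config.n_profiles
        s = matrix.alphabet.n_states
        # draw the initial state from the prior
        self.alpha = float(rng.exponential(config.alpha_prior_mean))
        self.profiles = rng.dirichlet(np.ones(s), size=k)
        self.profiles = np.clip(self.profiles, 1e-6, None)
        self.profiles /= self.profiles.sum(axis=1, keepdims=True)
        self.weights = rng.dirichlet(np.ones(k))
        self.z = rng.choice(k, size=matrix.n_columns, p=self.weights)
        if config.start_tree is not None:
            self.tree = PhyloTree.from_newick(config.start_tree)
            if sorted(self.tree.taxa) != sorted(matrix.taxa):
                raise ValueError("start_tree leaves do not match matrix taxa")
        else:
            self.tree = _random_topology(matrix.taxa, rng,
                                         config.branch_prior_mean)
        # tunable proposal windows
        self.win = {"branch": 1.0, "alpha": 0.7, "profile": config.profile_proposal_conc}
        self._acc = {m: [0, 0] for m in self.win}
        self._engine = LikelihoodEngine(matrix, self._model(), self.z)
        self.loglik = self._loglik()

    # -- likelihood plumbing -------------------------------------------
    def _model(self) -> SubstitutionModel:
        ps = ProfileSet(profiles=self.profiles.copy(),
                        weights=self.weights / self.weights.sum())
        base = self.profiles.mean(axis=0)
        return SubstitutionModel(self.exch, base / base.sum(),
                                 self.alpha, self.config.n_categories,
                                 ps, self.matrix.alphabet)

    def engine(self) -> LikelihoodEngine:
        return self._engine

    def set_alpha(self, alpha: float):
        self.alpha = alpha
        self._engine = self._engine.with_model(self._engine.model.with_alpha(alpha))

    def set_profile(self, k: int, vec: np.ndarray):
        self.profiles[k] = vec
        ps = ProfileSet(profiles=self.profiles.copy(),
                        weights=self.weights / self.weights.sum())
        self._engine = self._engine.with_model(
            self._engine.model.with_profiles(ps, keep_eigen_except=k))

    def rebuild_engine(self):
        self._engine = LikelihoodEngine(self.matrix, self._model(), self.z)

    def _loglik(self, tree: PhyloTree | None = None) -> float:
        return self.engine().log_likelihood(tree if tree is not None else self.tree)

    def logprior(self) -> float:
        mu = self.config.branch_prior_mean
        lp = 0.0
        for n in self.tree.postorder():
            if n.parent is not None:
                lp += -math.log(mu) - n.length / mu
        lp += -math.log(self.config.alpha_prior_mean) - \
            self.alpha / self.config.alpha_prior_mean
        return lp  # flat Dirichlet(1) priors contribute constants

    # -- moves ----------------------------------------------------------
    def _metropolis(self, kind: str, delta: float) -> bool:
        ok = math.log(self.rng.random()) < delta
        a = self._acc[kind]
        a[0] += ok
        a[1] += 1
        return ok

    def move_branch(self):
        edges = [n for n in self.tree.postorder() if n.parent is not None]
        node = edges[self.rng.integers(len(edges))]
        lam = self.win["branch"]
        factor = math.exp(lam * (self.rng.random() - 0.5))
        t_old, t_new = node.length, max(node.length * factor, BRANCH_FLOOR)
        node.length = t_new
        new_ll = self._loglik()
        mu = self.config.branch_prior_mean
        delta = (new_ll - self.loglik) - (t_new - t_old) / mu + math.log(factor)
        if self._metropolis("branch", delta):
            self.loglik = new_ll
        else:
            node.length = t_old

    def move_alpha(self):
        lam = self.win["alpha"]
        factor = math.exp(lam * (self.rng.random() - 0.5))
        a_old, a_new = self.alpha, self.alpha * factor
        self.set_alpha(a_new)
        new_ll = self._loglik()
        mu = self.config.alpha_prior_mean
        delta = (new_ll - self.loglik) - (a_new - a_old) / mu + math.log(factor)
        if self._metropolis("alpha", delta):
            self.loglik = new_ll
        else:
            self.set_alpha(a_old)

    def move_profile(self):
        k = self.rng.integers(self.config.n_profiles)
        conc = self.win["profile"]
        old = self.profiles[k].copy()
        prop = self.rng.dirichlet(conc * old)
        prop = np.clip(prop, 1e-6, None)
        prop /= prop.sum()
        # Hastings ratio of the Dirichlet random-walk proposal
        log_q_fwd = _dirichlet.logpdf(prop, conc * old)
        log_q_rev = _dirichlet.logpdf(old, conc * prop)
        self.set_profile(k, prop)
        new_ll = self._loglik()
        delta = (new_ll - self.loglik) + log_q_rev - log_q_fwd
        if self._metropolis("profile", delta):
            self.loglik = new_ll
        else:
            self.set_profile(k, old)

    def _residue_counts(self, k: int) -> np.ndarray:
        cols = np.nonzero(self.z == k)[0]
        s = self.matrix.alphabet.n_states
        counts = np.zeros(s)
        if cols.size:
            block = self.matrix.data[:, cols].ravel()
            block = block[block < s]
            counts += np.bincount(block, minlength=s)
        return counts

    def move_profile_ind(self):
        """Independence proposal from Dirichlet(1 + residue counts of the
        profile's sites) — a close match to the conditional posterior, so
        profiles can jump straight to the data's composition."""
        k = self.rng.integers(self.config.n_profiles)
        param = 1.0 + self._residue_counts(int(k))
        old = self.profiles[k].copy()
        prop = self.rng.dirichlet(param)
        prop = np.clip(prop, 1e-6, None)
        prop /= prop.sum()
        log_q_fwd = _dirichlet.logpdf(prop, param)
        log_q_rev = _dirichlet.logpdf(old, param)
        self.set_profile(k, prop)
        new_ll = self._loglik()
        delta = (new_ll - self.loglik) + log_q_rev - log_q_fwd
        if self._metropolis("profile", delta):
            self.loglik = new_ll
        else:
            self.set_profile(k, old)

    def move_weights(self):
        counts = np.bincount(self.z, minlength=self.config.n_profiles)
        self.weights = self.rng.dirichlet(1.0 + counts)
        # conjugate Gibbs draw: likelihood of z given weights is multinomial

    def move_realloc(self):
        per_profile = self.engine().site_loglik_by_profile(self.tree)  # (K, n)
        logp = per_profile + np.log(self.weights)[:, None]
        logp -= logp.max(axis=0, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=0, keepdims=True)
        u = self.rng.random(p.shape[1])
        self.z = (np.cumsum(p, axis=0) < u[None, :]).sum(axis=0).astype(np.intp)
        self.rebuild_engine()
        self.loglik = self._loglik()

    def move_topology(self):
        internal = [v for v in self.tree.postorder()
                    if v.parent is not None and not v.is_leaf
                    and len(v.children) == 2]
        if not internal:
            return
        v = internal[self.rng.integers(len(internal))]
        u = v.parent
        sibs = [c for c in u.children if c is not v]
        if not sibs:
            return
        # uniform choice of both subtrees keeps the proposal symmetric
        z = sibs[int(self.rng.integers(len(sibs)))]
        x = v.children[int(self.rng.integers(2))]
        v.children.remove(x)
        u.children.remove(z)
        u.add(x)
        v.add(z)
        new_ll = self._loglik()
        if math.log(self.rng.random()) < (new_ll - self.loglik):
            self.loglik = new_ll
        else:
            u.children.remove(x)
            v.children.remove(z)
            v.add(x)
            u.add(z)

    def tune(self):
        for kind in ("branch", "alpha"):
            acc, tot = self._acc[kind]
            if tot >= 20:
                rate = acc / tot
                if rate < 0.15:
                    self.win[kind] *= 0.7
                elif rate > 0.45:
                    self.win[kind] *= 1.4
                self._acc[kind] = [0, 0]


def mcmc_run(matrix: Supermatrix, config: MCMCConfig) -> list[list[ChainSample]]:
    """Run ``config.n_chains`` independent chains; return their samples.

    Samples are recorded after burn-in at the thinning interval.
    Identical matrix + config (seed included) reproduce the identical
    sample sequence.
    """
    if matrix.n_taxa < 4:
        raise ValueError("MCMC needs at least 4 taxa")
    chains = []
    moves_cycle = []
    for name, w in sorted(config.move_weights.items()):
        moves_cycle.extend([name] * int(w))
    burnin_end = int(config.burnin_fraction * config.n_iterations)
    for ci in range(config.n_chains):
        rng = stream(config.seed, f"mcmc/chain{ci}")
        state = _ChainState(matrix, config, rng)
        if not np.isfinite(state.loglik):
            raise FloatingPointError("non-finite likelihood at initialization")
        samples: list[ChainSample] = []
        for it in range(1, config.n_iterations + 1):
            order = rng.permutation(len(moves_cycle))
            for mi in order:
                name = moves_cycle[mi]
                getattr(state, f"move_{name}")()
            if it % config.realloc_every == 0:
                state.move_realloc()
            if it <= burnin_end and it % config.tune_interval == 0:
                state.tune()
            if it > burnin_end and it % config.sample_thinning == 0:
                ps = ProfileSet(profiles=state.profiles.copy(),
                                weights=state.weights / state.weights.sum())
                samples.append(ChainSample(
                    iteration=it,
                    tree=state.tree.copy(),
                    alpha=state.alpha,
                    profiles=ps,
                    site_allocations=state.z.copy(),
                    loglik=state.loglik,
                    logprior=state.logprior(),
                ))
        chains.append(samples)
    return chains


def posterior_supports(samples: list[ChainSample],
                       burnin_fraction: float = 0.0) -> SplitSupport:
    """Split frequencies over the post-burn-in sampled trees."""
    if not (0.0 <= burnin_fraction < 1.0):
        raise ValueError("burnin_fraction must be in [0, 1)")
    start = int(burnin_fraction * len(samples))
    kept = samples[start:]
    if not kept:
        raise ValueError("no post-burn-in samples")
    return split_frequencies([unroot(s.tree) for s in kept])


def convergence_report(chains: list[list[ChainSample]],
                       burnin_fraction: float = 0.0,
                       ) -> tuple[float, float, dict]:
    """MaxDiff/MeanDiff between chains' posterior split supports.

    With more than two chains, the pairwise maximum of each statistic
    is reported. The per-split table maps each split to its frequency
    in every chain.
    """
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    supports = [posterior_supports(c, burnin_fraction) for c in chains]
    max_diff = mean_diff = 0.0
    for i in range(len(supports)):
        for j in range(i + 1, len(supports)):
            mx, mn = chain_compare(supports[i], supports[j])
            max_diff = max(max_diff, mx)
            mean_diff = max(mean_diff, mn)
    union = sorted({s for sup in supports for s in sup.frequencies},
                   key=sorted)
    table = {s: [sup.frequencies.get(s, 0.0) for sup in supports] for s in union}
    return max_diff, mean_diff, table


class MCMCResults:
    """Posterior samples and diagnostics of a profile-mixture run."""

    def __init__(self, model: "ProfileMixturePhylogeny", config: MCMCConfig,
                 chains: list[list[ChainSample]]):
        self.model = model
        self.config = config
        self.chains = chains

    @property
    def samples(self) -> list[ChainSample]:
        return [s for c in self.chains for s in c]

    def posterior_supports(self, chain: int | None = None) -> SplitSupport:
        if chain is not None:
            return posterior_supports(self.chains[chain])
        return split_frequencies([unroot(s.tree) for s in self.samples])

    def consensus(self) -> PhyloTree:
        return consensus_from_support(self.posterior_supports())

    def convergence(self) -> tuple[float, float, dict]:
        return convergence_report(self.chains)

    def trace_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chain\titeration\tloglik\talpha\ttree_length\n")
            for ci, chain in enumerate(self.chains):
                for s in chain:
                    fh.write(f"{ci}\t{s.iteration}\t{s.loglik:.6g}\t"
                             f"{s.alpha:.6g}\t{s.tree.total_length():.6g}\n")

    def summary(self) -> str:
        alphas = np.array([s.alpha for s in self.samples])
        lls = np.array([s.loglik for s in self.samples])
        tls = np.array([s.tree.total_length() for s in self.samples])
        lines = [
            "Profile-mixture Bayesian phylogeny (finite-K CAT-style)",
            "=" * 56,
            f"Taxa:                 {self.model.matrix.n_taxa}",
            f"Columns:              {self.model.matrix.n_columns}",
            f"Profiles (K):         {self.config.n_profiles}",
            f"Chains x samples:     {len(self.chains)} x "
            f"{len(self.chains[0]) if self.chains else 0}",
            f"mean lnL:             {lls.mean():.4f}",
            f"alpha mean (sd):      {alphas.mean():.4f} ({alphas.std():.4f})",
            f"tree length mean:     {tls.mean():.4f}",
        ]
        if len(self.chains) >= 2:
            mx, mn, _ = self.convergence()
            lines.append(f"MaxDiff / MeanDiff:   {mx:.6g} / {mn:.6g}")
        return "\n".join(lines)


class ProfileMixturePhylogeny:
    """Site-heterogeneous Bayesian tree model for a supermatrix.

    Parameters mirror :class:`MCMCConfig`; ``fit()`` runs the chains
    and returns :class:`MCMCResults`.
    """

    def __init__(self, matrix: Supermatrix, config: MCMCConfig | None = None,
                 **config_kw):
        self.matrix = matrix
        if config is None:
            config = MCMCConfig(**config_kw)
        elif config_kw:
            config = replace(config, **config_kw)
        self.config = config

    def fit(self, seed: int | None = None) -> MCMCResults:
        config = self.config if seed is None else replace(self.config, seed=seed)
        chains = mcmc_run(self.matrix, config)
        return MCMCResults(self, config, chains)
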