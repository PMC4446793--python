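"""Time-reversible substitution models with discrete-gamma rates.

A :class:`SubstitutionModel` bundles symmetric exchangeabilities r_ij,
stationary frequencies pi, a gamma shape alpha with its discrete
categories, and optionally a set of site frequency profiles (the
site-heterogeneous, CAT-style case: same exchangeabilities, per-profile
stationary frequencies).

The rate matrix is the GTR construction Q_ij = r_ij * pi_j (i != j),
normalised so the expected substitution rate at stationarity,
-sum_i pi_i Q_ii, is one: branch lengths are then expected
substitutions per site. Transition matrices come from the symmetric
eigendecomposition of pi^{1/2} Q pi^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.stats import gamma as _gamma

from .alphabet import AMINO_ACIDS, TWO_STATE, Alphabet

__all__ = [
    "ProfileSet",
    "SubstitutionModel",
    "discrete_gamma_rates",
    "rate_matrix",
    "transition_probabilities",
    "lg_model",
    "poisson_model",
]

_SIMPLEX_TOL = 1e-12
_GAMMA_CACHE: dict = {}


@dataclass(frozen=True)
class ProfileSet:
    """K stationary-frequency profiles over the alphabet, with mixture weights."""

    profiles: np.ndarray  # (K, n_states)
    weights: np.ndarray   # (K,)

    def __post_init__(self):
        p = np.asarray(self.profiles, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if p.ndim != 2 or w.shape != (p.shape[0],):
            raise ValueError("profiles must be (K, S) with K weights")
        if np.any(p <= 0) or np.any(w < 0):
            raise ValueError("profiles must be strictly positive, weights non-negative")
        if np.abs(p.sum(axis=1) - 1.0).max() > _SIMPLEX_TOL * p.shape[1]:
            raise ValueError("each profile must sum to 1")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "profiles", p)
        object.__setattr__(self, "weights", w)

    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[0]


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Equal-weight discrete gamma categories by bin means.

    The gamma has shape ``alpha`` and mean one (rate parameter also
    ``alpha``). Category boundaries are the i/n quantiles and each
    category rate is the exact conditional mean of the density over its
    bin, via the incomplete-gamma identity; the weighted mean of the
    rates is one by construction.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_categories < 1:
        raise ValueError("need at least one category")
    n = int(n_categories)
    if n == 1:
        return np.array([1.0]), np.array([1.0])
    key = (float(alpha), n)
    hit = _GAMMA_CACHE.get(key)
    if hit is not None:
        return hit[0].copy(), hit[1].copy()
    edges = _gamma.ppf(np.arange(1, n) / n, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X | a<X<b] * P(a<X<b) = F_{alpha+1}(b) - F_{alpha+1}(a) for mean-1 gamma
    upper_cdf = _gamma.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    rates = n * np.diff(upper_cdf)
    weights = np.full(n, 1.0 / n)
    if len(_GAMMA_CACHE) > 4096:
        _GAMMA_CACHE.clear()
    _GAMMA_CACHE[key] = (rates, weights)
    return rates.copy(), weights.copy()


def rate_matrix(exchangeabilities: np.ndarray, frequencies: np.ndarray) -> np.ndarray:
    """Unit-normalised GTR rate matrix Q_ij = r_ij pi_j."""
    r = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(frequencies, dtype=float)
    s = r.shape[0]
    if r.shape != (s, s) or pi.shape != (s,):
        raise ValueError("shape mismatch between exchangeabilities and frequencies")
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > _SIMPLEX_TOL * s:
        raise ValueError("frequencies must be a strictly positive simplex")
    off = r * ~np.eye(s, dtype=bool)
    if np.any(off < 0) or not np.allclose(off, off.T):
        raise ValueError("exchangeabilities must be symmetric and non-negative")
    q = off * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    norm = -(pi * np.diag(q)).sum()
    if norm <= 0:
        raise ValueError("degenerate rate matrix")
    return q / norm


@dataclass(frozen=True)
class _Eigen:
    """Spectral factors of a reversible Q: Q = U diag(lam) V, V = U^{-1}."""

    lam: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self.u * np.exp(self.lam * t)) @ self.v
        return np.clip(p, 0.0, None)


def _eigendecompose(q: np.ndarray, pi: np.ndarray) -> _Eigen:
    d = np.sqrt(pi)
    b = (q * d[:, None]) / d[None, :]
    b = 0.5 * (b + b.T)  # exact symmetry against rounding
    lam, w = np.linalg.eigh(b)
    u = w / d[:, None]
    v = w.T * d[None, :]
    return _Eigen(lam=lam, u=u, v=v)


def transition_probabilities(q: np.ndarray, frequencies: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a reversible Q with stationary ``frequencies``."""
    return _eigendecompose(np.asarray(q, float), np.asarray(frequencies, float)).transition(t)


class SubstitutionModel:
    """Exchangeabilities + frequencies + discrete-gamma rates (+ profiles).

    Parameters
    ----------
    exchangeabilities
        Symmetric (S, S) matrix of relative rates r_ij; diagonal unused.
    frequencies
        Stationary frequencies pi (length S); with ``profiles`` set this
        is the fallback used when no profile index is requested.
    alpha
        Gamma shape for among-site rate variation.
    n_categories
        Number of equal-weight discrete gamma categories (default 4).
    profiles
        Optional :class:`ProfileSet` for site-heterogeneous likelihoods.
    """

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray,
                 alpha: float = 1.0, n_categories: int = 4,
                 profiles: ProfileSet | None = None,
                 alphabet: Alphabet = AMINO_ACIDS):
        self.exchangeabilities = np.asarray(exchangeabilities, dtype=float)
        self.frequencies = np.asarray(frequencies, dtype=float)
        if self.frequencies.shape[0] != alphabet.n_states:
            raise ValueError("frequency vector does not match alphabet size")
        self.alphabet = alphabet
        self.alpha = float(alpha)
        self.n_categories = int(n_categories)
        self.profiles = profiles
        self.category_rates, self.category_weights = discrete_gamma_rates(
            self.alpha, self.n_categories)
        self._eigen_cache: dict[int | None, _Eigen] = {}
        # validate eagerly
        rate_matrix(self.exchangeabilities, self.frequencies)

    @property
    def n_states(self) -> int:
        return self.alphabet.n_states

    def profile_frequencies(self, profile_index: int | None) -> np.ndarray:
        if profile_index is None:
            return self.frequencies
        if self.profiles is None:
            raise ValueError("model has no profile set")
        return self.profiles.profiles[profile_index]

    def rate_matrix(self, profile_index: int | None = None) -> np.ndarray:
        return rate_matrix(self.exchangeabilities,
                           self.profile_frequencies(profile_index))

    def eigen(self, profile_index: int | None = None) -> _Eigen:
        if profile_index not in self._eigen_cache:
            pi = self.profile_frequencies(profile_index)
            self._eigen_cache[profile_index] = _eigendecompose(
                self.rate_matrix(profile_index), pi)
        return self._eigen_cache[profile_index]

    def transition(self, t: float, profile_index: int | None = None) -> np.ndarray:
        return self.eigen(profile_index).transition(t)

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        m = SubstitutionModel(self.exchangeabilities, self.frequencies,
                              alpha, self.n_categories, self.profiles,
                              self.alphabet)
        m._eigen_cache = self._eigen_cache  # eigendecompositions are alpha-free
        return m

    def with_profiles(self, profiles: ProfileSet | None,
                      keep_eigen_except: int | None = None) -> "SubstitutionModel":
        m = SubstitutionModel(self.exchangeabilities, self.frequencies,
                              self.alpha, self.n_categories, profiles,
                              self.alphabet)
        if keep_eigen_except is not None:
            m._eigen_cache = {k: v for k, v in self._eigen_cache.items()
                              if k != keep_eigen_except}
        return m


def poisson_model(alpha: float = 1.0, n_categories: int = 4,
                  alphabet: Alphabet = AMINO_ACIDS,
                  profiles: ProfileSet | None = None) -> SubstitutionModel:
    """All exchangeabilities equal, uniform frequencies (F81/Poisson)."""
    s = alphabet.n_states
    r = np.ones((s, s))
    pi = np.full(s, 1.0 / s)
    return SubstitutionModel(r, pi, alpha, n_categories, profiles, alphabet)


def two_state_model(pi0: float = 0.5, alpha: float = 1.0,
                    n_categories: int = 1) -> SubstitutionModel:
    """Binary-alphabet model used by the closed-form oracles."""
    pi = np.array([pi0, 1.0 - pi0])
    return SubstitutionModel(np.ones((2, 2)), pi, alpha, n_categories,
                             alphabet=TWO_STATE)


def _load_lg() -> tuple[np.ndarray, np.ndarray, str]:
    text = resources.files("phylodissect.data").joinpath("lg.txt").read_text()
    values, order = [], None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("alphabet"):
            order = line.split()[1]
            continue
        values.append(float(line))
    assert order is not None and len(values) == 210
    s = len(order)
    r = np.zeros((s, s))
    k = 0
    for i in range(1, s):
        for j in range(i):
            r[i, j] = r[j, i] = values[k]
            k += 1
    pi = np.array(values[190:])
    pi = pi / pi.sum()
    return r, pi, order


def lg_model(alpha: float = 1.0, n_categories: int = 4,
             profiles: ProfileSet | None = None) -> SubstitutionModel:
    """The LG empirical amino-acid model, shipped as a data file."""
    r, pi, order = _load_lg()
    assert order == AMINO_ACIDS.letters
    return SubstitutionModel(r, pi, alpha, n_categories, profiles, AMINO_ACIDS)
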