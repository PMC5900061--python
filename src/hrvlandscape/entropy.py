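"""Entropic landscape of RR-increment actions.

For the empirical distributions of single, pair and triplet actions the
Shannon entropies (natural log) are

    H1 = -sum_i p(i) ln p(i)
    H2 = -sum_{ij} p(i,j) ln p(i,j)
    H3 = -sum_{ijk} p(i,j,k) ln p(i,j,k)

The excess entropies h_i = H_i - H_{i-1} give the transition-rate entropy
S_T = h2 = H2 - H1 (the entropy-rate estimate of the best first-order Markov
model) and the self-transfer entropy sTE = h3 - h2 = H3 - 2 H2 + H1, which
measures lag-2 memory not captured by a first-order transition matrix.  For
increments occurring independently, H2 = 2 H1 and H3 = 3 H1, hence S_T = H1
and sTE = 0.

Estimators are plug-in (maximum likelihood) without bias correction; each
H_L uses its own window count.  sTE may come out slightly negative from
finite-sample boundary effects and is reported unclamped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import product

import numpy as np

from .symbolize import (SymbolSeries, LGramDistribution, lgram_distribution,
                        InsufficientDataError)


@dataclass
class EntropyProfile:
    """Entropies (nats) of the action L-gram distributions of one signal."""

    H1: float
    H2: float
    H3: float
    n_windows: dict | None = None
    resolution: float | None = None
    alphabet: str = "full"

    @property
    def h2(self) -> float:
        return self.H2 - self.H1

    @property
    def h3(self) -> float:
        return self.H3 - self.H2

    @property
    def S_T(self) -> float:
        """Transition-rate entropy (entropy-rate estimate), h2 = H2 − H1."""
        return self.H2 - self.H1

    @property
    def sTE(self) -> float:
        """Self-transfer entropy, h3 − h2 = H3 − 2·H2 + H1."""
        return self.H3 - 2.0 * self.H2 + self.H1

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(h2=self.h2, h3=self.h3, S_T=self.S_T, sTE=self.sTE)
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def shannon(dist: LGramDistribution | dict | np.ndarray) -> float:
    """Shannon entropy −Σ p ln p in nats, with 0·ln 0 := 0."""
    if isinstance(dist, LGramDistribution):
        p = np.array(list(dist.probs.values()), dtype=float)
    elif isinstance(dist, dict):
        p = np.array(list(dist.values()), dtype=float)
    else:
        p = np.asarray(dist, dtype=float)
    if len(p) and (np.any(p < -1e-15) or abs(p.sum() - 1.0) > 1e-9):
        raise ValueError("not a probability distribution")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def entropy_profile(symbols: SymbolSeries, alphabet: str = "full") -> EntropyProfile:
    """H1, H2, H3 (and derived S_T, sTE) from plug-in L-gram distributions."""
    dists = {L: lgram_distribution(symbols, L, alphabet) for L in (1, 2, 3)}
    if dists[3].n_windows < 3:
        raise InsufficientDataError("need at least 3 valid triplet windows")
    return EntropyProfile(
        H1=shannon(dists[1]), H2=shannon(dists[2]), H3=shannon(dists[3]),
        n_windows={L: d.n_windows for L, d in dists.items()},
        resolution=symbols.space.resolution, alphabet=alphabet)


def profile_from_distributions(d1, d2, d3) -> EntropyProfile:
    """Entropy profile from explicitly supplied L = 1, 2, 3 distributions."""
    return EntropyProfile(H1=shannon(d1), H2=shannon(d2), H3=shannon(d3))


def iid_profile(p: np.ndarray | dict) -> EntropyProfile:
    """Profile of an exactly independent action process.

    The pair and triplet distributions are formed as exact outer products of
    the single-action distribution, so the identities H2 = 2·H1, H3 = 3·H1,
    S_T = H1 and sTE = 0 hold to machine precision.
    """
    if isinstance(p, dict):
        labels, probs = list(p.keys()), np.array(list(p.values()), dtype=float)
    else:
        probs = np.asarray(p, dtype=float)
        labels = list(range(len(probs)))
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("not a probability distribution")
    d1 = dict(zip(labels, probs))
    d2 = {(a, b): d1[a] * d1[b] for a, b in product(labels, repeat=2)}
    d3 = {(a, b, c): d1[a] * d1[b] * d1[c] for a, b, c in product(labels, repeat=3)}
    return profile_from_distributions(d1, d2, d3)


def _stationary(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (eigenvector)."""
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def analytic_profile(chain) -> EntropyProfile:
    """Exact entropy profile of a stationary Markov chain over actions.

    For a first-order chain with stationary distribution π and transition
    matrix T: H1 = H(π), S_T = −Σ_i π_i Σ_j T_ij ln T_ij (the entropy rate),
    sTE = 0 exactly, H2 = H1 + S_T and H3 = H1 + 2·S_T.  For a second-order
    chain the profile is computed from the stationary distribution over
    action pairs, and sTE is generally positive.
    """
    from .synth import MarkovChainSpec  # local import to avoid a cycle

    if not isinstance(chain, MarkovChainSpec):
        raise TypeError("expected a MarkovChainSpec")
    chain.validate()
    T = chain.transition
    if chain.order == 1:
        pi = _stationary(T)
        H1 = shannon(pi)
        with np.errstate(divide="ignore", invalid="ignore"):
            logT = np.where(T > 0, np.log(np.where(T > 0, T, 1.0)), 0.0)
        S_T = float(-(pi[:, None] * T * logT).sum())
        return EntropyProfile(H1=H1, H2=H1 + S_T, H3=H1 + 2 * S_T)
    # order 2: lift to the pair chain (i,j) -> (j,k)
    m = len(chain.labels)
    P = np.zeros((m * m, m * m))
    for i in range(m):
        for j in range(m):
            for k in range(m):
                P[i * m + j, j * m + k] = T[i, j, k]
    mu = _stationary(P)                       # stationary pair distribution
    mu2 = mu.reshape(m, m)
    H2 = shannon(mu)
    H1 = shannon(mu2.sum(axis=0))             # marginal of the second coordinate
    nu = mu2[:, :, None] * T                  # triple distribution p(i,j,k)
    H3 = shannon(nu.ravel() / nu.sum())
    return EntropyProfile(H1=H1, H2=H2, H3=H3)
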