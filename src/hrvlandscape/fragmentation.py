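"""Heart-rate fragmentation from the ternary a/d/0 action sequence.

Pattern probabilities over overlapping pairs and triplets of actions:
P(aa), P(dd), P(aaa), P(ddd) describe monotone runs; P(ad), P(da), P(ada),
P(dad) describe alternations.  The derived indices are

    PIP = P(ad) + P(da)          (abrupt sign changes of the increment)
    PSS = 1 - [P(aaa) + P(ddd)]  (complement of short monotone sequences)
    PAS = P(ada) + P(dad)        (alternation clusters of length 3)

Two modes are provided.  The default, ``zero-inclusive``, counts windows
over the full ternary sequence so that no-change (0) actions enter the
denominators — the appropriate convention when zero increments are abundant,
as in transplanted-heart rhythms.  ``zero-excluded`` drops the 0 actions
first (making the remaining a/d actions adjacent), which approximates the
original fragmentation-index definitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .symbolize import SymbolSeries, InsufficientDataError

MODES = ("zero-inclusive", "zero-excluded")


@dataclass
class FragmentationProfile:
    """Pattern probabilities and fragmentation indices of one signal."""

    pair_probs: dict = field(default_factory=dict)    # {('a','d'): p, ...}
    triple_probs: dict = field(default_factory=dict)
    mode: str = "zero-inclusive"
    n_pairs: int = 0
    n_triples: int = 0

    def _pp(self, *pattern: str) -> float:
        return self.pair_probs.get(pattern, 0.0) if len(pattern) == 2 \
            else self.triple_probs.get(pattern, 0.0)

    @property
    def P_aa(self) -> float:
        return self._pp("a", "a")

    @property
    def P_dd(self) -> float:
        return self._pp("d", "d")

    @property
    def P_ad(self) -> float:
        return self._pp("a", "d")

    @property
    def P_da(self) -> float:
        return self._pp("d", "a")

    @property
    def P_aaa(self) -> float:
        return self._pp("a", "a", "a")

    @property
    def P_ddd(self) -> float:
        return self._pp("d", "d", "d")

    @property
    def P_ada(self) -> float:
        return self._pp("a", "d", "a")

    @property
    def P_dad(self) -> float:
        return self._pp("d", "a", "d")

    @property
    def PIP(self) -> float:
        """Percentage (as probability per window) of inflection pairs."""
        return self.P_ad + self.P_da

    @property
    def PSS(self) -> float:
        """Complement of short monotone triples."""
        return 1.0 - (self.P_aaa + self.P_ddd)

    @property
    def PAS(self) -> float:
        """Alternation clusters of length 3."""
        return self.P_ada + self.P_dad

    def to_dict(self) -> dict:
        named = {f"P_{''.join(k)}": v for k, v in self.pair_probs.items()}
        named.update({f"P_{''.join(k)}": v for k, v in self.triple_probs.items()})
        return {
            "mode": self.mode, "n_pairs": self.n_pairs, "n_triples": self.n_triples,
            "P_aa": self.P_aa, "P_dd": self.P_dd, "P_ad": self.P_ad,
            "P_da": self.P_da, "P_aaa": self.P_aaa, "P_ddd": self.P_ddd,
            "P_ada": self.P_ada, "P_dad": self.P_dad,
            "PIP": self.PIP, "PSS": self.PSS, "PAS": self.PAS,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def pair_table(self) -> np.ndarray:
        """3×3 pair-probability table ordered (a, 0, d) × (a, 0, d)."""
        order = ("a", "0", "d")
        return np.array([[self.pair_probs.get((r, c), 0.0) for c in order]
                         for r in order])


def _segments(values: np.ndarray, valid: np.ndarray) -> list[np.ndarray]:
    """Contiguous stretches of valid actions (windows never span a gap)."""
    if len(values) == 0:
        return []
    segs, start = [], None
    for i, ok in enumerate(valid):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            segs.append(values[start:i])
            start = None
    if start is not None:
        segs.append(values[start:])
    return segs


def _count_windows(segs: list[np.ndarray], L: int) -> tuple[dict, int]:
    counts: dict = {}
    total = 0
    for seg in segs:
        n = len(seg) - L + 1
        if n <= 0:
            continue
        win = np.lib.stride_tricks.sliding_window_view(seg, L)
        uniq, c = np.unique(win, axis=0, return_counts=True)
        for row, cc in zip(uniq, c):
            key = tuple(str(x) for x in row)
            counts[key] = counts.get(key, 0) + int(cc)
        total += n
    return counts, total


def pattern_profile(symbols: SymbolSeries,
                    mode: str = "zero-inclusive") -> FragmentationProfile:
    """Pair/triple pattern probabilities and PIP/PSS/PAS.

    In ``zero-inclusive`` mode overlapping windows run over the full ternary
    sequence and the denominators count every valid window.  In
    ``zero-excluded`` mode the 0 actions are removed within each contiguous
    valid stretch before windowing.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    tern = symbols.ternary
    segs = _segments(tern, symbols.valid)
    if mode == "zero-excluded":
        segs = [s[s != "0"] for s in segs]
    pair_counts, n_pairs = _count_windows(segs, 2)
    triple_counts, n_triples = _count_windows(segs, 3)
    if n_pairs < 1 or n_triples < 1:
        raise InsufficientDataError("need at least one valid pair and triplet window")
    pair_probs = {k: v / n_pairs for k, v in pair_counts.items()}
    triple_probs = {k: v / n_triples for k, v in triple_counts.items()}
    return FragmentationProfile(pair_probs=pair_probs, triple_probs=triple_probs,
                                mode=mode, n_pairs=n_pairs, n_triples=n_triples)


def pattern_coverage(profile: FragmentationProfile) -> float:
    """Fraction of action pairs free of the no-change action.

    Returns P(aa) + P(dd) + P(ad) + P(da): the share of the dynamics the
    monotone/alternation pair statistics describe; the complement involves
    zero increments.
    """
    if profile.mode != "zero-inclusive":
        raise ValueError("coverage is defined for zero-inclusive profiles")
    return profile.P_aa + profile.P_dd + profile.P_ad + profile.P_da


def full_pattern_space(L: int) -> list[tuple[str, ...]]:
    """All ternary patterns of length L, in (a, 0, d) lexical order."""
    return list(product(("a", "0", "d"), repeat=L))
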