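"""RR-increment extraction and symbolization over a resolution-defined alphabet.

An RR series ``RR_0, RR_1, ...`` yields increments ``dRR_i = RR_i - RR_{i-1}``.
Each increment is mapped to the nearest multiple of the resolution ε (the
*action*); the sign of the action gives the ternary view: ``a`` (acceleration,
negative), ``d`` (deceleration, positive) or ``0`` (no change).  At ε = 7 ms
the grouping is {..., (-10..-4) → -7, (-3..3) → 0, (4..10) → 7, ...}.

Empirical distributions of L consecutive actions (L = 1, 2, 3) over
overlapping windows feed the entropy and fragmentation measures.  Windows
that span a gap boundary (a deleted segment) are excluded from all counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RRSeries

TERNARY = ("a", "0", "d")  # acceleration, no change, deceleration


class InsufficientDataError(ValueError):
    """Raised when too few valid windows are available for an estimate."""


@dataclass
class ActionSpace:
    """Alphabet of actions: multiples of the resolution ε in ms."""

    resolution: float = 8.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    def label_of(self, drr: np.ndarray) -> np.ndarray:
        """Nearest multiple of ε, exact ties rounded away from zero."""
        drr = np.asarray(drr, dtype=float)
        k = np.sign(drr) * np.floor(np.abs(drr) / self.resolution + 0.5)
        return k.astype(np.int64)


@dataclass
class IncrementSeries:
    """Consecutive RR differences with a pair-validity mask.

    ``valid_pair[i]`` is False when the increment ``rr[i+1] - rr[i]`` spans a
    gap boundary and must be excluded from all counts.
    """

    drr: np.ndarray
    valid_pair: np.ndarray

    def __post_init__(self) -> None:
        self.drr = np.asarray(self.drr, dtype=float)
        self.valid_pair = np.asarray(self.valid_pair, dtype=bool)
        if len(self.drr) != len(self.valid_pair):
            raise ValueError("drr and valid_pair must have equal length")

    def __len__(self) -> int:
        return len(self.drr)


@dataclass
class SymbolSeries:
    """Quantized actions: integer multiples ``k`` of the resolution ε."""

    k: np.ndarray                       # integer multiples of eps
    valid: np.ndarray                   # inherited pair-validity mask
    space: ActionSpace = field(default_factory=ActionSpace)

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.int64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.k) != len(self.valid):
            raise ValueError("k and valid must have equal length")

    def __len__(self) -> int:
        return len(self.k)

    @property
    def actions(self) -> np.ndarray:
        """Action labels in ms (k × ε)."""
        return self.k * self.space.resolution

    @property
    def ternary(self) -> np.ndarray:
        """Ternary view: 'a' for k < 0, 'd' for k > 0, '0' for k == 0."""
        out = np.full(len(self.k), "0", dtype="<U1")
        out[self.k < 0] = "a"
        out[self.k > 0] = "d"
        return out


def increments(series: RRSeries) -> IncrementSeries:
    """Consecutive differences dRR_i = RR_i − RR_{i−1} with gap masking."""
    if len(series) < 2:
        return IncrementSeries(np.empty(0), np.empty(0, dtype=bool))
    drr = np.diff(series.rr)
    # the increment into beat i+1 is invalid when that beat follows a gap
    valid = ~series.gap[1:]
    return IncrementSeries(drr, valid)


def quantize(inc: IncrementSeries, space: ActionSpace | float = 8.0) -> SymbolSeries:
    """Map increments to the nearest multiple of the resolution ε."""
    if not isinstance(space, ActionSpace):
        space = ActionSpace(float(space))
    return SymbolSeries(space.label_of(inc.drr), inc.valid_pair, space)


def symbolize(series: RRSeries, resolution: float = 8.0) -> SymbolSeries:
    """Convenience: increments + quantization in one step."""
    return quantize(increments(series), ActionSpace(resolution))


@dataclass
class LGramDistribution:
    """Empirical distribution of L consecutive actions (overlapping windows)."""

    L: int
    probs: dict
    n_windows: int
    alphabet: str = "full"              # "full" (ms labels) or "ternary"

    def __post_init__(self) -> None:
        if self.L not in (1, 2, 3):
            raise ValueError("L must be 1, 2 or 3")
        total = sum(self.probs.values())
        if self.probs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, expected 1")

    def __getitem__(self, key) -> float:
        return self.probs.get(key, 0.0)


def lgram_distribution(symbols: SymbolSeries, L: int,
                       alphabet: str = "full") -> LGramDistribution:
    """Plug-in distribution of L-grams of actions.

    Overlapping windows of L consecutive actions are counted; any window
    containing an invalid pair is dropped.  ``alphabet`` selects the full
    (ε-multiple) labels or the ternary a/d/0 view.
    """
    if L not in (1, 2, 3):
        raise ValueError("L must be 1, 2 or 3")
    if alphabet == "full":
        values = symbols.k * symbols.space.resolution
        if float(symbols.space.resolution).is_integer():
            values = values.astype(np.int64)
    elif alphabet == "ternary":
        values = symbols.ternary
    else:
        raise ValueError("alphabet must be 'full' or 'ternary'")
    # encode actions as small ids, windows as a single integer code, and
    # count with a 1-D unique (much faster than row-wise uniqueness)
    levels, ids = np.unique(values, return_inverse=True)
    base = len(levels)
    n_total = len(ids) - L + 1
    if n_total <= 0:
        raise InsufficientDataError(f"no valid windows of length {L}")
    code = ids[: n_total].astype(np.int64)
    ok = symbols.valid[: n_total].copy()
    for off in range(1, L):
        code = code * base + ids[off: off + n_total]
        ok &= symbols.valid[off: off + n_total]
    code = code[ok]
    n = len(code)
    if n == 0:
        raise InsufficientDataError(f"no valid windows of length {L}")
    uniq, counts = np.unique(code, return_counts=True)
    probs = {}
    for c_code, c in zip(uniq, counts):
        digits = []
        for _ in range(L):
            digits.append(levels[c_code % base])
            c_code //= base
        digits.reverse()
        key = digits[0].item() if L == 1 else tuple(d.item() for d in digits)
        probs[key] = c / n
    return LGramDistribution(L=L, probs=probs, n_windows=n, alphabet=alphabet)
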