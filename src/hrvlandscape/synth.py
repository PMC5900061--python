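"""Synthetic RR-series generators with analytic ground truth.

Four families cover every downstream stage:

- :func:`simulate_markov_rr` — action sequences from a finite-state Markov
  chain over increment labels (multiples of the resolution ε), integrated
  onto a mean RR level with reflection at physiologic bounds.  The analytic
  entropy profile of the chain (:func:`hrvlandscape.entropy.analytic_profile`)
  is the ground truth for the empirical estimators.
- :func:`simulate_modulated_rr` — a sinus-like rhythm with respiratory (HF)
  and low-frequency (LF) sinusoidal modulation plus Gaussian jitter, for the
  spectral indices.
- :func:`inject_erratic` — Poisson-placed bursts of strict ±amplitude
  alternation emulating episodes of erratic rhythm.
- :func:`simulate_cohort` — longitudinal two-arm cohorts whose per-signal
  target H1 follows a linear trajectory in months after surgery (flat in the
  F-like arm, increasing in the NF-like arm).  Signals are realized by a
  quantized-Gaussian level-noise generator whose H1 is known analytically,
  so designed slopes are recoverable end to end.

All generators are pure functions of their parameters and a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .io import RRSeries, CohortManifest, ManifestEntry

PHYSIO_BOUNDS = (300.0, 2000.0)
MAX_REFLECT_FRACTION = 1e-3


@dataclass
class MarkovChainSpec:
    """First- or second-order Markov chain over increment actions.

    ``labels`` are the action values in ms (multiples of the resolution,
    including 0).  For ``order == 1`` the transition table is (m, m); for
    ``order == 2`` it is (m, m, m) with ``transition[i, j, k]`` the
    probability of action ``k`` after the pair ``(i, j)``.
    """

    labels: np.ndarray
    transition: np.ndarray
    order: int = 1
    initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.validate()

    def validate(self) -> None:
        m = len(self.labels)
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        expected = (m,) * (self.order + 1)
        if self.transition.shape != expected:
            raise ValueError(f"transition table must have shape {expected}")
        if np.any(self.transition < 0):
            raise ValueError("transition probabilities must be non-negative")
        rows = self.transition.reshape(-1, m).sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition rows must each sum to 1")
        if 0.0 not in self.labels:
            raise ValueError("the action alphabet must include 0")

    def stationary(self) -> np.ndarray:
        """Stationary distribution over single actions."""
        from .entropy import _stationary
        m = len(self.labels)
        if self.order == 1:
            return _stationary(self.transition)
        P = np.zeros((m * m, m * m))
        for i in range(m):
            for j in range(m):
                for k in range(m):
                    P[i * m + j, j * m + k] = self.transition[i, j, k]
        return _stationary(P).reshape(m, m).sum(axis=0)


def iid_chain(probs, labels) -> MarkovChainSpec:
    """Chain with identical rows: actions drawn independently from ``probs``."""
    probs = np.asarray(probs, dtype=float)
    T = np.tile(probs, (len(probs), 1))
    return MarkovChainSpec(labels=np.asarray(labels, float), transition=T)


def alternation_chain(q: float, resolution: float = 8.0) -> MarkovChainSpec:
    """Two-action chain that switches sign with probability ``q``.

    The stationary pair distribution assigns probability ``q`` to the
    alternating pairs, so the designed PIP equals ``q`` exactly.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    # three labels keep 0 in the alphabet but give it zero probability
    T = np.array([
        [1 - q, 0.0, q],
        [0.5, 0.0, 0.5],     # never visited
        [q, 0.0, 1 - q],
    ])
    return MarkovChainSpec(labels=np.array([-resolution, 0.0, resolution]),
                           transition=T)


def antipersistent_chain(resolution: float = 8.0) -> MarkovChainSpec:
    """A 3-action first-order chain with strong acceleration/deceleration
    alternation (an erratic-rhythm caricature).  The near-deterministic
    reversal keeps the integrated RR walk within physiologic bounds."""
    T = np.array([
        [0.01, 0.09, 0.90],
        [0.40, 0.20, 0.40],
        [0.90, 0.09, 0.01],
    ])
    return MarkovChainSpec(labels=np.array([-resolution, 0.0, resolution]),
                           transition=T)


def lag2_mirror_chain(c: float = 0.9, resolution: float = 8.0) -> MarkovChainSpec:
    """Second-order chain whose next action mirrors the action two steps back.

    The next action equals the negative of the lag-2 action with probability
    ``c``, a pure memory effect invisible to any first-order transition
    matrix — its analytic |sTE| is strictly positive.
    """
    if not 0.0 < c < 1.0:
        raise ValueError("c must be in (0, 1)")
    labels = np.array([-resolution, 0.0, resolution])
    m = 3
    T = np.full((m, m, m), (1.0 - c) / (m - 1))
    for i in range(m):
        mirror = {0: 2, 1: 1, 2: 0}[i]
        T[i, :, :] = (1.0 - c) / (m - 1)
        T[i, :, mirror] = c
    return MarkovChainSpec(labels=labels, transition=T, order=2)


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] by folding."""
    period = 2.0 * (hi - lo)
    y = np.mod(x - lo, period)
    return lo + np.minimum(y, period - y)


def _sample_chain(chain: MarkovChainSpec, n: int, rng: np.random.Generator
                  ) -> np.ndarray:
    """Indices of n actions sampled from the chain."""
    m = len(chain.labels)
    out = np.empty(n, dtype=np.int64)
    if chain.order == 1:
        init = chain.initial if chain.initial is not None else chain.stationary()
        cum = np.cumsum(chain.transition, axis=1)
        out[0] = rng.choice(m, p=np.asarray(init, float) / np.sum(init))
        u = rng.random(n)
        for t in range(1, n):
            out[t] = np.searchsorted(cum[out[t - 1]], u[t])
        return out
    # order 2: seed with two independent draws from the pair marginal
    init = chain.initial if chain.initial is not None else np.full(m, 1.0 / m)
    cum = np.cumsum(chain.transition, axis=2)
    out[0] = rng.choice(m, p=init)
    if n > 1:
        out[1] = rng.choice(m, p=init)
    u = rng.random(n)
    for t in range(2, n):
        out[t] = np.searchsorted(cum[out[t - 2], out[t - 1]], u[t])
    return out


def simulate_markov_rr(chain: MarkovChainSpec, n_beats: int, mean_rr: float = 1150.0,
                       seed: int | None = None,
                       bounds: tuple[float, float] = PHYSIO_BOUNDS,
                       max_reflect_fraction: float = MAX_REFLECT_FRACTION
                       ) -> RRSeries:
    """RR series whose increments follow a Markov chain over actions.

    ``n_beats - 1`` actions are sampled and cumulatively summed onto
    ``mean_rr``; the walk is reflected at the physiologic ``bounds``.  If
    more than ``max_reflect_fraction`` of beats are altered by reflection the
    chain drifts irrecoverably and an error advises a balanced chain.
    """
    if seed is None:
        raise ValueError("a seed is required (generators are pure functions)")
    if n_beats < 2:
        raise ValueError("n_beats must be at least 2")
    rng = np.random.default_rng(seed)
    idx = _sample_chain(chain, n_beats - 1, rng)
    inc = chain.labels[idx]
    free = mean_rr + np.concatenate(([0.0], np.cumsum(inc)))
    rr = _fold(free, *bounds)
    # count beats whose increment was altered by folding: a mirrored stretch
    # of a sign-symmetric chain is statistically identical, only fold points
    # distort the action sequence
    n_reflected = int(np.sum(np.diff(rr) != np.diff(free)))
    if n_reflected > max_reflect_fraction * n_beats:
        raise ValueError(
            f"{n_reflected}/{n_beats} beats required reflection at the "
            f"physiologic bounds {bounds}; use a balanced (mean-zero, "
            "antipersistent) chain or fewer beats")
    return RRSeries(rr=rr, meta={"generator": "markov", "seed": seed,
                                 "n_reflected": n_reflected})


def simulate_modulated_rr(params: dict, n_beats: int, seed: int | None = None
                          ) -> RRSeries:
    """Sinus-like rhythm with HF/LF sinusoidal modulation and Gaussian jitter.

    ``RR_i = mean_rr + hf_amp sin(2π hf_freq t_i) + lf_amp sin(2π lf_freq t_i)
    + N(0, noise_sd)`` with ``t_i`` the cumulative RR time in seconds.
    """
    if seed is None:
        raise ValueError("a seed is required (generators are pure functions)")
    p = {"mean_rr": 800.0, "hf_amp": 0.0, "hf_freq": 0.25,
         "lf_amp": 0.0, "lf_freq": 0.1, "noise_sd": 0.0}
    p.update(params)
    if p["hf_amp"] < 0 or p["lf_amp"] < 0 or p["noise_sd"] < 0:
        raise ValueError("amplitudes must be non-negative")
    for f in (p["hf_freq"], p["lf_freq"]):
        if not 0.0 < f < 0.5:
            raise ValueError("modulation frequencies must lie in (0, 0.5) Hz")
    if p["mean_rr"] - p["hf_amp"] - p["lf_amp"] <= 0:
        raise ValueError("modulation amplitudes can produce non-positive RR")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, p["noise_sd"], n_beats) if p["noise_sd"] > 0 \
        else np.zeros(n_beats)
    rr = np.empty(n_beats)
    t = 0.0
    two_pi = 2.0 * np.pi
    for i in range(n_beats):
        rr[i] = (p["mean_rr"]
                 + p["hf_amp"] * np.sin(two_pi * p["hf_freq"] * t)
                 + p["lf_amp"] * np.sin(two_pi * p["lf_freq"] * t)
                 + noise[i])
        if rr[i] <= 0:
            raise ValueError("parameters produced a non-positive RR interval")
        t += rr[i] / 1000.0
    return RRSeries(rr=rr, meta={"generator": "modulated", "seed": seed})


def inject_erratic(series: RRSeries, burst_rate: float, burst_len: int,
                   burst_amp: float, seed: int | None = None) -> RRSeries:
    """Superimpose Poisson-placed bursts of strict ±amplitude alternation.

    ``burst_rate`` is the expected number of bursts per hour of recording;
    each burst perturbs ``burst_len`` consecutive beats with offsets
    0, +amp, 0, +amp, ... so the increments alternate +amp / −amp.
    """
    if seed is None:
        raise ValueError("a seed is required (generators are pure functions)")
    if burst_rate < 0:
        raise ValueError("burst_rate must be non-negative")
    out = series.take(np.arange(len(series)))
    if burst_rate == 0 or burst_len < 2 or len(series) < burst_len:
        return out
    rng = np.random.default_rng(seed)
    hours = float(np.sum(series.rr)) / 3.6e6
    n_bursts = rng.poisson(burst_rate * hours)
    offsets = burst_amp * (np.arange(burst_len) % 2)
    for start in np.sort(rng.integers(0, len(series) - burst_len + 1, n_bursts)):
        out.rr[start:start + burst_len] = (
            series.rr[start:start + burst_len] + offsets)
    out.meta = dict(series.meta)
    out.meta.update(n_bursts=int(n_bursts), burst_amp=burst_amp,
                    burst_len=burst_len)
    return out


# ---------------------------------------------------------------------------
# quantized-Gaussian level-noise generator with analytic H1
# ---------------------------------------------------------------------------

def _discrete_gaussian_pmf(sigma: float, resolution: float) -> np.ndarray:
    """PMF over multiples of ε of a Gaussian level rounded to the ε grid."""
    kmax = max(2, int(np.ceil(8.0 * sigma / resolution)))
    k = np.arange(-kmax, kmax + 1)
    edges_hi = (k + 0.5) * resolution / sigma
    edges_lo = (k - 0.5) * resolution / sigma
    p = 0.5 * (special.erf(edges_hi / np.sqrt(2)) - special.erf(edges_lo / np.sqrt(2)))
    return p / p.sum()


def h1_of_level_sigma(sigma: float, resolution: float = 8.0) -> float:
    """Analytic H1 of the increments of i.i.d. quantized-Gaussian RR levels.

    With RR_i = mean + z_i, z_i i.i.d. on the ε grid, the increment
    distribution is the autocorrelation of the level PMF; H1 is its Shannon
    entropy (nats).
    """
    from scipy.signal import fftconvolve
    from .entropy import shannon
    if sigma <= 0:
        return 0.0
    pz = _discrete_gaussian_pmf(sigma, resolution)
    pd = fftconvolve(pz, pz[::-1])
    pd = np.abs(pd)
    pd = pd / pd.sum()
    return shannon(pd)


#: upper sigma bracket for the H1 inversion; H1 grows logarithmically with
#: sigma so this covers targets far beyond physiologic entropy levels
_SIGMA_MAX = 2000.0


def level_sigma_for_h1(target_h1: float, resolution: float = 8.0) -> float:
    """Invert :func:`h1_of_level_sigma` (monotone in sigma)."""
    lo = 1e-2
    h_lo = h1_of_level_sigma(lo, resolution)
    if target_h1 <= h_lo:
        raise ValueError(
            f"target H1={target_h1:.3f} nats at or below the lower bound "
            f"{h_lo:.3f} of the level-noise generator")
    hi = max(4.0 * resolution, 2.0)
    while h1_of_level_sigma(hi, resolution) < target_h1:
        hi *= 2.0
        if hi > _SIGMA_MAX:
            raise ValueError(
                f"target H1={target_h1:.3f} nats above the reachable bound "
                f"{h1_of_level_sigma(_SIGMA_MAX, resolution):.3f} "
                "of the level-noise generator")
    return float(optimize.brentq(
        lambda s: h1_of_level_sigma(s, resolution) - target_h1, lo, hi,
        xtol=1e-6, rtol=1e-10))


def simulate_level_noise_rr(sigma: float, n_beats: int, mean_rr: float = 800.0,
                            resolution: float = 8.0, seed: int | None = None
                            ) -> RRSeries:
    """RR series = mean level + i.i.d. Gaussian noise rounded to the ε grid.

    The signal is stationary and bounded (no random-walk drift); the
    increment marginal — hence H1 — is known in closed form via
    :func:`h1_of_level_sigma`.
    """
    if seed is None:
        raise ValueError("a seed is required (generators are pure functions)")
    rng = np.random.default_rng(seed)
    z = resolution * np.round(rng.normal(0.0, sigma, n_beats) / resolution)
    rr = mean_rr + z
    if np.any(rr <= 0):
        raise ValueError("noise level produced non-positive RR; raise mean_rr")
    return RRSeries(rr=rr, meta={"generator": "level-noise", "seed": seed,
                                 "sigma": sigma})


# ---------------------------------------------------------------------------
# longitudinal cohorts
# ---------------------------------------------------------------------------

#: follow-up visit structure (months after surgery) of a 6-subject stable arm
#: and an 8-subject complicated arm, as used in long-term transplant follow-up
F_VISITS = {
    "F1": [12, 20, 67], "F2": [14, 19, 96], "F3": [14, 36, 50, 61, 86],
    "F4": [12, 46, 57], "F5": [8, 12, 24, 36, 66, 78], "F6": [8, 12, 24, 36],
}
NF_VISITS = {
    "NF1": [14, 24, 37], "NF2": [20, 24, 25, 26, 36, 63],
    "NF3": [6, 12, 50, 64, 75], "NF4": [6, 32, 39, 91],
    "NF5": [9, 12, 19, 36, 61], "NF6": [7, 17, 36], "NF7": [12, 63, 78],
    "NF8": [14, 23, 38, 39, 42],
}


@dataclass
class ArmDesign:
    """Trajectory model for one cohort arm: H1 target per subject/visit."""

    group: str
    visits: dict                      # subject_id -> list of months
    intercept: float                  # target H1 (nats) at surgery
    slope_per_year: float             # change in target H1 per 12 months
    between_sd: float = 0.10          # SD of subject-level intercepts
    within_sd: float = 0.08           # SD of visit-level deviations


@dataclass
class CohortDesign:
    """Two-arm longitudinal design realized by the level-noise generator."""

    arms: list = field(default_factory=list)
    n_beats: int = 20_000
    mean_rr: float = 800.0
    resolution: float = 8.0


def default_cohort_design(slope_nf: float = 0.15) -> CohortDesign:
    """Flat (F-like) arm versus linearly increasing (NF-like) arm.

    Intercepts sit at the typical transplant-recipient H1 level (~1.4 nats);
    the NF-like arm gains ``slope_nf`` nats of H1 per year.
    """
    return CohortDesign(arms=[
        ArmDesign(group="F", visits=dict(F_VISITS), intercept=1.38,
                  slope_per_year=0.0),
        ArmDesign(group="NF", visits=dict(NF_VISITS), intercept=1.30,
                  slope_per_year=slope_nf),
    ])


def simulate_cohort(design: CohortDesign, seed: int | None = None,
                    out_dir: str | None = None
                    ) -> tuple[list[RRSeries], CohortManifest]:
    """Generate a longitudinal cohort of RR signals plus its manifest.

    For each subject an intercept is drawn around the arm intercept
    (between-subject SD); each visit's target H1 adds the linear time trend
    and a within-subject deviation.  The target is realized exactly (up to
    sampling noise) by the level-noise generator via the analytic
    H1 ↔ sigma mapping.  With ``out_dir`` set, signals and the manifest are
    written in the package's text formats.
    """
    if seed is None:
        raise ValueError("a seed is required (generators are pure functions)")
    root = np.random.SeedSequence(seed)
    signals: list[RRSeries] = []
    entries: list[ManifestEntry] = []
    arm_seeds = root.spawn(max(len(design.arms), 1))
    for arm, arm_ss in zip(design.arms, arm_seeds):
        subj_seeds = arm_ss.spawn(max(len(arm.visits), 1))
        for (subject, months), sss in zip(sorted(arm.visits.items()), subj_seeds):
            child = np.random.default_rng(sss)
            b0 = arm.intercept + child.normal(0.0, arm.between_sd)
            for visit_no, m in enumerate(months):
                target = (b0 + arm.slope_per_year * m / 12.0
                          + child.normal(0.0, arm.within_sd))
                sigma = level_sigma_for_h1(target, design.resolution)
                sig_seed = int(child.integers(0, 2**31 - 1))
                s = simulate_level_noise_rr(
                    sigma, design.n_beats, design.mean_rr,
                    design.resolution, seed=sig_seed)
                s.subject_id = subject
                s.months_post_htx = float(m)
                s.group = arm.group
                s.meta.update(target_H1=target)
                signals.append(s)
                entries.append(ManifestEntry(
                    path=f"{subject}_m{m:03d}.csv", subject_id=subject,
                    months_post_htx=float(m), group=arm.group))
    manifest = CohortManifest(entries)
    if out_dir is not None:
        import os
        from .io import write_rr, write_manifest
        os.makedirs(out_dir, exist_ok=True)
        for s, e in zip(signals, manifest.entries):
            e.path = os.path.join(out_dir, e.path)
            write_rr(s, e.path)
        write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return signals, manifest
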