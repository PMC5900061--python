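"""Model objects tying the per-signal and cohort analyses together.

``DynamicalLandscape`` is built from one RR series; ``fit()`` runs the
preprocessing chain, symbolization and all index families, returning a
``LandscapeResults`` with the complete index vector, a ``summary()`` table
and serialization helpers.  ``CohortTrend`` is built from a per-signal
profile table (one row per signal); ``fit()`` runs the full statistical
protocol for each index and renders the descriptive-plus-regression table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RRSeries, read_rr
from . import preprocess as _pre
from .symbolize import ActionSpace, increments, quantize, lgram_distribution
from .entropy import entropy_profile, EntropyProfile
from .fragmentation import pattern_profile, pattern_coverage, FragmentationProfile
from .hrv import all_indices, HRVIndices
from .symbolize import InsufficientDataError
from . import cohort as _cohort

#: index columns produced per signal, in reporting order
ENTROPY_INDICES = ["H3", "H2", "H1", "S_T", "sTE"]
HRV_INDICES = ["mean_HR", "SDNN", "RMSSD", "pNN20", "pNN50", "VLF", "LF", "HF"]
FRAG_INDICES = ["P_aa", "P_dd", "P_aaa", "P_ddd",
                "P_ad", "P_da", "P_ada", "P_dad", "PIP", "PSS", "PAS"]


class DynamicalLandscape:
    """Per-signal dynamical-landscape model.

    Parameters
    ----------
    series : RRSeries
        The beat-annotated series to analyse.
    resolution : float
        Symbolization resolution ε in ms (default 8, the usual Holter
        R-peak timing accuracy).
    preprocess : bool
        Apply the editing / hour-quality / nocturnal-selection chain before
        analysis.  Disable for synthetic, already-clean signals.
    n_beats : int
        Length of the analysed segment when preprocessing (default 20,000).
    frag_mode : str
        ``zero-inclusive`` (default) or ``zero-excluded`` fragmentation
        counting.
    """

    def __init__(self, series: RRSeries, resolution: float = 8.0,
                 preprocess: bool = True, n_beats: int = _pre.DEFAULT_N_BEATS,
                 frag_mode: str = "zero-inclusive",
                 median_window: int = _pre.DEFAULT_MEDIAN_WINDOW,
                 max_substitute_run: int = _pre.DEFAULT_MAX_SUBSTITUTE_RUN,
                 min_normal_fraction: float = _pre.DEFAULT_MIN_NORMAL_FRACTION,
                 min_beats: int = 100):
        self.series = series
        self.resolution = float(resolution)
        self.preprocess = preprocess
        self.n_beats = n_beats
        self.frag_mode = frag_mode
        self.median_window = median_window
        self.max_substitute_run = max_substitute_run
        self.min_normal_fraction = min_normal_fraction
        self.min_beats = min_beats

    @classmethod
    def from_file(cls, path: str, dialect: str = "auto", **kwargs
                  ) -> "DynamicalLandscape":
        return cls(read_rr(path, dialect), **kwargs)

    def config(self) -> dict:
        from . import __version__
        return {
            "package_version": __version__,
            "resolution_ms": self.resolution,
            "preprocess": self.preprocess,
            "n_beats": self.n_beats,
            "frag_mode": self.frag_mode,
            "median_window": self.median_window,
            "max_substitute_run": self.max_substitute_run,
            "min_normal_fraction": self.min_normal_fraction,
        }

    def fit(self) -> "LandscapeResults":
        series = self.series
        if self.preprocess:
            series = _pre.run(series, self.median_window,
                              self.max_substitute_run,
                              self.min_normal_fraction, self.n_beats)
        if self.preprocess and len(series) < self.min_beats:
            raise InsufficientDataError(
                f"only {len(series)} beats after preprocessing "
                f"(need at least {self.min_beats} for stable index estimates)")
        symbols = quantize(increments(series), ActionSpace(self.resolution))
        if len(symbols) < 4:
            raise InsufficientDataError("too few beats after preprocessing")
        ent = entropy_profile(symbols, alphabet="full")
        frag = pattern_profile(symbols, mode=self.frag_mode)
        hrv = all_indices(series)
        return LandscapeResults(model=self, processed=series, symbols=symbols,
                                entropy=ent, fragmentation=frag, hrv=hrv)


@dataclass
class LandscapeResults:
    """Fitted index vector of one signal."""

    model: DynamicalLandscape
    processed: RRSeries
    symbols: object
    entropy: EntropyProfile
    fragmentation: FragmentationProfile
    hrv: HRVIndices

    def to_dict(self) -> dict:
        out = {"config": self.model.config(),
               "subject_id": self.processed.subject_id,
               "months_post_htx": self.processed.months_post_htx,
               "group": self.processed.group,
               "n_beats_analyzed": len(self.processed)}
        out.update({k: getattr(self.entropy, k) for k in ENTROPY_INDICES})
        out["n_windows"] = self.entropy.n_windows
        out.update({k: v for k, v in self.hrv.to_dict().items()})
        out.update({k: getattr(self.fragmentation, k) for k in FRAG_INDICES})
        out["pattern_coverage"] = (
            pattern_coverage(self.fragmentation)
            if self.fragmentation.mode == "zero-inclusive" else None)
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def row(self) -> dict:
        """Flat per-signal row for a cohort table."""
        d = self.to_dict()
        d.pop("config")
        d.pop("n_windows")
        return d

    def pair_distribution(self, alphabet: str = "full") -> pd.DataFrame:
        """Long-format joint distribution of consecutive action pairs.

        Columns ``label_i, label_j, probability`` — the input for
        two-action probability-density heatmaps.
        """
        dist = lgram_distribution(self.symbols, 2, alphabet)
        rows = [(i, j, p) for (i, j), p in sorted(dist.probs.items())]
        return pd.DataFrame(rows, columns=["label_i", "label_j", "probability"])

    def plot_pair_distribution(self, ax=None, log: bool = True):
        """Heatmap of the two-action distribution (requires matplotlib)."""
        import matplotlib.pyplot as plt
        df = self.pair_distribution("full")
        piv = df.pivot(index="label_j", columns="label_i", values="probability")
        piv = piv.sort_index(ascending=False)
        if ax is None:
            _, ax = plt.subplots()
        data = np.log10(piv.to_numpy() * 100.0) if log else piv.to_numpy() * 100.0
        im = ax.imshow(data, aspect="auto", origin="upper",
                       extent=[piv.columns.min(), piv.columns.max(),
                               piv.index.min(), piv.index.max()])
        ax.set_xlabel("first increment [ms]")
        ax.set_ylabel("second increment [ms]")
        ax.figure.colorbar(im, ax=ax,
                           label="log10 probability [%]" if log else "probability [%]")
        return ax

    def summary(self) -> str:
        e, f, h = self.entropy, self.fragmentation, self.hrv
        lines = [
            "Dynamical landscape summary",
            "=" * 46,
            f"beats analysed      {len(self.processed):>10d}",
            f"resolution eps      {self.model.resolution:>10.1f} ms",
            "-" * 46,
            f"H1                  {e.H1:>10.4f} nats",
            f"H2                  {e.H2:>10.4f} nats",
            f"H3                  {e.H3:>10.4f} nats",
            f"S_T (= H2 - H1)     {e.S_T:>10.4f} nats",
            f"sTE (= h3 - h2)     {e.sTE:>10.4f} nats",
            "-" * 46,
            f"PIP                 {f.PIP:>10.4f}",
            f"PSS                 {f.PSS:>10.4f}",
            f"PAS                 {f.PAS:>10.4f}",
            f"pattern coverage    {pattern_coverage(f):>10.4f}"
            if f.mode == "zero-inclusive" else
            f"mode                {f.mode:>10s}",
            "-" * 46,
            f"mean HR             {h.mean_HR:>10.2f} /min",
            f"SDNN                {h.SDNN:>10.2f} ms",
            f"RMSSD               {h.RMSSD:>10.2f} ms",
            f"pNN20               {h.pNN20:>10.3f} %",
            f"pNN50               {h.pNN50:>10.3f} %",
        ]
        if h.HF is not None:
            lines += [
                f"VLF                 {h.VLF:>10.2f} ms^2",
                f"LF                  {h.LF:>10.2f} ms^2",
                f"HF                  {h.HF:>10.2f} ms^2",
            ]
        return "\n".join(lines)


def build_cohort_table(results: list[LandscapeResults] | list[dict]
                       ) -> pd.DataFrame:
    """One row per signal, columns = metadata + every landscape index."""
    rows = [r.row() if isinstance(r, LandscapeResults) else dict(r)
            for r in results]
    return pd.DataFrame(rows)


class CohortTrend:
    """Cohort-level model over a per-signal profile table.

    Parameters
    ----------
    table : DataFrame
        One row per signal with ``subject_id``, ``months_post_htx``,
        ``group`` and index columns.
    indices : list of str, optional
        Index columns to analyse (defaults to every known landscape index
        present in the table).
    groups : pair of str
        The two arms compared (default F vs NF).
    """

    def __init__(self, table: pd.DataFrame, indices: list[str] | None = None,
                 groups: tuple[str, str] = ("F", "NF")):
        _cohort.validate_table(table)
        if indices is None:
            known = ENTROPY_INDICES + HRV_INDICES + FRAG_INDICES
            indices = [c for c in known if c in table.columns]
        _cohort.validate_table(table, indices)
        self.table = table.reset_index(drop=True)
        self.indices = indices
        self.groups = groups

    def fit(self, dependence_tests: bool = True) -> "CohortTrendResults":
        comparisons, regressions, equal_slopes = {}, {}, {}
        for index in self.indices:
            comparisons[index] = _cohort.compare_groups(
                self.table, index, self.groups)
            regressions[index] = {
                g: _cohort.regress_time(self.table, index, g)
                for g in self.groups}
            equal_slopes[index] = _cohort.equal_slopes_test(
                self.table, index, self.groups)
        dependence = None
        if dependence_tests and all(c in self.table.columns
                                    for c in ("H1", "H2", "H3", "S_T", "sTE")):
            dependence = _cohort.paired_dependence_tests(self.table, self.groups)
        return CohortTrendResults(model=self, comparisons=comparisons,
                                  regressions=regressions,
                                  equal_slopes=equal_slopes,
                                  dependence=dependence)


@dataclass
class CohortTrendResults:
    """Group comparisons, time trends and dependence tests per index."""

    model: CohortTrend
    comparisons: dict
    regressions: dict
    equal_slopes: dict
    dependence: list | None = None

    def to_frame(self) -> pd.DataFrame:
        """Descriptive-plus-regression table, one row per index."""
        g1, g2 = self.model.groups
        rows = []
        for index in self.model.indices:
            c = self.comparisons[index]
            r1, r2 = self.regressions[index][g1], self.regressions[index][g2]
            m1, q1lo, q1hi, _ = c.summaries[g1]
            m2, q2lo, q2hi, _ = c.summaries[g2]
            rows.append({
                "index": index,
                f"{g1}_median": m1, f"{g1}_q25": q1lo, f"{g1}_q75": q1hi,
                f"{g2}_median": m2, f"{g2}_q25": q2lo, f"{g2}_q75": q2hi,
                "group_p": c.p,
                f"{g1}_slope": r1.slope, f"{g1}_slope_se": r1.stderr,
                f"{g1}_R": r1.r, f"{g1}_slope_p": r1.p,
                f"{g2}_slope": r2.slope, f"{g2}_slope_se": r2.stderr,
                f"{g2}_R": r2.r, f"{g2}_slope_p": r2.p,
                "equal_slopes_p": self.equal_slopes[index].p,
            })
        return pd.DataFrame(rows)

    def classification_counts(self, features: list[str]) -> dict:
        return _cohort.classification_counts(self.model.table, features,
                                             self.model.groups)

    def loso(self, index: str, group: str):
        return _cohort.loso_slopes(self.model.table, index, group)

    def summary(self) -> str:
        g1, g2 = self.model.groups
        lines = ["Cohort dynamical-landscape trends",
                 "=" * 88,
                 f"{'index':<10}{g1 + ' median [IQR]':<26}{g2 + ' median [IQR]':<26}"
                 f"{'p':<8}{'slopes/yr (' + g1 + ', ' + g2 + ')':<18}"]
        for index in self.model.indices:
            c = self.comparisons[index]
            r1, r2 = self.regressions[index][g1], self.regressions[index][g2]
            m1, a1, b1, _ = c.summaries[g1]
            m2, a2, b2, _ = c.summaries[g2]
            lines.append(
                f"{index:<10}"
                f"{f'{m1:.3g} [{a1:.3g}, {b1:.3g}]':<26}"
                f"{f'{m2:.3g} [{a2:.3g}, {b2:.3g}]':<26}"
                f"{c.p:<8.3f}"
                f"{f'{r1.slope:+.3g}, {r2.slope:+.3g}':<18}")
        if self.dependence:
            lines.append("-" * 88)
            lines.append("dependence tests (per group):")
            for d in self.dependence:
                lines.append(f"  [{d.group}] {d.hypothesis:<10} "
                             f"{d.test_used:<12} p={d.p:.4g} (n={d.n})")
        return "\n".join(lines)
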