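"""Holter NN-interval editing and nocturnal segment selection.

The chain mirrors the signal-conditioning protocol for long nocturnal Holter
recordings:

1. :func:`edit_beats` — runs of fewer than five consecutive non-normal beats
   are substituted by the median of the last seven normal RR values; longer
   runs are deleted and the following beat is flagged as a gap boundary.
2. :func:`hour_quality_filter` — one-hour blocks (tiled from the recording
   start by cumulative RR time) whose pre-edit fraction of normal beats is
   below 95% are removed entirely.
3. :func:`select_nocturnal` — the analysed segment starts at the first beat
   of the one-hour block with the slowest mean heart rate and comprises the
   next 20,000 beats.

:func:`run` applies the three steps in order.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .io import RRSeries, NORMAL, EDITED

logger = logging.getLogger(__name__)

DEFAULT_MEDIAN_WINDOW = 7
DEFAULT_MAX_SUBSTITUTE_RUN = 4
DEFAULT_MIN_NORMAL_FRACTION = 0.95
DEFAULT_N_BEATS = 20_000


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, as (start, stop) half-open."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def edit_beats(series: RRSeries,
               median_window: int = DEFAULT_MEDIAN_WINDOW,
               max_substitute_run: int = DEFAULT_MAX_SUBSTITUTE_RUN) -> RRSeries:
    """Substitute short non-normal runs, delete long ones.

    A run of consecutive beats not labelled normal is *short* when its
    length is at most ``max_substitute_run`` (default 4, i.e. "fewer than 5
    values").  Each beat of a short run is replaced by the median of the
    ``median_window`` normal beats preceding the run and relabelled
    ``edited``; previously edited beats do not contribute to the median, so
    substituted values never cascade.  Longer runs — and short runs without
    enough preceding normal beats — are deleted, and the next surviving beat
    receives a gap-boundary flag.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    rr = series.rr.copy()
    labels = series.beat_label.copy()
    gap = series.gap.copy()
    keep = np.ones(len(series), dtype=bool)

    normal_idx = np.flatnonzero(series.is_normal)
    for start, stop in _runs(~series.is_normal):
        preceding = normal_idx[normal_idx < start]
        short = (stop - start) <= max_substitute_run
        if short and len(preceding) >= median_window:
            med = float(np.median(rr[preceding[-median_window:]]))
            rr[start:stop] = med
            labels[start:stop] = EDITED
        else:
            if short:
                logger.warning(
                    "run at beats %d-%d deleted: fewer than %d preceding normal beats",
                    start, stop - 1, median_window)
            keep[start:stop] = False
            if stop < len(series):
                gap[stop] = True

    out = replace(series, rr=rr, beat_label=labels, gap=gap, t=None,
                  meta=dict(series.meta))
    return out.take(keep)


def _hour_blocks(series: RRSeries) -> np.ndarray:
    """Index of the one-hour block each beat belongs to.

    Blocks are tiled from the recording start using cumulative RR time; the
    beat's own interval is taken to end at its cumulative time, so a beat
    belongs to the hour in which it starts.
    """
    t_end = series.cumulative_time_s()
    t_start = t_end - series.rr / 1000.0
    return np.floor(t_start / 3600.0).astype(int)


def hour_quality_filter(series: RRSeries,
                        min_normal_fraction: float = DEFAULT_MIN_NORMAL_FRACTION
                        ) -> RRSeries:
    """Remove one-hour blocks with a pre-edit normal fraction below threshold.

    The fraction counts beats labelled normal; edited beats were non-normal
    before substitution and therefore count against the block.  Removing a
    block sets a gap-boundary flag on the first retained beat after it.
    """
    if len(series) == 0:
        return series
    block = _hour_blocks(series)
    keep = np.ones(len(series), dtype=bool)
    for b in np.unique(block):
        in_block = block == b
        frac = np.mean(series.beat_label[in_block] == NORMAL)
        if frac < min_normal_fraction:
            keep[in_block] = False
    gap = series.gap.copy()
    removed = ~keep
    if removed.any():
        # flag the first kept beat following each removed stretch
        for start, stop in _runs(removed):
            nxt = np.flatnonzero(keep[stop:])
            if len(nxt):
                gap[stop + nxt[0]] = True
    out = replace(series, gap=gap, t=None, meta=dict(series.meta))
    return out.take(keep)


def select_nocturnal(series: RRSeries, n_beats: int = DEFAULT_N_BEATS) -> RRSeries:
    """Extract ``n_beats`` beats starting at the slowest-rhythm hour.

    Mean heart rate is computed per contiguous one-hour block (tiled by
    cumulative RR time); the selection starts at the first beat of the block
    with the minimum mean HR (ties broken toward the earliest block).  If
    fewer than ``n_beats`` beats remain from that point the series is
    truncated with a warning and ``meta['short_signal']`` is set.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if len(series) <= n_beats:
        # nothing to choose: the whole series is the analysed segment
        out = series.take(np.arange(len(series)))
        out.meta = dict(series.meta)
        if len(out) < n_beats:
            logger.warning("series has only %d beats (requested %d)",
                           len(out), n_beats)
            out.meta["short_signal"] = True
        return out
    block = _hour_blocks(series)
    uniq = np.unique(block)
    # mean HR per block: 60000 / mean RR; slowest rhythm = minimal HR
    mean_rr = np.array([series.rr[block == b].mean() for b in uniq])
    best = uniq[int(np.argmax(mean_rr))]
    start = int(np.flatnonzero(block == best)[0])
    out = series.take(np.arange(start, min(start + n_beats, len(series))))
    out.meta = dict(series.meta)
    if len(out) < n_beats:
        logger.warning("only %d beats available from the slowest hour (requested %d)",
                       len(out), n_beats)
        out.meta["short_signal"] = True
    # the selection boundary is a fresh start, not a deletion gap
    if len(out):
        out.gap[0] = False
    return out


def run(series: RRSeries,
        median_window: int = DEFAULT_MEDIAN_WINDOW,
        max_substitute_run: int = DEFAULT_MAX_SUBSTITUTE_RUN,
        min_normal_fraction: float = DEFAULT_MIN_NORMAL_FRACTION,
        n_beats: int = DEFAULT_N_BEATS) -> RRSeries:
    """Full preprocessing chain: edit → hour-quality filter → nocturnal select."""
    out = edit_beats(series, median_window, max_substitute_run)
    out = hour_quality_filter(out, min_normal_fraction)
    out = select_nocturnal(out, n_beats)
    return out
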