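"""Standard time- and frequency-domain HRV indices.

Time domain: mean heart rate (60000 / mean RR), SDNN (population standard
deviation of the RR intervals, ms), RMSSD (root mean square of successive
differences, ms), pNN20 and pNN50 (percentage of successive differences with
|dRR| strictly greater than 20 / 50 ms).

Frequency domain: the RR tachogram is interpolated onto an evenly sampled
grid (cubic spline, 4 Hz by default) and the power spectral density is
estimated by Welch's method (Hann window, 300-s segments, 50% overlap,
per-segment linear detrend).  Band powers in ms² are integrated over
VLF 0.003–0.04 Hz, LF 0.04–0.15 Hz and HF 0.15–0.40 Hz.  Increments across
gap boundaries are excluded from RMSSD/pNNx; the spectrum is estimated on
the longest contiguous valid stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import interpolate, signal

from .io import RRSeries
from .symbolize import increments, InsufficientDataError

BANDS = {"VLF": (0.003, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.40)}


@dataclass
class HRVIndices:
    """Standard HRV index vector (frequency fields None when not computed)."""

    mean_HR: float | None = None        # beats / min
    SDNN: float | None = None           # ms
    RMSSD: float | None = None          # ms
    pNN20: float | None = None          # percent
    pNN50: float | None = None          # percent
    VLF: float | None = None            # ms^2
    LF: float | None = None             # ms^2
    HF: float | None = None             # ms^2

    def to_dict(self) -> dict:
        return asdict(self)


def time_domain(series: RRSeries) -> HRVIndices:
    """Mean HR, SDNN, RMSSD, pNN20 and pNN50 of a series."""
    if len(series) < 2:
        raise InsufficientDataError("need at least 2 beats")
    rr = series.rr
    inc = increments(series)
    d = inc.drr[inc.valid_pair]
    if len(d) == 0:
        raise InsufficientDataError("no valid increments")
    return HRVIndices(
        mean_HR=60000.0 / float(np.mean(rr)),
        SDNN=float(np.std(rr)),
        RMSSD=float(np.sqrt(np.mean(d ** 2))),
        pNN20=float(np.mean(np.abs(d) > 20.0) * 100.0),
        pNN50=float(np.mean(np.abs(d) > 50.0) * 100.0),
    )


def _longest_valid_stretch(series: RRSeries) -> RRSeries:
    """Longest run of beats uninterrupted by gap boundaries."""
    if not series.gap.any():
        return series
    cut = np.flatnonzero(series.gap)
    bounds = np.concatenate(([0], cut, [len(series)]))
    lengths = np.diff(bounds)
    i = int(np.argmax(lengths))
    return series.take(np.arange(bounds[i], bounds[i + 1]))


def frequency_domain(series: RRSeries,
                     resample_hz: float = 4.0,
                     welch_segment_s: float = 300.0,
                     welch_overlap: float = 0.5) -> HRVIndices:
    """VLF, LF and HF band powers (ms²) of the RR tachogram."""
    seg = _longest_valid_stretch(series)
    if len(seg) < 4:
        raise InsufficientDataError("need at least 4 contiguous beats")
    t = seg.cumulative_time_s()
    duration = t[-1] - t[0]
    if duration < 300.0:
        raise InsufficientDataError(
            f"need at least 5 min of contiguous data, got {duration:.0f} s")
    spline = interpolate.CubicSpline(t, seg.rr)
    fs = resample_hz
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    x = spline(grid)
    nperseg = min(int(welch_segment_s * fs), len(x))
    freqs, psd = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * welch_overlap), detrend="linear")
    out = HRVIndices()
    for name, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & (freqs < hi)
        power = float(np.trapezoid(psd[sel], freqs[sel])) if sel.sum() > 1 else 0.0
        setattr(out, name, power)
    return out


def all_indices(series: RRSeries, **freq_kwargs) -> HRVIndices:
    """Time-domain indices, plus frequency-domain ones when enough data."""
    out = time_domain(series)
    try:
        fd = frequency_domain(series, **freq_kwargs)
    except InsufficientDataError:
        return out
    out.VLF, out.LF, out.HF = fd.VLF, fd.LF, fd.HF
    return out
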