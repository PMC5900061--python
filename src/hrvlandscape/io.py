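"""Reading and writing beat-annotated RR-interval series and cohort manifests.

Two delimited-text dialects are supported for RR files:

``single-column``
    one RR value in milliseconds per line, no header; every beat is assumed
    to be a normal sinus beat.
``csv-with-labels``
    CSV with header ``rr_ms,label[,t_s]``.  ``label`` is a single-character
    beat code: ``N`` normal, ``A`` artifact, ``V`` ectopic, ``E`` edited
    (median-substituted), ``G`` normal beat carrying a gap-boundary flag
    (the preceding beats were deleted), ``g`` edited beat carrying a
    gap-boundary flag.  ``t_s`` is optional cumulative time in seconds.

Cohort manifests are CSV files ``path,subject_id,months_post_htx,group``
with ``group`` one of ``F`` (progress free of complications), ``NF``
(progress not free of complications) or ``control``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

NORMAL = "N"
ARTIFACT = "A"
ECTOPIC = "V"
EDITED = "E"

VALID_LABELS = (NORMAL, ARTIFACT, ECTOPIC, EDITED)
VALID_GROUPS = ("F", "NF", "control")

#: on-disk code for (label, gap-flag) pairs that cannot be written verbatim
_GAP_CODE = {NORMAL: "G", EDITED: "g"}
_GAP_DECODE = {"G": NORMAL, "g": EDITED}


class RRParseError(ValueError):
    """Raised when an RR file or manifest cannot be parsed."""


class EmptyInputError(RRParseError):
    """Raised when an input file contains no beats."""


@dataclass
class RRSeries:
    """Ordered normal-to-normal RR intervals in milliseconds.

    Parameters
    ----------
    rr : ndarray of float
        RR intervals in ms; all strictly positive.
    beat_label : ndarray of str
        Per-beat single-character code from ``{N, A, V, E}``.
    gap : ndarray of bool
        True on a beat that immediately follows a deleted segment; the
        increment into such a beat is not a physiological pair.
    t : ndarray of float, optional
        Cumulative time in seconds (strictly increasing) if known.
    subject_id, months_post_htx, group :
        Cohort metadata; ``group`` is one of F / NF / control / unknown.
    meta : dict
        Free-form provenance (e.g. ``short_signal`` flag after truncation).
    """

    rr: np.ndarray
    beat_label: np.ndarray | None = None
    gap: np.ndarray | None = None
    t: np.ndarray | None = None
    subject_id: str = ""
    months_post_htx: float = float("nan")
    group: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1:
            raise ValueError("rr must be one-dimensional")
        if len(self.rr) and np.nanmin(self.rr) <= 0:
            raise ValueError("all RR intervals must be positive")
        if self.beat_label is None:
            self.beat_label = np.full(len(self.rr), NORMAL, dtype="<U1")
        else:
            self.beat_label = np.asarray(self.beat_label, dtype="<U1")
        if self.gap is None:
            self.gap = np.zeros(len(self.rr), dtype=bool)
        else:
            self.gap = np.asarray(self.gap, dtype=bool)
        if len(self.beat_label) != len(self.rr) or len(self.gap) != len(self.rr):
            raise ValueError("beat_label/gap must match rr in length")
        bad = set(np.unique(self.beat_label)) - set(VALID_LABELS)
        if len(self.rr) and bad:
            raise ValueError(f"unknown beat labels: {sorted(bad)}")
        if self.t is not None:
            self.t = np.asarray(self.t, dtype=float)
            if len(self.t) != len(self.rr):
                raise ValueError("t must match rr in length")
            if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
                raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rr)

    @property
    def is_normal(self) -> np.ndarray:
        """Boolean mask of beats labelled normal (edited beats excluded)."""
        return self.beat_label == NORMAL

    @property
    def is_clean(self) -> np.ndarray:
        """Beats usable for analysis: normal or edited."""
        return (self.beat_label == NORMAL) | (self.beat_label == EDITED)

    def cumulative_time_s(self) -> np.ndarray:
        """Cumulative time at the *end* of each beat, seconds from start."""
        return np.cumsum(self.rr) / 1000.0

    def take(self, index: np.ndarray) -> "RRSeries":
        """Subset by boolean mask or integer index, keeping metadata."""
        return replace(
            self,
            rr=self.rr[index],
            beat_label=self.beat_label[index],
            gap=self.gap[index],
            t=self.t[index] if self.t is not None else None,
            meta=dict(self.meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RRSeries):
            return NotImplemented
        return (
            np.array_equal(self.rr, other.rr)
            and np.array_equal(self.beat_label, other.beat_label)
            and np.array_equal(self.gap, other.gap)
        )


@dataclass
class ManifestEntry:
    path: str
    subject_id: str
    months_post_htx: float
    group: str


@dataclass
class CohortManifest:
    """Listing of RR files with subject, time-after-surgery and group."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterable[ManifestEntry]:
        return iter(self.entries)


def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise RRParseError(f"{path}:{lineno}: not a number: {token!r}") from None


def read_rr(path: str | os.PathLike, dialect: str = "auto") -> RRSeries:
    """Read an RR series from a delimited-text file.

    ``dialect`` is ``single-column``, ``csv-with-labels`` or ``auto``
    (sniffed from the first line).  Unlabelled input defaults every beat
    to normal.
    """
    path = os.fspath(path)
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln]
    if dialect == "auto":
        dialect = "csv-with-labels" if lines and ("," in lines[0][1] or
                                                  lines[0][1].startswith("rr")) else "single-column"
    rr: list[float] = []
    labels: list[str] = []
    gap: list[bool] = []
    t: list[float] = []
    for lineno, ln in lines:
        if dialect == "csv-with-labels" and ln.lower().startswith("rr"):
            continue  # header
        parts = [p.strip() for p in ln.split(",")] if dialect == "csv-with-labels" else [ln]
        value = _parse_float(parts[0], path, lineno)
        if value <= 0:
            raise RRParseError(f"{path}:{lineno}: non-positive RR interval {value}")
        rr.append(value)
        code = parts[1] if len(parts) > 1 and parts[1] else NORMAL
        if code in _GAP_DECODE:
            labels.append(_GAP_DECODE[code])
            gap.append(True)
        elif code in VALID_LABELS:
            labels.append(code)
            gap.append(False)
        else:
            raise RRParseError(
                f"{path}:{lineno}: unknown beat label {code!r} "
                f"(expected one of {VALID_LABELS + tuple(_GAP_DECODE)})")
        if len(parts) > 2 and parts[2]:
            t.append(_parse_float(parts[2], path, lineno))
    if not rr:
        raise EmptyInputError(f"{path}: no beats found")
    return RRSeries(
        rr=np.array(rr),
        beat_label=np.array(labels),
        gap=np.array(gap),
        t=np.array(t) if len(t) == len(rr) else None,
    )


def write_rr(series: RRSeries, path: str | os.PathLike) -> None:
    """Write a series in the ``csv-with-labels`` dialect (round-trips read_rr)."""
    path = os.fspath(path)
    with_t = series.t is not None
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rr_ms,label,t_s\n" if with_t else "rr_ms,label\n")
        for i in range(len(series)):
            label = series.beat_label[i]
            code = _GAP_CODE.get(label, label) if series.gap[i] else label
            row = f"{series.rr[i]:g},{code}"
            if with_t:
                row += f",{series.t[i]:g}"
            fh.write(row + "\n")


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read a cohort manifest CSV ``path,subject_id,months_post_htx,group``."""
    path = os.fspath(path)
    entries: list[ManifestEntry] = []
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.lower().startswith("path"):
                continue
            parts = [p.strip() for p in ln.split(",")]
            if len(parts) < 4:
                raise RRParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            fpath, subject, months_s, group = parts[:4]
            if not subject:
                raise RRParseError(f"{path}:{lineno}: empty subject_id")
            months = _parse_float(months_s, path, lineno)
            if months < 0:
                raise RRParseError(f"{path}:{lineno}: months_post_htx must be >= 0")
            if group not in VALID_GROUPS:
                raise RRParseError(
                    f"{path}:{lineno}: unknown group {group!r} "
                    f"(allowed: {', '.join(VALID_GROUPS)})")
            entries.append(ManifestEntry(fpath, subject, months, group))
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write("path,subject_id,months_post_htx,group\n")
        for e in manifest.entries:
            fh.write(f"{e.path},{e.subject_id},{e.months_post_htx:g},{e.group}\n")
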