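"""Breath-by-breath preprocessing for six-minute walk test (6MWT) sessions.

A portable metabolic cart records one row per breath (VO2, VCO2, heart rate,
SpO2, tidal volume, respiratory rate).  Before curve fitting, the walk-phase
VO2 is averaged over consecutive fixed-width windows (default 20 s), and the
resting VO2 is estimated from the last stable segment of the seated rest
phase.  This module defines the two in-memory containers (`BreathSeries`,
`WindowedSeries`), the breath CSV dialect, and those two preprocessing steps.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd

__all__ = [
    "BREATH_COLUMNS",
    "BreathSeries",
    "WindowedSeries",
    "BreathTableError",
    "UnstableRestError",
    "read_breath_table",
    "write_breath_table",
    "estimate_rest_vo2",
    "window_average",
]

#: Column order of the breath CSV dialect.  One row per breath; times are
#: seconds since session start; VO2/VCO2 in ml/min; VT in litres.
BREATH_COLUMNS = (
    "time_s",
    "vo2_mlmin",
    "vco2_mlmin",
    "hr_bpm",
    "spo2_pct",
    "vt_l",
    "rr_brpm",
)

#: Marker keys carried as ``#key=value`` comment lines above the header.
MARKER_KEYS = ("rest_start_s", "walk_start_s", "walk_end_s")


class BreathTableError(ValueError):
    """Raised when a breath table violates the dialect or its invariants."""


class UnstableRestError(RuntimeError):
    """Raised when no stable resting segment can be found."""


@dataclass
class BreathSeries:
    """One 6MWT session: per-breath records plus phase markers.

    ``data`` holds one row per breath with the columns in
    :data:`BREATH_COLUMNS`.  Markers delimit the seated rest phase and the
    six-minute walk; the recovery phase is whatever follows ``walk_end_s``.
    """

    data: pd.DataFrame
    rest_start_s: float
    walk_start_s: float
    walk_end_s: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in BREATH_COLUMNS if c not in self.data.columns]
        if missing:
            raise BreathTableError(f"missing breath columns: {missing}")
        t = self.data["time_s"].to_numpy(dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise BreathTableError("breath times must be strictly increasing")
        if not (self.rest_start_s <= self.walk_start_s < self.walk_end_s):
            raise BreathTableError(
                "markers must satisfy rest_start_s <= walk_start_s < walk_end_s"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def walk_duration_s(self) -> float:
        return self.walk_end_s - self.walk_start_s

    def phase(self, name: str) -> pd.DataFrame:
        """Rows belonging to a phase: 'rest', 'walk' or 'recovery'."""
        t = self.data["time_s"]
        if name == "rest":
            mask = (t >= self.rest_start_s) & (t < self.walk_start_s)
        elif name == "walk":
            mask = (t >= self.walk_start_s) & (t < self.walk_end_s)
        elif name == "recovery":
            mask = t >= self.walk_end_s
        else:
            raise ValueError(f"unknown phase {name!r}")
        return self.data.loc[mask]


@dataclass
class WindowedSeries:
    """Fixed-width window means of walk-phase VO2 — the fitting substrate.

    Midpoints are seconds since walk onset.  Windows are contiguous,
    half-open ``[k*w, (k+1)*w)``, anchored at walk onset; empty windows are
    dropped (``n_dropped`` counts them) and a trailing partial window is kept
    when it holds at least one breath.
    """

    midpoint_s: np.ndarray
    vo2_mlmin: np.ndarray
    width_s: float
    n_breaths: np.ndarray
    n_dropped: int = 0
    usable: bool = True

    def __post_init__(self) -> None:
        self.midpoint_s = np.asarray(self.midpoint_s, dtype=float)
        self.vo2_mlmin = np.asarray(self.vo2_mlmin, dtype=float)
        self.n_breaths = np.asarray(self.n_breaths, dtype=int)

    def __len__(self) -> int:
        return len(self.midpoint_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "midpoint_s": self.midpoint_s,
                "vo2_mlmin": self.vo2_mlmin,
                "n_breaths": self.n_breaths,
            }
        )


Source = Union[str, Path, IO[str]]


def write_breath_table(series: BreathSeries, dest: Source) -> None:
    """Write a session in the breath CSV dialect.

    Comment lines ``#key=value`` carry the phase markers (and the subject id
    when set), followed by a normal CSV header and one row per breath.
    """
    buf = io.StringIO()
    if series.subject_id:
        buf.write(f"#subject_id={series.subject_id}\n")
    buf.write(f"#rest_start_s={series.rest_start_s:g}\n")
    buf.write(f"#walk_start_s={series.walk_start_s:g}\n")
    buf.write(f"#walk_end_s={series.walk_end_s:g}\n")
    series.data.loc[:, list(BREATH_COLUMNS)].to_csv(buf, index=False)
    text = buf.getvalue()
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")


def read_breath_table(source: Source) -> BreathSeries:
    """Read one session from the breath CSV dialect.

    Raises :class:`BreathTableError` naming the problem when columns are
    missing, breath times are non-monotone, or phase markers are absent.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise BreathTableError("empty breath table")
    missing_markers = [k for k in MARKER_KEYS if k not in meta]
    if missing_markers:
        raise BreathTableError(f"missing markers: {missing_markers}")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    missing = [c for c in BREATH_COLUMNS if c not in df.columns]
    if missing:
        raise BreathTableError(f"missing breath columns: {missing}")
    return BreathSeries(
        data=df,
        rest_start_s=float(meta["rest_start_s"]),
        walk_start_s=float(meta["walk_start_s"]),
        walk_end_s=float(meta["walk_end_s"]),
        subject_id=meta.get("subject_id", ""),
    )


def estimate_rest_vo2(
    series: BreathSeries,
    window_s: float = 60.0,
    cv_threshold: float = 0.10,
) -> float:
    """Mean VO2 over the last stable segment of the seated rest phase.

    Stability: a rolling ``window_s`` segment whose VO2 coefficient of
    variation is below ``cv_threshold`` (default 10%).  The mean of the last
    such segment is returned; the rolling origin steps breath by breath.

    Raises ``ValueError`` when the rest phase is shorter than ``window_s``
    and :class:`UnstableRestError` when no segment qualifies (callers may
    fall back to the plain final-``window_s`` mean with a warning).
    """
    rest = series.phase("rest")
    t = rest["time_s"].to_numpy(dtype=float)
    v = rest["vo2_mlmin"].to_numpy(dtype=float)
    if len(t) == 0 or t[-1] - t[0] < window_s:
        raise ValueError(
            f"rest phase must span at least {window_s:g} s of breaths"
        )
    last_mean = None
    for i in range(len(t)):
        if t[i] + window_s > t[-1]:
            break  # remaining span shorter than one full window
        j = int(np.searchsorted(t, t[i] + window_s, side="right"))
        seg = v[i:j]
        m = float(np.mean(seg))
        if m > 0 and float(np.std(seg, ddof=0)) / m < cv_threshold:
            last_mean = m
    if last_mean is None:
        raise UnstableRestError("no stable 60 s rest segment (rolling CV >= threshold)")
    return last_mean


def window_average(
    series: BreathSeries,
    width_s: float = 20.0,
    max_empty_frac: float = 0.20,
) -> WindowedSeries:
    """Average walk-phase VO2 over consecutive ``width_s`` windows.

    Windows are anchored at walk onset (t=0): window ``k`` covers
    ``[k*width_s, (k+1)*width_s)`` and is summarised by the plain mean of the
    breaths falling in it, placed at midpoint ``(k+0.5)*width_s``.  A trailing
    partial window is retained if it holds a breath.  Empty windows are
    dropped with a warning; if more than ``max_empty_frac`` of windows are
    empty the result is flagged unusable.
    """
    if width_s <= 0:
        raise ValueError("width_s must be positive")
    walk = series.phase("walk")
    if len(walk) == 0:
        raise ValueError("no walk-phase breaths")
    t = walk["time_s"].to_numpy(dtype=float) - series.walk_start_s
    v = walk["vo2_mlmin"].to_numpy(dtype=float)
    # tolerate float jitter in the markers so e.g. a 360.0000001 s walk
    # still yields 18 twenty-second windows
    n_windows = int(np.ceil(series.walk_duration_s / width_s - 1e-9))
    idx = np.minimum(np.floor(t / width_s).astype(int), n_windows - 1)
    mids, means, counts = [], [], []
    n_dropped = 0
    for k in range(n_windows):
        sel = idx == k
        n = int(np.count_nonzero(sel))
        if n == 0:
            n_dropped += 1
            continue
        mids.append((k + 0.5) * width_s)
        means.append(float(np.mean(v[sel])))
        counts.append(n)
    if n_dropped:
        warnings.warn(f"{n_dropped} empty window(s) dropped", stacklevel=2)
    usable = n_dropped <= max_empty_frac * n_windows
    return WindowedSeries(
        midpoint_s=np.array(mids),
        vo2_mlmin=np.array(means),
        width_s=float(width_s),
        n_breaths=np.array(counts, dtype=int),
        n_dropped=n_dropped,
        usable=usable,
    )
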