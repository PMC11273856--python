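"""Event-anchored RR-interval windowing and short-term HRV metrics.

RR intervals are the times (ms) between consecutive R waves of the ECG.  For
each OCT acquisition the 20 s of RR data preceding the acquisition's end are
windowed out and reduced to two metrics: mean heart rate (bpm) and RMSSD, the
root mean square of successive RR differences — a standard short-term index of
cardiac parasympathetic activity.

Mean HR uses the time-weighted convention ``60000 * n / sum(rr)`` (equivalent
to 60000 over the mean RR interval), not the mean of instantaneous per-beat
rates; the two differ for variable rhythms and the time-weighted form is the
stable choice for short windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RRSeries",
    "HRVMetrics",
    "window_rr",
    "mean_hr",
    "rmssd",
    "session_metrics",
    "load_rr_export",
    "save_rr_export",
]


@dataclass
class RRSeries:
    """Ordered RR intervals (ms) with cumulative end-times and event markers.

    ``t_end_ms[i]`` is the cumulative time at which beat ``i`` ends, taking the
    start of the recording as time 0.  ``events`` maps labels (e.g.
    ``"baseline_scan1"``) to OCT-acquisition end times in ms.
    """

    rr_ms: np.ndarray
    events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=np.float64)
        if self.rr_ms.ndim != 1 or self.rr_ms.size == 0:
            raise ValueError("rr_ms must be a nonempty 1D sequence")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")
        span = float(self.rr_ms.sum())
        for label, t in self.events.items():
            if not (0 <= t <= span):
                raise ValueError(f"event {label!r} at {t} ms lies outside the recording span {span} ms")

    @property
    def t_end_ms(self) -> np.ndarray:
        """Cumulative beat end-times (ms)."""
        return np.cumsum(self.rr_ms)

    @property
    def duration_ms(self) -> float:
        return float(self.rr_ms.sum())


@dataclass
class HRVMetrics:
    """Mean HR and RMSSD over one analysis window."""

    mean_hr_bpm: float
    rmssd_ms: float
    n_beats: int
    window_ms: tuple[float, float]


def window_rr(series: RRSeries, event_ms: float, window_s: float = 20.0) -> np.ndarray:
    """Beats whose end-time lies in ``(event_ms - window, event_ms]``.

    The boundary beat is included when its end-time equals the event time.
    Raises ``ValueError`` when the event lies outside the recording, and
    flags windows with fewer than 2 beats (RMSSD needs a difference).
    """
    if not (0 <= event_ms <= series.duration_ms):
        raise ValueError("event lies outside the recording")
    t_end = series.t_end_ms
    lo = event_ms - window_s * 1000.0
    sel = (t_end > lo) & (t_end <= event_ms)
    subset = series.rr_ms[sel]
    if subset.size < 2:
        raise ValueError("insufficient data: fewer than 2 beats in window")
    return subset


def mean_hr(rr_ms: np.ndarray) -> float:
    """Time-weighted mean heart rate in bpm: ``60000 * n / sum(rr)``."""
    rr_ms = np.asarray(rr_ms, dtype=np.float64)
    if rr_ms.size == 0:
        raise ValueError("empty RR subset")
    return 60000.0 * rr_ms.size / float(rr_ms.sum())


def rmssd(rr_ms: np.ndarray) -> float:
    """Root mean square of successive RR differences (ms)."""
    rr_ms = np.asarray(rr_ms, dtype=np.float64)
    if rr_ms.size < 2:
        raise ValueError("RMSSD needs at least 2 beats")
    d = np.diff(rr_ms)
    return float(np.sqrt(np.mean(d * d)))


def session_metrics(series: RRSeries, event_ms: float, window_s: float = 20.0) -> HRVMetrics:
    """Window the series at one acquisition-end event and compute both metrics."""
    subset = window_rr(series, event_ms, window_s)
    return HRVMetrics(
        mean_hr_bpm=mean_hr(subset),
        rmssd_ms=rmssd(subset),
        n_beats=int(subset.size),
        window_ms=(event_ms - window_s * 1000.0, event_ms),
    )


def median_filter_beats(rr_ms: np.ndarray, window: int = 5, threshold: float = 0.2) -> np.ndarray:
    """Optional ectopic-beat rejection: drop beats deviating from a running
    median by more than ``threshold`` (fractional).  Off by default in the
    pipeline — the study design applies no artifact filtering.
    """
    from scipy.ndimage import median_filter

    rr_ms = np.asarray(rr_ms, dtype=np.float64)
    med = median_filter(rr_ms, size=window, mode="nearest")
    keep = np.abs(rr_ms - med) <= threshold * med
    return rr_ms[keep]


def save_rr_export(series: RRSeries, rr_path: str | Path, events_path: str | Path | None = None) -> None:
    """Write the plain-text export dialect: one RR (ms) per line, JSON event sidecar."""
    rr_path = Path(rr_path)
    rr_path.write_text("".join(f"{v:.0f}\n" for v in series.rr_ms))
    if events_path is None:
        events_path = rr_path.with_suffix(".events.json")
    Path(events_path).write_text(json.dumps(series.events, indent=2))


def load_rr_export(rr_path: str | Path, events_path: str | Path | None = None) -> RRSeries:
    """Read a plain-text RR export (one ms value per line) plus its JSON event sidecar."""
    rr_path = Path(rr_path)
    rr = np.array([float(line) for line in rr_path.read_text().split()], dtype=np.float64)
    events: dict[str, float] = {}
    if events_path is None:
        candidate = rr_path.with_suffix(".events.json")
        events_path = candidate if candidate.exists() else None
    if events_path is not None:
        events = {k: float(v) for k, v in json.loads(Path(events_path).read_text()).items()}
    return RRSeries(rr, events)
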