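"""Two-channel fibre-photometry processing.

The 470-nm channel carries the calcium-dependent signal; the 410-nm channel
is a calcium-independent (isosbestic) reference that shares motion artifact
and photobleaching with the signal channel.  dF/F is computed against a
baseline F predicted from the reference: a least-squares line is fitted
mapping f410 -> f470 over the whole recording, and

    dF/F(t) = (f470(t) - Fhat(t)) / Fhat(t),   Fhat = slope * f410 + intercept.

Peri-event analysis extracts dF/F segments on a shared relative-time grid
around event times (feeding onsets or state-transition times), then reports
the event-average trace with s.e.m., the trapezoidal area under the curve
(AUC, dF/F*s) and the signed peak dF/F (percent).  Default windows are
(-20, +10) s around feeding onsets and (-10, +10) s around state
transitions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhotometryTrace",
    "DffSeries",
    "AnalysisWindow",
    "PeriEventMatrix",
    "PeriEventSummary",
    "FEEDING_WINDOW",
    "STATE_TRANSITION_WINDOW",
    "fit_reference",
    "compute_dff",
    "extract_peri_event",
    "auc",
    "peak_dff",
    "peri_event_average",
    "read_trace",
    "write_trace",
]


@dataclass
class PhotometryTrace:
    """Uniformly sampled two-channel recording (arbitrary fluorescence units)."""

    t_s: np.ndarray
    f470: np.ndarray
    f410: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.f470 = np.asarray(self.f470, dtype=float)
        self.f410 = np.asarray(self.f410, dtype=float)
        if not (len(self.t_s) == len(self.f470) == len(self.f410)):
            raise ValueError("channels must share a length")
        if len(self.t_s) > 1 and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.t_s)


@dataclass
class DffSeries:
    t_s: np.ndarray
    dff: np.ndarray
    fit: tuple[float, float]  # (slope, intercept) of the reference fit
    rate_hz: float

    def __len__(self) -> int:
        return len(self.t_s)


@dataclass(frozen=True)
class AnalysisWindow:
    """Event-relative analysis window in seconds (start < end)."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("window start must precede end")

    @property
    def span_s(self) -> float:
        return self.end_s - self.start_s


FEEDING_WINDOW = AnalysisWindow(-20.0, 10.0)
STATE_TRANSITION_WINDOW = AnalysisWindow(-10.0, 10.0)


@dataclass
class PeriEventMatrix:
    """dF/F segments (one row per retained event) on a shared relative grid."""

    rel_time_s: np.ndarray
    data: np.ndarray  # (n_events, n_samples)
    event_times_s: np.ndarray
    n_dropped: int = 0

    @property
    def n_events(self) -> int:
        return self.data.shape[0]


@dataclass
class PeriEventSummary:
    rel_time_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    auc_per_event: np.ndarray  # dF/F * s
    peak_pct_per_event: np.ndarray  # percent


def fit_reference(trace: PhotometryTrace) -> tuple[float, float]:
    """Least-squares line mapping the 410 reference onto the 470 signal."""
    if len(trace) < 3:
        raise ValueError("need at least 3 samples to fit the reference")
    if np.ptp(trace.f410) == 0:
        raise ValueError(
            "constant 410 reference; use compute_dff(..., method='ratio') "
            "for a mean-ratio baseline instead"
        )
    res = stats.linregress(trace.f410, trace.f470)
    return float(res.slope), float(res.intercept)


def compute_dff(trace: PhotometryTrace, method: str = "regression") -> DffSeries:
    """dF/F against the reference-predicted baseline.

    ``method='regression'`` (default) predicts F from the fitted 410->470
    line; ``method='ratio'`` scales the 410 channel by mean(f470)/mean(f410),
    a fallback for recordings whose reference carries no variance.
    """
    if method == "regression":
        slope, intercept = fit_reference(trace)
        fhat = slope * trace.f410 + intercept
    elif method == "ratio":
        if np.mean(trace.f410) == 0:
            raise ValueError("zero-mean reference channel")
        slope = float(np.mean(trace.f470) / np.mean(trace.f410))
        intercept = 0.0
        fhat = slope * trace.f410
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    if np.any(fhat <= 0):
        raise ValueError("fitted baseline is not strictly positive")
    dff = (trace.f470 - fhat) / fhat
    return DffSeries(t_s=trace.t_s, dff=dff, fit=(slope, intercept), rate_hz=trace.rate_hz)


def extract_peri_event(
    dff: DffSeries, event_times_s, window: AnalysisWindow
) -> PeriEventMatrix:
    """Align dF/F segments to events on a shared relative-time grid.

    Alignment is to the nearest sample (no interpolation).  Events whose full
    window does not fit inside the recording are dropped and counted in
    ``n_dropped``; extracting zero events is an error.
    """
    events = np.atleast_1d(np.asarray(event_times_s, dtype=float))
    if len(events) == 0:
        raise ValueError("no events supplied")
    rate = dff.rate_hz
    lo = int(round(window.start_s * rate))
    hi = int(round(window.end_s * rate))
    offsets = np.arange(lo, hi + 1)
    rel_time = offsets / rate
    rows, kept = [], []
    n = len(dff.t_s)
    for ev in events:
        center = int(np.argmin(np.abs(dff.t_s - ev)))
        if center + lo < 0 or center + hi >= n:
            continue
        rows.append(dff.dff[center + offsets])
        kept.append(ev)
    if not rows:
        raise ValueError("no events with a full window inside the recording")
    return PeriEventMatrix(
        rel_time_s=rel_time,
        data=np.vstack(rows),
        event_times_s=np.asarray(kept),
        n_dropped=len(events) - len(rows),
    )


def _window_mask(rel_time: np.ndarray, window: AnalysisWindow) -> np.ndarray:
    eps = 1e-9
    if rel_time[0] > window.start_s + eps or rel_time[-1] < window.end_s - eps:
        raise ValueError("trace grid does not cover the analysis window")
    return (rel_time >= window.start_s - eps) & (rel_time <= window.end_s + eps)


def auc(values: np.ndarray, rel_time: np.ndarray, window: AnalysisWindow) -> float:
    """Trapezoidal integral of dF/F over the window (dF/F * s)."""
    values = np.asarray(values, dtype=float)
    rel_time = np.asarray(rel_time, dtype=float)
    m = _window_mask(rel_time, window)
    return float(np.trapezoid(values[m], rel_time[m]))


def peak_dff(values: np.ndarray, rel_time: np.ndarray, window: AnalysisWindow) -> float:
    """Signed maximum dF/F within the window, as a percentage."""
    values = np.asarray(values, dtype=float)
    rel_time = np.asarray(rel_time, dtype=float)
    m = _window_mask(rel_time, window)
    return float(100.0 * np.max(values[m]))


def peri_event_average(
    matrix: PeriEventMatrix, window: AnalysisWindow | None = None
) -> PeriEventSummary:
    """Event-average trace with s.e.m., plus per-event AUC and peak."""
    if matrix.n_events < 1:
        raise ValueError("empty peri-event matrix")
    if window is None:
        window = AnalysisWindow(matrix.rel_time_s[0], matrix.rel_time_s[-1])
    mean = matrix.data.mean(axis=0)
    if matrix.n_events > 1:
        sem = matrix.data.std(axis=0, ddof=1) / np.sqrt(matrix.n_events)
    else:
        sem = np.zeros_like(mean)
    aucs = np.array([auc(r, matrix.rel_time_s, window) for r in matrix.data])
    peaks = np.array([peak_dff(r, matrix.rel_time_s, window) for r in matrix.data])
    return PeriEventSummary(
        rel_time_s=matrix.rel_time_s,
        mean=mean,
        sem=sem,
        auc_per_event=aucs,
        peak_pct_per_event=peaks,
    )


def read_trace(path) -> PhotometryTrace:
    """Read a `time_s,f470,f410` CSV with a ``# rate_hz=`` comment."""
    rate = None
    body = io.StringIO()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("rate_hz="):
                    rate = float(stripped.split("=", 1)[1])
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, float_precision="round_trip")
    t = df["time_s"].to_numpy(dtype=float)
    if rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from one sample")
        rate = 1.0 / float(np.median(np.diff(t)))
    return PhotometryTrace(
        t_s=t,
        f470=df["f470"].to_numpy(dtype=float),
        f410=df["f410"].to_numpy(dtype=float),
        rate_hz=rate,
    )


def write_trace(trace: PhotometryTrace, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# rate_hz={float(trace.rate_hz)!r}\n")
        fh.write("time_s,f470,f410\n")
        for t, a, b in zip(trace.t_s, trace.f470, trace.f410):
            # repr gives the shortest exact representation => lossless round trip
            fh.write(f"{float(t)!r},{float(a)!r},{float(b)!r}\n")
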