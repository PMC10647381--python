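"""Time-domain and Poincaré HRV parameters over sliding windows.

Scalar parameters (all on NN intervals, in ms unless noted):

* SDNN — sample standard deviation of all NN intervals,
* SDANN — sample sd of the mean NN per 5-min bin,
* ASDNN — mean of the sample sd of NN per 5-min bin,
* RMSSD — root mean square of successive NN differences,
* NN50 / pNN50 — count / percentage of successive differences > 50 ms,
* SD1, SD2 — Poincaré ellipse axes via the standard identities
  sd1 = rmssd/sqrt(2) and sd2^2 = 2*sdnn^2 - sd1^2.

Two aggregation methods combine the clean NN segments of a window:

* Average (A) — each parameter is the unweighted mean of the per-segment
  values (SDANN/ASDNN are computed on the window's 5-min partition of all
  accepted intervals, since segments may be shorter than 5 min).
* Combined (C) — parameters are computed once on the concatenation of all
  segment intervals; successive-difference statistics never take a
  difference across a segment junction.

Sample (n-1 divisor) standard deviations are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import RRSeries
from .nn_cleaning import CleaningConfig, NNSegment, extract_nn_segments

MS_PER_MIN = 60_000.0


class UndefinedHRV(ValueError):
    """Raised when a parameter is requested on too little data."""


# ---------------------------------------------------------------------------
# scalar parameters
# ---------------------------------------------------------------------------

def sdnn(nn: Sequence[float]) -> float:
    """Sample standard deviation of the NN intervals (ms)."""
    if len(nn) < 2:
        raise UndefinedHRV("SDNN needs at least 2 intervals")
    return float(np.std(nn, ddof=1))


def _succ_diffs(nn: Sequence[float]) -> np.ndarray:
    if len(nn) < 2:
        raise UndefinedHRV("successive differences need at least 2 intervals")
    return np.diff(np.asarray(nn, dtype=float))


def rmssd(nn: Sequence[float]) -> float:
    """Root mean square of successive NN differences (ms)."""
    d = _succ_diffs(nn)
    return float(np.sqrt(np.mean(d * d)))


def nn50(nn: Sequence[float]) -> int:
    """Number of successive-interval pairs differing by more than 50 ms."""
    return int(np.sum(np.abs(_succ_diffs(nn)) > 50.0))


def pnn50(nn: Sequence[float]) -> float:
    """Percentage of successive pairs differing by more than 50 ms."""
    d = _succ_diffs(nn)
    return 100.0 * float(np.sum(np.abs(d) > 50.0)) / d.size


def poincare(nn: Sequence[float]) -> tuple[float, float, float | None]:
    """Poincaré (SD1, SD2, SD1/SD2); the ratio is None when SD2 is 0."""
    s = sdnn(nn)
    sd1 = rmssd(nn) / math.sqrt(2.0)
    sd2 = math.sqrt(max(0.0, 2.0 * s * s - sd1 * sd1))
    ratio = sd1 / sd2 if sd2 > 0 else None
    return sd1, sd2, ratio


def sdann_asdnn(
    intervals: Iterable[tuple[float, float]],
    window_start_ms: float,
    bin_min: float = 5.0,
) -> tuple[float, float]:
    """SDANN and ASDNN from (onset_ms, rr_ms) pairs inside one window.

    The window is partitioned into contiguous ``bin_min``-minute bins by
    interval onset; bins with fewer than 2 intervals are skipped, and at
    least 2 qualifying bins are required.
    """
    pairs = list(intervals)
    if not pairs:
        raise UndefinedHRV("no intervals for SDANN/ASDNN")
    bin_ms = bin_min * MS_PER_MIN
    bins: dict[int, list[float]] = {}
    for onset, rr in pairs:
        bins.setdefault(int((onset - window_start_ms) // bin_ms), []).append(rr)
    means = []
    sds = []
    for _, vals in sorted(bins.items()):
        if len(vals) < 2:
            continue
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)))
    if len(means) < 2:
        raise UndefinedHRV("SDANN/ASDNN need at least 2 qualifying 5-min bins")
    return float(np.std(means, ddof=1)), float(np.mean(sds))


# ---------------------------------------------------------------------------
# window specification
# ---------------------------------------------------------------------------

STANDARD_WINDOWS_MIN = (30, 120, 480, 1440)


def duration_class(w_min: float) -> str:
    """short (<= 30 min), medium (30 min, 8 h], long (8 h, 24 h]."""
    if w_min <= 30:
        return "short"
    if w_min <= 480:
        return "medium"
    return "long"


def default_slide_min(w_min: float) -> int:
    """Sliding offset: 5 min for short/medium windows, 10 min for long."""
    return 10 if duration_class(w_min) == "long" else 5


@dataclass(frozen=True)
class WindowSpec:
    w_min: int
    s_min: int | None = None

    def __post_init__(self) -> None:
        if self.w_min <= 0:
            raise ValueError("window length must be positive")
        if self.s_min is None:
            object.__setattr__(self, "s_min", default_slide_min(self.w_min))
        if self.s_min <= 0:
            raise ValueError("sliding offset must be positive")

    @property
    def duration_class(self) -> str:
        return duration_class(self.w_min)


def sliding_windows(
    record_span_min: float, spec: WindowSpec
) -> list[tuple[float, float]]:
    """Window placements [k*s, k*s + w] while the window fits in the record.

    The count equals floor((span - w)/s) + 1 when span >= w, else 0.
    """
    w, s = spec.w_min, spec.s_min
    out = []
    k = 0
    while k * s + w <= record_span_min:
        out.append((float(k * s), float(k * s + w)))
        k += 1
    return out


# ---------------------------------------------------------------------------
# segment aggregation: Average and Combined methods
# ---------------------------------------------------------------------------

@dataclass
class HRVResult:
    """HRV parameters of one window under one aggregation method.

    Fields are None where the parameter is undefined on the window (e.g.
    SDANN without two qualifying 5-min bins, or no clean segment at all).
    Under method A, nn50 is the real-valued mean of per-segment counts.
    """

    method: str  # "A" or "C"
    window_id: str = ""
    n_intervals: int = 0
    sdnn: float | None = None
    sdann: float | None = None
    asdnn: float | None = None
    rmssd: float | None = None
    nn50: float | None = None
    pnn50: float | None = None
    sd1: float | None = None
    sd2: float | None = None
    sd1_sd2: float | None = None
    reason: str | None = None  # why the window is undefined

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "window_id": self.window_id,
            "n_intervals": self.n_intervals,
            "sdnn": self.sdnn,
            "sdann": self.sdann,
            "asdnn": self.asdnn,
            "rmssd": self.rmssd,
            "nn50": self.nn50,
            "pnn50": self.pnn50,
            "sd1": self.sd1,
            "sd2": self.sd2,
            "sd1_sd2": self.sd1_sd2,
            "reason": self.reason,
        }


def _segment_onsets(seg: NNSegment) -> list[tuple[float, float]]:
    out = []
    t = seg.start_ms
    for rr in seg.rr_ms:
        out.append((t, rr))
        t += rr
    return out


def _window_sdann_asdnn(
    segments: Sequence[NNSegment], window_start_ms: float
) -> tuple[float | None, float | None]:
    pairs = [p for seg in segments for p in _segment_onsets(seg)]
    try:
        return sdann_asdnn(pairs, window_start_ms)
    except UndefinedHRV:
        return None, None


def hrv_average(
    segments: Sequence[NNSegment],
    window_id: str = "",
    window_start_ms: float = 0.0,
) -> HRVResult:
    """Method A: unweighted mean of per-segment parameters."""
    usable = [s for s in segments if s.n >= 2]
    if not usable:
        return HRVResult(method="A", window_id=window_id, reason="no_segments")
    per_sdnn, per_rmssd, per_nn50, per_pnn50 = [], [], [], []
    per_sd1, per_sd2, per_ratio = [], [], []
    for seg in usable:
        per_sdnn.append(sdnn(seg.rr_ms))
        per_rmssd.append(rmssd(seg.rr_ms))
        per_nn50.append(nn50(seg.rr_ms))
        per_pnn50.append(pnn50(seg.rr_ms))
        s1, s2, ratio = poincare(seg.rr_ms)
        per_sd1.append(s1)
        per_sd2.append(s2)
        if ratio is not None:
            per_ratio.append(ratio)
    sdann_v, asdnn_v = _window_sdann_asdnn(usable, window_start_ms)
    return HRVResult(
        method="A",
        window_id=window_id,
        n_intervals=sum(s.n for s in usable),
        sdnn=float(np.mean(per_sdnn)),
        sdann=sdann_v,
        asdnn=asdnn_v,
        rmssd=float(np.mean(per_rmssd)),
        nn50=float(np.mean(per_nn50)),
        pnn50=float(np.mean(per_pnn50)),
        sd1=float(np.mean(per_sd1)),
        sd2=float(np.mean(per_sd2)),
        sd1_sd2=float(np.mean(per_ratio)) if per_ratio else None,
    )


def hrv_combined(
    segments: Sequence[NNSegment],
    window_id: str = "",
    window_start_ms: float = 0.0,
) -> HRVResult:
    """Method C: one computation on the concatenated clean intervals.

    Successive differences are pooled within segments only, so an artifact
    boundary the cleaning removed can never re-enter RMSSD/NN50/SD1.
    """
    usable = [s for s in segments if s.n >= 1]
    all_nn = [rr for seg in usable for rr in seg.rr_ms]
    if len(all_nn) < 2:
        return HRVResult(method="C", window_id=window_id, reason="no_segments")
    diffs = np.concatenate(
        [np.diff(seg.rr_ms) for seg in usable if seg.n >= 2]
        or [np.empty(0)]
    )
    sdnn_v = sdnn(all_nn)
    if diffs.size:
        rmssd_v = float(np.sqrt(np.mean(diffs * diffs)))
        nn50_v = float(np.sum(np.abs(diffs) > 50.0))
        pnn50_v = 100.0 * nn50_v / diffs.size
        sd1 = rmssd_v / math.sqrt(2.0)
    else:
        rmssd_v = nn50_v = pnn50_v = sd1 = None
    sd2 = (
        math.sqrt(max(0.0, 2.0 * sdnn_v**2 - sd1**2)) if sd1 is not None else None
    )
    ratio = sd1 / sd2 if sd1 is not None and sd2 and sd2 > 0 else None
    sdann_v, asdnn_v = _window_sdann_asdnn(usable, window_start_ms)
    return HRVResult(
        method="C",
        window_id=window_id,
        n_intervals=len(all_nn),
        sdnn=sdnn_v,
        sdann=sdann_v,
        asdnn=asdnn_v,
        rmssd=rmssd_v,
        nn50=nn50_v,
        pnn50=pnn50_v,
        sd1=sd1,
        sd2=sd2,
        sd1_sd2=ratio,
    )


def windowed_hrv(
    rr: RRSeries,
    spec: WindowSpec,
    cfg: CleaningConfig = CleaningConfig(),
    methods: Sequence[str] = ("A", "C"),
) -> pd.DataFrame:
    """Clean and compute HRV in every sliding-window placement.

    Window membership is by interval onset, half-open [start, start+w), so
    adjacent windows never double-count an interval. Returns one row per
    (window, method); windows with no clean data carry a reason code and
    absent parameter values.
    """
    for m in methods:
        if m not in ("A", "C"):
            raise ValueError(f"unknown method {m!r}")
    span_min = rr.span_ms / MS_PER_MIN if len(rr) else 0.0
    t0 = rr.intervals[0].onset_ms if len(rr) else 0.0
    rows = []
    for start_min, end_min in sliding_windows(span_min, spec):
        lo = t0 + start_min * MS_PER_MIN
        hi = t0 + end_min * MS_PER_MIN
        sub = [iv for iv in rr if lo <= iv.onset_ms < hi]
        window_id = f"w{spec.w_min}s{spec.s_min}@{start_min:g}"
        segments = extract_nn_segments(sub, cfg) if sub else []
        for m in methods:
            fn = hrv_average if m == "A" else hrv_combined
            res = fn(segments, window_id=window_id, window_start_ms=lo)
            row = res.as_dict()
            row["start_min"] = start_min
            rows.append(row)
    cols = [
        "window_id", "start_min", "method", "sdnn", "sdann", "asdnn",
        "rmssd", "nn50", "pnn50", "sd1", "sd2", "sd1_sd2", "n_intervals",
        "reason",
    ]
    return pd.DataFrame(rows, columns=cols)
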