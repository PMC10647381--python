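"""NN-interval cleaning: ectopic/artifact exclusion and run filtering.

An NN interval is the time between two consecutive normal (N) beats. HRV
statistics are only meaningful on clean NN runs, so this module

1. screens out whole recordings with diagnosed atrial fibrillation or a
   sinus pause/arrest (any interval at or above ``pause_ms``),
2. rejects every interval adjacent to an A, V, S, F, Q beat or an X
   artifact marker,
3. applies a relative-change threshold between consecutive accepted
   intervals — ``prev*(1-a) < cur < prev*(1+a)`` with allowable change
   ``a`` (default 15%), strict bounds — and
4. drops runs shorter than ``min_run`` intervals (default 6).

When an interval violates the relative-change bound it is discarded
entirely; the following interval seeds a new candidate run without a
comparison (it has no accepted predecessor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import RRInterval, RRSeries


@dataclass(frozen=True)
class CleaningConfig:
    """Parameters of the NN-extraction rules.

    allowable_change
        Maximum relative change between consecutive NN intervals, as a
        fraction in (0, 1).
    min_run
        Minimum number of NN intervals a clean run must contain to be kept.
    pause_ms
        Any interval at least this long is treated as a sinus pause/arrest
        and excludes the whole recording (3 s clinical convention).
    afib_flag_excludes
        Whether a diagnosed-AFIB flag excludes the recording.
    """

    allowable_change: float = 0.15
    min_run: int = 6
    pause_ms: float = 3000.0
    afib_flag_excludes: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.allowable_change < 1:
            raise ValueError("allowable_change must be in (0, 1)")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if self.pause_ms <= 0:
            raise ValueError("pause_ms must be positive")


@dataclass(frozen=True)
class ScreenResult:
    accepted: bool
    reason: str | None = None  # "afib" or "pause" when excluded


@dataclass
class NNSegment:
    """A contiguous run of accepted NN intervals."""

    rr_ms: list[float]
    start_ms: float
    end_ms: float

    @property
    def n(self) -> int:
        return len(self.rr_ms)


def screen_recording(
    rr: RRSeries, afib_diagnosed: bool, cfg: CleaningConfig = CleaningConfig()
) -> ScreenResult:
    """Accept or exclude a whole recording before NN extraction."""
    if len(rr) == 0:
        raise ValueError("empty RR series")
    if afib_diagnosed and cfg.afib_flag_excludes:
        return ScreenResult(False, "afib")
    if any(iv.rr_ms >= cfg.pause_ms for iv in rr):
        return ScreenResult(False, "pause")
    return ScreenResult(True)


def nn_bound_ok(
    prev_ms: float, cur_ms: float, cfg: CleaningConfig = CleaningConfig()
) -> bool:
    """Relative-change rule between consecutive NN intervals (strict bounds)."""
    if prev_ms <= 0 or cur_ms <= 0:
        raise ValueError("intervals must be positive")
    a = cfg.allowable_change
    return prev_ms * (1 - a) < cur_ms < prev_ms * (1 + a)


def extract_nn_segments(
    rr: RRSeries | Sequence[RRInterval], cfg: CleaningConfig = CleaningConfig()
) -> list[NNSegment]:
    """Extract clean NN segments from an interval series.

    Returns disjoint, time-ordered segments in which every interval has N
    beats at both ends, every consecutive pair satisfies the
    relative-change bound, and every segment has at least ``min_run``
    intervals. An input with no qualifying run yields an empty list.
    """
    intervals = list(rr.intervals if isinstance(rr, RRSeries) else rr)
    if not intervals:
        raise ValueError("empty RR series")

    rr_ms = np.array([iv.rr_ms for iv in intervals])
    onset = np.array([iv.onset_ms for iv in intervals])
    cand = np.array(
        [iv.start_label == "N" and iv.end_label == "N" for iv in intervals]
    )

    segments: list[NNSegment] = []

    def emit(lo: int, hi: int) -> None:  # [lo, hi)
        if hi - lo >= cfg.min_run:
            segments.append(
                NNSegment(
                    rr_ms=rr_ms[lo:hi].tolist(),
                    start_ms=float(onset[lo]),
                    end_ms=float(onset[hi - 1] + rr_ms[hi - 1]),
                )
            )

    # maximal stretches of candidate intervals
    boundaries = np.flatnonzero(np.diff(cand.astype(np.int8)))
    starts = [0] + (boundaries + 1).tolist()
    for a, b in zip(starts, starts[1:] + [len(intervals)]):
        if not cand[a]:
            continue
        # consecutive-pair bound within the stretch; ok[k] refers to the
        # pair (a+k, a+k+1)
        lo_b = rr_ms[a:b - 1] * (1 - cfg.allowable_change)
        hi_b = rr_ms[a:b - 1] * (1 + cfg.allowable_change)
        ok = (lo_b < rr_ms[a + 1:b]) & (rr_ms[a + 1:b] < hi_b)
        viol = (np.flatnonzero(~ok) + a + 1).tolist()
        seg_start = a
        for v in viol:
            if v < seg_start + 1:
                # v is the first interval of the current run (fresh seed):
                # a seed has no predecessor so this pair is never checked
                continue
            emit(seg_start, v)
            seg_start = v + 1  # the violating interval is discarded
        if seg_start < b:
            emit(seg_start, b)
    return segments


def segments_total_intervals(segments: Sequence[NNSegment]) -> int:
    return sum(s.n for s in segments)
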