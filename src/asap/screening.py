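"""Automated HR-defined sustained-attention screening (Step 1, back half).

Applies the coding rules to a change-point segmentation: an SA candidate
opens at a change point whose mean-HR drop reaches 5 bpm (or 3–5 bpm with a
peak-to-peak drop above 5 bpm, in which case the onset moves to the HR peak
just before the change point); it closes symmetrically at a qualifying
rise.  Consecutive qualifying drops keep the earliest onset; intervals
shorter than 2 s are discarded, as is a candidate still open at session
end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .changepoint import ChangePointSegmentation
from .io_signals import BeatSeries, UniformSeries

__all__ = ["AttentionIntervals", "screen_sa", "to_binary", "count_fixated_objects"]

BIG_DELTA_BPM = 5.0
SMALL_DELTA_BPM = 3.0
PEAK_WINDOW_BEATS = 5
MIN_SA_DURATION_S = 2.0


@dataclass
class AttentionIntervals:
    """Sorted, disjoint half-open [onset, offset) attention periods."""

    intervals: list[tuple[float, float]] = field(default_factory=list)
    source: str = "step1"
    session_id: str = ""

    def __post_init__(self) -> None:
        iv = sorted((float(a), float(b)) for a, b in self.intervals)
        for a, b in iv:
            if a >= b:
                raise ValueError("interval onset must precede offset")
        for (_, b0), (a1, _) in zip(iv[:-1], iv[1:]):
            if a1 < b0:
                raise ValueError("intervals must be pairwise disjoint")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals])

    def total_time(self) -> float:
        return float(self.durations.sum()) if self.intervals else 0.0

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Vectorised point-in-interval indicator."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros(t.size, dtype=bool)
        for a, b in self.intervals:
            out |= (t >= a) & (t < b)
        return out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "onset_s": [a for a, _ in self.intervals],
                "offset_s": [b for _, b in self.intervals],
                "source": self.source,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, session_id: str = "") -> "AttentionIntervals":
        df = pd.read_csv(path)
        src = str(df["source"].iloc[0]) if len(df) else "step1"
        return cls(
            intervals=list(zip(df["onset_s"], df["offset_s"])),
            source=src,
            session_id=session_id,
        )


def _local_extreme_before(hr: np.ndarray, times: np.ndarray, k: int, kind: str) -> tuple[float, float]:
    """(value, time) of the local max/min of HR within the 5 beats up to k."""
    lo = max(0, k - PEAK_WINDOW_BEATS)
    window = hr[lo : k + 1]
    j = int(np.argmax(window)) if kind == "max" else int(np.argmin(window))
    return float(window[j]), float(times[lo + j])


def _local_extreme_after(hr: np.ndarray, times: np.ndarray, k: int, kind: str) -> tuple[float, float]:
    hi = min(hr.size, k + 1 + PEAK_WINDOW_BEATS)
    window = hr[k + 1 : hi]
    if window.size == 0:
        window, base = hr[k : k + 1], k
    else:
        base = k + 1
    j = int(np.argmax(window)) if kind == "max" else int(np.argmin(window))
    return float(window[j]), float(times[base + j])


def screen_sa(
    seg: ChangePointSegmentation,
    beats: BeatSeries,
    big_drop: float = BIG_DELTA_BPM,
    small_lo: float = SMALL_DELTA_BPM,
    min_duration_s: float = MIN_SA_DURATION_S,
    session_id: str = "",
) -> AttentionIntervals:
    """Screen a segmentation for putative SA periods (greedy left-to-right)."""
    hr = beats.hr_bpm
    hr_t = beats.hr_times
    out: list[tuple[float, float]] = []
    onset: float | None = None

    for k_idx in range(seg.change_points.size):
        k = int(seg.change_points[k_idx])
        delta = float(seg.deltas[k_idx])
        cp_time = float(seg.times[k_idx])

        onset_here: float | None = None
        term_here: float | None = None
        if delta <= -big_drop:
            onset_here = cp_time
        elif -big_drop < delta <= -small_lo:
            peak_before, t_before = _local_extreme_before(hr, hr_t, k - 1, "max")
            trough_after, _ = _local_extreme_after(hr, hr_t, k - 1, "min")
            if peak_before - trough_after > big_drop:
                onset_here = t_before
        elif delta >= big_drop:
            term_here = cp_time
        elif small_lo <= delta < big_drop:
            trough_before, _ = _local_extreme_before(hr, hr_t, k - 1, "min")
            peak_after, t_after = _local_extreme_after(hr, hr_t, k - 1, "max")
            if peak_after - trough_before >= big_drop:
                term_here = t_after

        if onset_here is not None:
            if onset is None:
                onset = onset_here  # earliest drop fixes the onset
        elif term_here is not None and onset is not None:
            if term_here > onset and term_here - onset >= min_duration_s:
                if not out or onset >= out[-1][1]:
                    out.append((onset, term_here))
            onset = None  # candidate closed (or dropped as too short)

    return AttentionIntervals(intervals=out, source="step1", session_id=session_id)


def to_binary(intervals: AttentionIntervals, grid: UniformSeries) -> UniformSeries:
    """0/1 indicator of the intervals on the analysis grid (gaps stay masked)."""
    vals = intervals.contains(grid.times).astype(float)
    vals = np.where(grid.gap_mask, np.nan, vals)
    return UniformSeries(grid.t0, grid.rate_hz, vals, grid.gap_mask.copy())


def count_fixated_objects(
    fixations: list[tuple[float, float, object]],
    interval: tuple[float, float],
    max_objects: int = 5,
) -> tuple[int, bool]:
    """Distinct non-null object labels fixated during [onset, offset).

    The pass flag implements the annotation-support criterion: at least one
    and at most ``max_objects`` objects fixated during the period.  Used for
    coding support only, never at inference.
    """
    a, b = interval
    labels = {
        lab
        for start, end, lab in fixations
        if lab is not None and not (pd.isna(lab) if np.isscalar(lab) else False) and start < b and end > a
    }
    count = len(labels)
    return count, (1 <= count <= max_objects)
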