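"""Egocentric model-application pipeline.

Windows the fixation stream into consecutive 5 s windows, builds a binary
circular-mask union per window (50 px radius), averages a per-frame scalar
map (saliency, clutter, or any pluggable backend) over the masked pixels
and frames of each window, and contrasts the within-session standardised
window values between attention and inattention states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screening import AttentionIntervals

__all__ = [
    "FixationSeries",
    "WindowedFeatureSeries",
    "fixation_mask",
    "windowed_stat",
    "state_contrast",
    "gradient_energy_map",
]

DEFAULT_RADIUS_PX = 50
DEFAULT_WINDOW_S = 5.0
DEFAULT_FRAME_SIZE = (640, 480)  # (width, height)


@dataclass
class FixationSeries:
    """Labelled fixations: (start_s, end_s, x_px, y_px, label)."""

    fixations: list[tuple[float, float, int, int, object]]
    frame_size: tuple[int, int] = DEFAULT_FRAME_SIZE

    def __post_init__(self) -> None:
        w, h = self.frame_size
        for start, end, x, y, _ in self.fixations:
            if end - start <= 0.1:
                raise ValueError("fixations must last more than 100 ms")
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError("fixation coordinates outside the frame")

    def in_window(self, t0: float, t1: float) -> list[tuple[float, float, int, int, object]]:
        return [f for f in self.fixations if f[0] < t1 and f[1] > t0]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.fixations, columns=["start_s", "end_s", "x_px", "y_px", "label"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_size=DEFAULT_FRAME_SIZE) -> "FixationSeries":
        df = pd.read_csv(path)
        fixes = [
            (float(r.start_s), float(r.end_s), int(r.x_px), int(r.y_px), r.label)
            for r in df.itertuples()
        ]
        return cls(fixes, frame_size)


@dataclass
class WindowedFeatureSeries:
    """Per-window mean map value inside the fixation mask (NaN = no fixation)."""

    window_starts: np.ndarray
    values: np.ndarray
    measure: str = "saliency"
    window_s: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.window_starts.shape != self.values.shape:
            raise ValueError("window_starts and values must align")


def fixation_mask(
    fixations: list[tuple],
    frame_size: tuple[int, int] = DEFAULT_FRAME_SIZE,
    radius: int = DEFAULT_RADIUS_PX,
) -> np.ndarray:
    """Union of filled circles around each fixation, clipped to the frame.

    ``fixations`` items need (x, y) at positions 2 and 3 (full fixation
    tuples) or 0 and 1 (bare coordinates).  Returns (height, width) bool.
    """
    w, h = frame_size
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for fx in fixations:
        x, y = (fx[2], fx[3]) if len(fx) >= 4 else (fx[0], fx[1])
        mask |= (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    return mask


def windowed_stat(
    maps: np.ndarray,
    frame_times: np.ndarray,
    fixations: FixationSeries,
    window_s: float = DEFAULT_WINDOW_S,
    radius: int = DEFAULT_RADIUS_PX,
    measure: str = "saliency",
) -> WindowedFeatureSeries:
    """Mean map value inside each window's fixation mask.

    Frames are assigned to the window covering their timestamp; incomplete
    trailing windows are dropped; windows without fixations get NaN.
    """
    maps = np.asarray(maps)
    frame_times = np.asarray(frame_times, dtype=float)
    if maps.shape[0] != frame_times.size:
        raise ValueError("maps and frame_times misaligned")
    h, w = maps.shape[1:]
    if (w, h) != fixations.frame_size:
        raise ValueError("map frames do not match the fixation frame size")

    t_end = frame_times[-1] + np.median(np.diff(frame_times)) if frame_times.size > 1 else window_s
    n_windows = int(np.floor(t_end / window_s))
    starts = np.arange(n_windows) * window_s
    values = np.full(n_windows, np.nan)
    for k, t0 in enumerate(starts):
        sel = (frame_times >= t0) & (frame_times < t0 + window_s)
        fx = fixations.in_window(t0, t0 + window_s)
        if not fx or not sel.any():
            continue
        mask = fixation_mask(fx, fixations.frame_size, radius)
        if not mask.any():
            continue
        values[k] = float(maps[sel][:, mask].mean())
    return WindowedFeatureSeries(starts, values, measure=measure, window_s=window_s)


def state_contrast(
    series: WindowedFeatureSeries,
    intervals: AttentionIntervals,
) -> dict[str, float]:
    """Within-session standardised per-state means and their difference.

    Non-missing window values are z-scored within the session; a window
    counts as attention when more than half of it overlaps an interval.
    Returns attention mean, inattention mean, and attention - inattention.
    """
    vals = series.values
    good = np.isfinite(vals)
    if good.sum() < 2:
        raise ValueError("need at least two non-missing windows")
    z = np.full_like(vals, np.nan)
    z[good] = (vals[good] - vals[good].mean()) / max(vals[good].std(), 1e-12)

    att = np.zeros(vals.size, dtype=bool)
    for k, t0 in enumerate(series.window_starts):
        t1 = t0 + series.window_s
        overlap = sum(max(0.0, min(t1, b) - max(t0, a)) for a, b in intervals)
        att[k] = overlap > 0.5 * series.window_s

    mean_att = float(np.nanmean(z[att])) if (att & good).any() else np.nan
    mean_inatt = float(np.nanmean(z[~att])) if (~att & good).any() else np.nan
    return {
        "attention_mean": mean_att,
        "inattention_mean": mean_inatt,
        "difference": mean_att - mean_inatt,
        "n_windows": int(good.sum()),
    }


def gradient_energy_map(frame: np.ndarray) -> np.ndarray:
    """Trivial bundled map backend: smoothed gradient magnitude of a frame."""
    from scipy.ndimage import gaussian_filter, sobel

    gx = sobel(frame.astype(float), axis=1)
    gy = sobel(frame.astype(float), axis=0)
    return gaussian_filter(np.hypot(gx, gy), sigma=3.0)
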