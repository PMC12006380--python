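"""Multiple mean-shift detection in beat-indexed heart rate.

Wild binary segmentation 2 (WBS2): within each current stretch the CUSUM
contrast is maximised over the stretch itself plus a batch of randomly drawn
sub-intervals; the winning split is recorded as a candidate and the
recursion continues on both sides.  The number of change points is then
chosen by the steepest-drop-to-low-levels (SDLL) rule on the sorted
candidate magnitudes.

The change-point index convention is "first index of the new segment": a
change point at index ``p`` splits ``x`` into ``x[:p]`` and ``x[p:]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_signals import BeatSeries

__all__ = [
    "CandidateChangePoint",
    "ChangePointSegmentation",
    "cusum_stats",
    "wbs2_candidates",
    "mad_sigma",
    "sdll_select",
    "segment_stats",
    "detect_changepoints",
]

DEFAULT_N_INTERVALS = 100
DEFAULT_MIN_SEG = 2
DEFAULT_SDLL_C = 1.3


@dataclass(frozen=True)
class CandidateChangePoint:
    index: int
    cusum_mag: float
    interval: tuple[int, int]


@dataclass
class ChangePointSegmentation:
    """Sorted change points with per-segment statistics."""

    change_points: np.ndarray  # indices into the series
    segment_means: np.ndarray  # bpm, len = n_cp + 1
    deltas: np.ndarray  # bpm, len = n_cp, mean[k+1] - mean[k]
    directions: np.ndarray  # 'descending' | 'ascending', len = n_cp
    times: np.ndarray  # seconds, len = n_cp
    n_obs: int = 0

    @property
    def n_segments(self) -> int:
        return int(self.change_points.size) + 1


def cusum_stats(x: np.ndarray, s: int, e: int, min_seg: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Absolute CUSUM contrast for every admissible split of ``x[s:e]``.

    Returns (split positions p, statistics); split ``p`` contrasts
    ``x[s:p]`` against ``x[p:e]`` with at least ``min_seg`` points per side.
    """
    n = e - s
    if n < 2 * min_seg:
        return np.empty(0, dtype=int), np.empty(0)
    seg = x[s:e]
    csum = np.cumsum(seg)
    total = csum[-1]
    left = np.arange(min_seg, n - min_seg + 1)  # left-size l
    sum_left = csum[left - 1]
    right = n - left
    stat = np.abs(
        np.sqrt(right / (n * left)) * sum_left - np.sqrt(left / (n * right)) * (total - sum_left)
    )
    return s + left, stat


def _best_split(x: np.ndarray, s: int, e: int, min_seg: int) -> tuple[int, float]:
    pos, stat = cusum_stats(x, s, e, min_seg)
    if pos.size == 0:
        return -1, -np.inf
    k = int(np.argmax(stat))
    return int(pos[k]), float(stat[k])


def wbs2_candidates(
    series: np.ndarray,
    n_intervals: int = DEFAULT_N_INTERVALS,
    min_seg: int = DEFAULT_MIN_SEG,
    seed: int | np.random.Generator = 0,
) -> list[CandidateChangePoint]:
    """Recursive WBS2 candidate generation (order of discovery)."""
    x = np.asarray(series, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[CandidateChangePoint] = []
    if x.size < 2 * min_seg:
        return out

    stack = [(0, x.size)]
    while stack:
        s, e = stack.pop()
        if e - s < 2 * min_seg:
            continue
        # the full stretch always competes
        best_p, best_stat = _best_split(x, s, e, min_seg)
        best_iv = (s, e)
        n = e - s
        if n > 2 * min_seg:
            lo = rng.integers(s, e - 2 * min_seg + 1, size=n_intervals)
            hi_min = lo + 2 * min_seg
            hi = hi_min + (rng.random(n_intervals) * (e - hi_min + 1)).astype(int)
            for a, b in zip(lo, np.minimum(hi, e)):
                p, stat = _best_split(x, int(a), int(b), min_seg)
                if stat > best_stat:
                    best_p, best_stat, best_iv = p, stat, (int(a), int(b))
        if best_p < 0:
            continue
        out.append(CandidateChangePoint(index=best_p, cusum_mag=best_stat, interval=best_iv))
        stack.append((s, best_p))
        stack.append((best_p, e))
    return out


def mad_sigma(series: np.ndarray) -> float:
    """Robust noise scale: MAD of first differences / (sqrt(2) * 0.6745)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        return 0.0
    d = np.diff(x)
    return float(np.median(np.abs(d - np.median(d))) / (np.sqrt(2.0) * 0.6745))


def sdll_select(
    candidates: list[CandidateChangePoint],
    sigma_hat: float,
    series_len: int,
    c: float = DEFAULT_SDLL_C,
    scale: float | None = None,
) -> np.ndarray:
    """Steepest-drop-to-low-levels model selection.

    With magnitudes (scaled by ``sigma_hat``) sorted descending and the
    universal threshold T = c * sqrt(2 log n): no change point is kept when
    the largest magnitude is below T; otherwise K maximises the drop ratio
    s_k / s_{k+1} over the drops that leave signal level for low levels
    (s_k >= T > s_{k+1}, with a zero sentinel after the last candidate;
    ties toward smaller K, so K = m when every magnitude clears T).

    ``scale`` (typically the series' max absolute value) sets an absolute
    floor for ``sigma_hat`` so floating-point residue on noise-free signals
    cannot register as candidate magnitude.
    """
    if not candidates:
        return np.empty(0, dtype=int)
    order = sorted(candidates, key=lambda cand: -cand.cusum_mag)
    raw = np.array([cand.cusum_mag for cand in order])
    sigma = max(float(sigma_hat), 1e-8 * raw[0], 1e-9 * (scale or 0.0), 1e-300)
    s = raw / sigma
    thresh = c * np.sqrt(2.0 * np.log(max(series_len, 2)))
    if s[0] < thresh:
        return np.empty(0, dtype=int)
    succ = np.append(s[1:], 0.0)
    eligible = np.flatnonzero((s >= thresh) & (succ < thresh))
    ratios = s[eligible] / np.maximum(succ[eligible], 1e-300)
    k_sel = int(eligible[int(np.argmax(ratios))]) + 1
    idx = sorted(cand.index for cand in order[:k_sel])
    return np.asarray(idx, dtype=int)


def segment_stats(
    series: np.ndarray,
    change_points: np.ndarray,
    beats: BeatSeries | None = None,
    slope_window: int = 2,
) -> ChangePointSegmentation:
    """Per-segment means, deltas and local-slope direction labels.

    ``times`` maps each change point to the time stamp of its beat when a
    :class:`BeatSeries` is supplied (the HR series is stamped at the later
    peak of each interval), otherwise to the index itself.
    """
    x = np.asarray(series, dtype=float)
    cps = np.asarray(sorted(int(p) for p in change_points), dtype=int)
    if cps.size and (cps[0] < 1 or cps[-1] > x.size - 1):
        raise ValueError("change-point index out of range")

    bounds = np.concatenate([[0], cps, [x.size]])
    means = np.array([x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    deltas = np.diff(means)

    directions = np.empty(cps.size, dtype=object)
    for i, p in enumerate(cps):
        after = x[p : min(p + slope_window, x.size)].mean()
        before = x[max(p - slope_window, 0) : p].mean()
        directions[i] = "descending" if after - before < 0 else "ascending"

    if beats is not None:
        hr_times = beats.hr_times
        times = hr_times[np.clip(cps, 0, hr_times.size - 1)]
    else:
        times = cps.astype(float)
    return ChangePointSegmentation(
        change_points=cps,
        segment_means=means,
        deltas=deltas,
        directions=directions,
        times=times,
        n_obs=int(x.size),
    )


def detect_changepoints(
    beats: BeatSeries,
    n_intervals: int = DEFAULT_N_INTERVALS,
    min_seg: int = DEFAULT_MIN_SEG,
    sdll_c: float = DEFAULT_SDLL_C,
    seed: int | np.random.Generator = 0,
) -> ChangePointSegmentation:
    """Step-1 front half: WBS2 + SDLL on the beat-indexed HR series."""
    hr = beats.hr_bpm
    cands = wbs2_candidates(hr, n_intervals=n_intervals, min_seg=min_seg, seed=seed)
    selected = sdll_select(
        cands, mad_sigma(hr), hr.size, c=sdll_c, scale=float(np.max(np.abs(hr)))
    )
    return segment_stats(hr, selected, beats=beats)
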