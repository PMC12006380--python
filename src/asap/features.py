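"""Step-2 feature extraction: the 51-column, 2 Hz predictor matrix.

Columns, in canonical order:

* ``HR``, ``Acc`` — the 2 Hz heart-rate and acceleration-magnitude series;
* ``WPT-HR-1..16``, ``WPT-Acc-1..16`` — level-4 maximal-overlap wavelet
  packet decomposition (Daubechies, two vanishing moments), sequency
  ordered coarse→fine so the 16 bands tile 0–1 Hz in 0.0625 Hz steps;
* ``LSW-HR-Acc-1..12`` — Fisher-z time-varying wavelet coherence between
  HR and Acc at the 12 finest dyadic scales;
* ``SDRR`` — session standard deviation of inter-beat intervals;
* ``CPbinary``, ``Duration``, ``Latency`` — Step-1 segmentation covariates;
* ``Age`` — age in months.

The non-decimated transforms are computed in the Fourier domain as products
of upsampled quadrature-mirror filter responses.  ``modwpt_bands`` returns
the multiresolution *details*, which sum exactly to the input series;
``modwpt_coefficients`` returns the coefficient series, whose band energies
sum exactly to the input energy.  Both identities are exercised in tests.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
import pywt
from scipy.ndimage import uniform_filter1d

from .io_signals import BeatSeries, UniformSeries
from .screening import AttentionIntervals

__all__ = [
    "FEATURE_NAMES",
    "modwpt_bands",
    "modwpt_coefficients",
    "lsw_coherence",
    "sdrr",
    "segment_covariates",
    "assemble",
    "FeatureMatrix",
]

N_WPT_BANDS = 16
N_COH_LEVELS = 12
COHERENCE_CLIP = 1.0 - 1e-6
SMOOTH_SPAN_S = 30.0

FEATURE_NAMES: tuple[str, ...] = (
    ("HR", "Acc")
    + tuple(f"WPT-HR-{i}" for i in range(1, N_WPT_BANDS + 1))
    + tuple(f"WPT-Acc-{i}" for i in range(1, N_WPT_BANDS + 1))
    + tuple(f"LSW-HR-Acc-{i}" for i in range(1, N_COH_LEVELS + 1))
    + ("SDRR", "CPbinary", "Duration", "Latency", "Age")
)
assert len(FEATURE_NAMES) == 51


# ---------------------------------------------------------------------------
# non-decimated transforms in the Fourier domain
# ---------------------------------------------------------------------------


def _reflect_extend(x: np.ndarray, target: int) -> np.ndarray:
    """Repeated-reflection tiling of ``x`` up to ``target`` samples."""
    if x.size >= target:
        return x[:target]
    tiles = [x]
    flip = True
    while sum(t.size for t in tiles) < target:
        tiles.append(x[::-1] if flip else x)
        flip = not flip
    return np.concatenate(tiles)[:target]


def _fill_gaps(series: UniformSeries) -> np.ndarray:
    """Linear interpolation across masked spans (transforms need no NaNs)."""
    vals = series.values.copy()
    bad = series.gap_mask | ~np.isfinite(vals)
    if bad.all():
        raise ValueError("series is entirely masked")
    if bad.any():
        idx = np.arange(vals.size)
        vals[bad] = np.interp(idx[bad], idx[~bad], vals[~bad])
    return vals


@lru_cache(maxsize=32)
def _filter_responses(n_fft: int, wavelet: str, level: int) -> np.ndarray:
    """DFT response of the rescaled low/high filters, upsampled per level.

    Returns complex array of shape (level, 2, n_fft): [j, 0] the scaling
    (low-pass) and [j, 1] the wavelet (high-pass) response at level j+1.
    """
    w = pywt.Wavelet(wavelet)
    g = np.asarray(w.dec_lo) / np.sqrt(2.0)  # MODWT scaling
    h = np.asarray(w.dec_hi) / np.sqrt(2.0)
    k = np.arange(n_fft)
    out = np.empty((level, 2, n_fft), dtype=complex)
    for j in range(level):
        up = 2**j
        phase = np.exp(-2j * np.pi * up * k / n_fft)
        for which, filt in enumerate((g, h)):
            resp = np.zeros(n_fft, dtype=complex)
            for l, coef in enumerate(filt):
                resp += coef * phase**l
            out[j, which] = resp
    return out


def _sequency_paths(level: int) -> list[list[int]]:
    """Filter choice (0 = low, 1 = high) per level for sequency-ordered nodes.

    Children of node ``m``: when ``m`` is even its low-pass child is ``2m``;
    when odd the order flips, which yields the frequency-ordered bands.
    """
    paths = []
    for n in range(2**level):
        chain = []
        m = n
        for _ in range(level):
            chain.append(m)
            m //= 2
        chain.reverse()
        parent = 0
        choice = []
        for mj in chain:
            low_child = 2 * parent if parent % 2 == 0 else 2 * parent + 1
            choice.append(0 if mj == low_child else 1)
            parent = mj
        paths.append(choice)
    return paths


def _node_transfers(n_fft: int, wavelet: str, level: int) -> np.ndarray:
    """Equivalent transfer function of each sequency-ordered packet node."""
    resp = _filter_responses(n_fft, wavelet, level)
    transfers = np.empty((2**level, n_fft), dtype=complex)
    for n, path in enumerate(_sequency_paths(level)):
        acc = np.ones(n_fft, dtype=complex)
        for j, which in enumerate(path):
            acc = acc * resp[j, which]
        transfers[n] = acc
    return transfers


def _padded_fft(values: np.ndarray, min_len: int = 0) -> tuple[np.ndarray, int, int]:
    n = values.size
    n_fft = 1
    while n_fft < max(2 * n, min_len, 8):
        n_fft *= 2
    ext = _reflect_extend(values, n_fft)
    return np.fft.rfft(ext), n, n_fft


def modwpt_bands(
    series: UniformSeries | np.ndarray,
    level: int = 4,
    wavelet: str = "db2",
) -> np.ndarray:
    """Additive MODWPT band series (multiresolution details).

    Shape (2**level, n); the bands sum to the input exactly and are
    sequency-ordered coarse→fine (at 2 Hz: 0.0625 Hz steps tiling 0–1 Hz).
    """
    vals = _fill_gaps(series) if isinstance(series, UniformSeries) else np.asarray(series, float)
    if vals.size < 2**level * len(pywt.Wavelet(wavelet).dec_lo):
        raise ValueError("series too short for the requested level")
    spec, n, n_fft = _padded_fft(vals)
    transfers = _node_transfers(n_fft, wavelet, level)[:, : spec.size]
    bands = np.empty((2**level, n))
    for b in range(2**level):
        gain = np.abs(transfers[b]) ** 2  # analysis then zero-phase synthesis
        bands[b] = np.fft.irfft(spec * gain, n=n_fft)[:n]
    return bands


def modwpt_coefficients(
    series: UniformSeries | np.ndarray,
    level: int = 4,
    wavelet: str = "db2",
) -> np.ndarray:
    """Energy-conserving MODWPT coefficient series (circular filtering)."""
    vals = _fill_gaps(series) if isinstance(series, UniformSeries) else np.asarray(series, float)
    if vals.size < 2**level * len(pywt.Wavelet(wavelet).dec_lo):
        raise ValueError("series too short for the requested level")
    n = vals.size
    n_fft = n  # circular on the native length: Parseval holds exactly
    spec = np.fft.rfft(vals)
    transfers = _node_transfers(n_fft, wavelet, level)[:, : spec.size]
    coeffs = np.empty((2**level, n))
    for b in range(2**level):
        coeffs[b] = np.fft.irfft(spec * transfers[b], n=n_fft)
    return coeffs


def _modwt_transfers(n_fft: int, levels: int, wavelet: str) -> np.ndarray:
    """Equivalent wavelet-filter transfer per MODWT level 1..levels."""
    resp = _filter_responses(n_fft, wavelet, levels)
    out = np.empty((levels, n_fft), dtype=complex)
    acc = np.ones(n_fft, dtype=complex)
    for j in range(levels):
        out[j] = acc * resp[j, 1]
        acc = acc * resp[j, 0]
    return out


def lsw_coherence(
    hr: UniformSeries,
    acc: UniformSeries,
    levels: int = N_COH_LEVELS,
    wavelet: str = "haar",
    smooth_span_s: float = SMOOTH_SPAN_S,
) -> np.ndarray:
    """Fisher-z time-varying wavelet coherence at the ``levels`` finest scales.

    Locally stationary wavelet estimator: non-decimated wavelet coefficients
    of both series per scale, evolutionary auto-/cross-spectra smoothed with
    a centred moving average, coherence clipped to |rho| <= 1 - 1e-6 and
    atanh-transformed.  Series are reflection-extended to a power of two of
    at least 2**levels and cropped back.  Returns shape (levels, n),
    ordered fine→coarse (level 1 first).
    """
    if hr.rate_hz != acc.rate_hz or len(hr) != len(acc):
        raise ValueError("HR and Acc must share one analysis grid")
    if len(hr) < 64:
        raise ValueError("series too short for coherence estimation")
    x = _fill_gaps(hr)
    y = _fill_gaps(acc)
    n = x.size
    spec_x, _, n_fft = _padded_fft(x, min_len=2**levels)
    spec_y, _, _ = _padded_fft(y, min_len=2**levels)
    transfers = _modwt_transfers(n_fft, levels, wavelet)[:, : spec_x.size]

    span = max(3, int(round(smooth_span_s * hr.rate_hz)) | 1)
    out = np.empty((levels, n))
    for j in range(levels):
        wx = np.fft.irfft(spec_x * transfers[j], n=n_fft)
        wy = np.fft.irfft(spec_y * transfers[j], n=n_fft)
        sxx = uniform_filter1d(wx * wx, span)[:n]
        syy = uniform_filter1d(wy * wy, span)[:n]
        sxy = uniform_filter1d(wx * wy, span)[:n]
        rho = sxy / np.sqrt(sxx * syy + 1e-300)
        rho = np.clip(rho, -COHERENCE_CLIP, COHERENCE_CLIP)
        out[j] = np.arctanh(rho)
    return out


def sdrr(beats: BeatSeries) -> float:
    """Session SD of inter-beat intervals (seconds, n-1 denominator)."""
    if beats.n_beats < 3:
        raise ValueError("need at least 3 beats for SDRR")
    return float(np.std(beats.ibi, ddof=1))


def segment_covariates(
    step1: AttentionIntervals,
    grid: UniformSeries,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step-1 covariates on the grid: (cp_binary, duration_s, latency_s).

    The session is partitioned into alternating putative-attention and
    inattention stretches by the Step-1 boundaries.  ``Duration`` is the
    length of the stretch containing each grid point; ``Latency`` is the
    time from the end of the previous putative SA interval to the start of
    the current stretch (0 before any SA has occurred).
    """
    t = grid.times
    t_start, t_end = float(t[0]), float(t[-1]) + 1.0 / grid.rate_hz
    bounds = [t_start]
    for a, b in step1:
        bounds.extend([a, b])
    bounds.append(t_end)
    bounds = sorted({b for b in bounds if t_start <= b <= t_end})

    cp_bin = step1.contains(t).astype(float)
    duration = np.zeros(t.size)
    latency = np.zeros(t.size)
    prev_sa_end: float | None = None
    for a, b in zip(bounds[:-1], bounds[1:]):
        sel = (t >= a) & (t < b)
        duration[sel] = b - a
        latency[sel] = 0.0 if prev_sa_end is None else a - prev_sa_end
        if step1.contains(np.array([(a + b) / 2]))[0]:
            prev_sa_end = b
    return cp_bin, duration, latency


class FeatureMatrix:
    """Named 51-column predictor matrix on the 2 Hz grid."""

    def __init__(self, times: np.ndarray, data: pd.DataFrame, row_mask: np.ndarray,
                 labels: np.ndarray | None = None, session_id: str = ""):
        if tuple(data.columns) != FEATURE_NAMES:
            raise ValueError("feature columns must match the canonical 51 names")
        if labels is not None and len(labels) != len(data):
            raise ValueError("labels must align with rows")
        bad = ~np.isfinite(data.to_numpy()[~row_mask])
        if bad.any():
            raise ValueError("non-finite feature values on unmasked rows")
        self.times = np.asarray(times, dtype=float)
        self.data = data
        self.row_mask = np.asarray(row_mask, dtype=bool)
        self.labels = None if labels is None else np.asarray(labels)
        self.session_id = session_id

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self) -> pd.DataFrame:
        """Unmasked predictor rows."""
        return self.data.loc[~self.row_mask]

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("matrix has no labels")
        return self.labels[~self.row_mask]

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df.insert(0, "time_s", self.times)
        df["row_mask"] = self.row_mask.astype(int)
        if self.labels is not None:
            df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, session_id: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy() if "label" in df.columns else None
        mask = df.pop("row_mask").to_numpy(bool)
        times = df.pop("time_s").to_numpy(float)
        return cls(times, df[list(FEATURE_NAMES)], mask, labels, session_id)


def assemble(
    hr: UniformSeries,
    acc: UniformSeries,
    wpt_hr: np.ndarray,
    wpt_acc: np.ndarray,
    coherence: np.ndarray,
    sdrr_s: float,
    covariates: tuple[np.ndarray, np.ndarray, np.ndarray],
    age_months: float,
    labels: np.ndarray | None = None,
    session_id: str = "",
) -> FeatureMatrix:
    """Assemble the canonical 51-column matrix; masked rows propagate."""
    n = len(hr)
    if len(acc) != n:
        raise ValueError("HR and Acc grids differ in length")
    if wpt_hr.shape != (N_WPT_BANDS, n) or wpt_acc.shape != (N_WPT_BANDS, n):
        raise ValueError(f"wavelet packet blocks must be ({N_WPT_BANDS}, n)")
    if coherence.shape != (N_COH_LEVELS, n):
        raise ValueError(f"coherence block must be ({N_COH_LEVELS}, n)")
    cp_bin, duration, latency = covariates

    cols: dict[str, np.ndarray] = {
        "HR": hr.values,
        "Acc": acc.values,
    }
    for i in range(N_WPT_BANDS):
        cols[f"WPT-HR-{i + 1}"] = wpt_hr[i]
    for i in range(N_WPT_BANDS):
        cols[f"WPT-Acc-{i + 1}"] = wpt_acc[i]
    for i in range(N_COH_LEVELS):
        cols[f"LSW-HR-Acc-{i + 1}"] = coherence[i]
    cols["SDRR"] = np.full(n, sdrr_s)
    cols["CPbinary"] = cp_bin
    cols["Duration"] = duration
    cols["Latency"] = latency
    cols["Age"] = np.full(n, float(age_months))

    mask = hr.gap_mask | acc.gap_mask
    df = pd.DataFrame({name: cols[name] for name in FEATURE_NAMES})
    # gap-filled transform values are defined everywhere; the raw HR/Acc
    # columns may be NaN inside gaps, which masked rows absorb
    df.loc[mask, :] = df.loc[mask, :].fillna(0.0)
    df.loc[mask, ["HR", "Acc"]] = 0.0
    return FeatureMatrix(hr.times, df, mask, labels, session_id)
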