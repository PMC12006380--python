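"""Session I/O, signal conditioning and heart-rate extraction.

The wearable device records a single-lead ECG (mV) and a triaxial
accelerometer (raw counts), both at 500 Hz.  This module turns those raw
channels into the two substrates everything downstream consumes:

* a :class:`BeatSeries` of R-peak times with per-interval instantaneous
  heart rate, ``HR (bpm) = 60 / IBI``;
* :class:`UniformSeries` objects on the common 2 Hz analysis grid, with an
  explicit gap mask for spans where the device lost connection or no beat
  could be detected.

Accelerometer counts are centred by subtracting 2**15 and scaled by 1/5000
before taking the per-sample Euclidean magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import median_filter, uniform_filter1d

__all__ = [
    "RawSession",
    "BeatSeries",
    "UniformSeries",
    "SessionRecord",
    "preprocess_acc",
    "detect_rpeaks",
    "correct_beats",
    "hr_series",
    "resample_2hz",
    "acc_to_grid",
    "read_session_csv",
    "read_gaps_csv",
    "write_beats_csv",
    "read_beats_csv",
    "write_uniform_csv",
    "read_uniform_csv",
    "ingest_session",
]

ACC_CENTRE = 2**15
ACC_SCALE = 5000.0
ANALYSIS_RATE_HZ = 2.0
#: spans longer than this without a detected beat are masked as data gaps
MAX_BEATLESS_SPAN_S = 3.0


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class RawSession:
    """One recording session of raw 500 Hz sensor channels."""

    session_id: str
    age_months: float
    rate_hz: float
    ecg: np.ndarray
    acc_xyz: np.ndarray  # shape (3, n)
    start_time: float = 0.0
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.acc_xyz = np.asarray(self.acc_xyz, dtype=float)
        if self.acc_xyz.shape != (3, self.ecg.size):
            raise ValueError("ECG and accelerometer channels must share one length")
        if self.age_months <= 0:
            raise ValueError("age_months must be positive")

    @property
    def duration_s(self) -> float:
        return self.ecg.size / self.rate_hz


@dataclass
class BeatSeries:
    """R-peak times with derived inter-beat intervals and instantaneous HR.

    ``flags`` marks each peak as original (0) or interpolated during
    artifact correction (1).
    """

    peak_times: np.ndarray
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.peak_times.size, dtype=int)
        self.flags = np.asarray(self.flags, dtype=int)
        if self.flags.size != self.peak_times.size:
            raise ValueError("flags must align with peak_times")
        if self.peak_times.size and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.peak_times.size)

    @property
    def ibi(self) -> np.ndarray:
        """Inter-beat intervals in seconds (one fewer than peaks)."""
        return np.diff(self.peak_times)

    @property
    def hr_bpm(self) -> np.ndarray:
        """Instantaneous HR per interval, 60 / IBI."""
        return 60.0 / self.ibi

    @property
    def hr_times(self) -> np.ndarray:
        """Time stamp of each HR value: the later peak of its interval."""
        return self.peak_times[1:]


@dataclass
class UniformSeries:
    """Regularly sampled series with a boolean gap mask (True = no data)."""

    t0: float
    rate_hz: float
    values: np.ndarray
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.size, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.size != self.values.size:
            raise ValueError("gap_mask must align with values")
        if np.any(~np.isfinite(self.values[~self.gap_mask])):
            raise ValueError("values must be finite outside gaps")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate_hz

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class SessionRecord:
    """Preprocessed session: the input unit of the ASAP chain."""

    session_id: str
    age_months: float
    beats: BeatSeries
    acc_2hz: UniformSeries
    duration_s: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def preprocess_acc(acc_xyz: np.ndarray) -> np.ndarray:
    """Centred/scaled triaxial magnitude: ||(counts - 2**15) / 5000||_2."""
    acc = np.asarray(acc_xyz, dtype=float)
    if acc.ndim != 2 or acc.shape[0] != 3:
        raise ValueError("acc_xyz must have shape (3, n)")
    scaled = (acc - ACC_CENTRE) / ACC_SCALE
    return np.sqrt(np.sum(scaled**2, axis=0))


def detect_rpeaks(ecg: np.ndarray, rate_hz: float, t0: float = 0.0) -> BeatSeries:
    """Detect QRS complexes with a filtered-energy (Pan–Tompkins style) scheme.

    Band-passes the ECG, squares it, integrates over a 100 ms window and
    thresholds the envelope; each detection is then refined to the local
    maximum of the filtered signal.
    """
    ecg = np.asarray(ecg, dtype=float)
    if rate_hz < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    if ecg.size < 2 * rate_hz:
        raise ValueError("need at least 2 s of ECG")
    if np.ptp(ecg) == 0:
        raise ValueError("no peaks found: flat signal")

    high = min(45.0, 0.45 * rate_hz)
    sos = sps.butter(3, [5.0, high], btype="bandpass", fs=rate_hz, output="sos")
    filt = sps.sosfiltfilt(sos, ecg)
    energy = uniform_filter1d(filt**2, size=max(3, int(round(0.10 * rate_hz))))

    height = max(4.0 * float(np.median(energy)), 0.15 * float(np.max(energy)))
    min_dist = max(1, int(round(0.20 * rate_hz)))  # refractory, < 300 bpm
    locs, _ = sps.find_peaks(energy, height=height, distance=min_dist)
    if locs.size == 0:
        raise ValueError("no peaks found")

    # refine each detection to the nearby extremum of the band-passed signal
    half = int(round(0.05 * rate_hz))
    refined = np.empty(locs.size, dtype=int)
    for i, loc in enumerate(locs):
        lo, hi = max(0, loc - half), min(ecg.size, loc + half + 1)
        refined[i] = lo + int(np.argmax(np.abs(filt[lo:hi])))
    refined = np.unique(refined)
    return BeatSeries(peak_times=t0 + refined / rate_hz)


def correct_beats(
    beats: BeatSeries,
    bounds: tuple[float, float] = (60.0, 250.0),
    max_jump: float = 0.4,
    max_passes: int = 4,
) -> BeatSeries:
    """Physiologic-bounds and local-median artifact filter.

    Beats implying HR outside ``bounds`` or an IBI deviating from the local
    median IBI by more than ``max_jump`` (fraction) are treated as artifacts:
    spuriously short intervals drop the intervening peak, long intervals
    (missed beats) are filled with linearly interpolated peaks.  Interpolated
    peaks carry flag 1.
    """
    if beats.n_beats < 3:
        raise ValueError("need at least 3 beats to correct")
    lo_bpm, hi_bpm = bounds

    hr0 = beats.hr_bpm
    if np.all((hr0 < lo_bpm) | (hr0 > hi_bpm)):
        raise ValueError("all beats outside physiologic bounds")

    times = beats.peak_times.copy()
    flags = beats.flags.copy()

    for _ in range(max_passes):
        ibi = np.diff(times)
        if ibi.size < 1:
            break
        loc_med = median_filter(ibi, size=min(11, 2 * (ibi.size // 2) + 1), mode="nearest")
        short = (ibi < (1 - max_jump) * loc_med) | (60.0 / ibi > hi_bpm)
        long_ = (ibi > (1 + max_jump) * loc_med) | (60.0 / ibi < lo_bpm)
        if not (short.any() or long_.any()):
            break
        if short.any():
            # an ectopic/spurious peak splits one beat in two: drop the
            # interior peak of the first offending short interval
            k = int(np.argmax(short))
            drop = k + 1 if k + 1 < times.size - 1 else k
            times = np.delete(times, drop)
            flags = np.delete(flags, drop)
            continue
        k = int(np.argmax(long_))
        n_missing = max(1, int(round(ibi[k] / loc_med[k])) - 1)
        new = np.linspace(times[k], times[k + 1], n_missing + 2)[1:-1]
        times = np.insert(times, k + 1, new)
        flags = np.insert(flags, k + 1, np.ones(new.size, dtype=int))

    return BeatSeries(peak_times=times, flags=flags)


def hr_series(beats: BeatSeries) -> tuple[np.ndarray, np.ndarray]:
    """Beat-indexed instantaneous HR, stamped at the later peak of each IBI."""
    if beats.n_beats < 2:
        raise ValueError("need at least 2 peaks for an HR series")
    return beats.hr_times, beats.hr_bpm


def _declared_gap_mask(times: np.ndarray, gaps: list[tuple[float, float]] | None) -> np.ndarray:
    mask = np.zeros(times.size, dtype=bool)
    for start, end in gaps or []:
        mask |= (times >= start) & (times < end)
    return mask


def resample_2hz(
    times: np.ndarray,
    values: np.ndarray,
    gaps: list[tuple[float, float]] | None = None,
    span: tuple[float, float] | None = None,
    rate_hz: float = ANALYSIS_RATE_HZ,
    max_beatless_span_s: float = MAX_BEATLESS_SPAN_S,
) -> UniformSeries:
    """Linear interpolation of time-stamped values onto the 2 Hz grid.

    Grid points inside declared gaps, inside spans of more than
    ``max_beatless_span_s`` without an observation, or outside the observed
    range, are masked.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty input series")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time stamps must be increasing")

    t_start, t_end = span if span is not None else (times[0], times[-1])
    grid = np.arange(t_start, t_end + 0.5 / rate_hz, 1.0 / rate_hz)
    vals = np.interp(grid, times, values)

    mask = _declared_gap_mask(grid, gaps)
    mask |= (grid < times[0]) | (grid > times[-1])
    # spans with no underlying observation for too long
    big = np.flatnonzero(np.diff(times) > max_beatless_span_s)
    for k in big:
        mask |= (grid > times[k]) & (grid < times[k + 1])
    vals = np.where(mask, np.nan, vals)
    return UniformSeries(t0=t_start, rate_hz=rate_hz, values=vals, gap_mask=mask)


def acc_to_grid(
    acc_mag: np.ndarray,
    rate_hz: float,
    gaps: list[tuple[float, float]] | None = None,
    t0: float = 0.0,
    out_rate_hz: float = ANALYSIS_RATE_HZ,
) -> UniformSeries:
    """Average the acceleration magnitude within each 0.5 s analysis bin."""
    acc_mag = np.asarray(acc_mag, dtype=float)
    if acc_mag.size == 0:
        raise ValueError("empty accelerometer series")
    per_bin = int(round(rate_hz / out_rate_hz))
    n_bins = acc_mag.size // per_bin
    binned = acc_mag[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    grid_t = t0 + np.arange(n_bins) / out_rate_hz
    mask = _declared_gap_mask(grid_t, gaps)
    return UniformSeries(t0=t0, rate_hz=out_rate_hz, values=np.where(mask, np.nan, binned), gap_mask=mask)


# ---------------------------------------------------------------------------
# file I/O (delimited text)
# ---------------------------------------------------------------------------


def read_session_csv(path: str | Path, session_id: str | None = None, age_months: float = 12.0) -> RawSession:
    """Read a session from delimited text: time_s, ecg_mv, acc_x, acc_y, acc_z."""
    df = pd.read_csv(path)
    required = ["time_s", "ecg_mv", "acc_x", "acc_y", "acc_z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"session file missing columns: {missing}")
    t = df["time_s"].to_numpy(float)
    rate = 1.0 / float(np.median(np.diff(t)))
    return RawSession(
        session_id=session_id or Path(path).stem,
        age_months=age_months,
        rate_hz=rate,
        ecg=df["ecg_mv"].to_numpy(float),
        acc_xyz=df[["acc_x", "acc_y", "acc_z"]].to_numpy(float).T,
        start_time=float(t[0]),
    )


def read_gaps_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return [(float(r.start_s), float(r.end_s)) for r in df.itertuples()]


def write_beats_csv(beats: BeatSeries, path: str | Path) -> None:
    ibi = np.concatenate([[np.nan], beats.ibi])
    hr = np.concatenate([[np.nan], beats.hr_bpm])
    pd.DataFrame(
        {"peak_time_s": beats.peak_times, "ibi_s": ibi, "hr_bpm": hr, "flag": beats.flags}
    ).to_csv(path, index=False)


def read_beats_csv(path: str | Path) -> BeatSeries:
    df = pd.read_csv(path)
    return BeatSeries(df["peak_time_s"].to_numpy(float), df["flag"].to_numpy(int))


def write_uniform_csv(series: UniformSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": series.times, "value": series.values, "gap": series.gap_mask.astype(int)}
    ).to_csv(path, index=False)


def read_uniform_csv(path: str | Path) -> UniformSeries:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    rate = 1.0 / float(np.median(np.diff(t)))
    return UniformSeries(float(t[0]), rate, df["value"].to_numpy(float), df["gap"].to_numpy(bool))


def ingest_session(raw: RawSession) -> SessionRecord:
    """Full preprocessing path: acc magnitude, R-peaks, artifact correction."""
    acc_mag = preprocess_acc(raw.acc_xyz)
    beats = detect_rpeaks(raw.ecg, raw.rate_hz, t0=raw.start_time)
    beats = correct_beats(beats)
    acc = acc_to_grid(acc_mag, raw.rate_hz, gaps=raw.gaps, t0=raw.start_time)
    return SessionRecord(
        session_id=raw.session_id,
        age_months=raw.age_months,
        beats=beats,
        acc_2hz=acc,
        duration_s=raw.duration_s,
    )
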