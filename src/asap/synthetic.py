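"""Synthetic session generator.

Produces fully specified sessions with the statistical structure the
detection method assumes: infant beat-to-beat heart rate with two HRV
spectral bands (defaults 0.03–0.15 Hz and 0.3–0.6 Hz), sustained-attention
episodes expressed as >= 5 bpm step decelerations lasting 2–20 s with
raised-cosine transitions, movement magnitude suppressed during attention
and coupled to HR through a shared slow (< 0.1 Hz) component, and a
session attention prevalence near 0.29.  Optionally synthesises a raw
500 Hz ECG trace and an egocentric map/fixation stream with a planted
saliency effect.

Everything is deterministic under (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats
from scipy.ndimage import gaussian_filter, uniform_filter1d

from .io_signals import BeatSeries, SessionRecord, UniformSeries, acc_to_grid
from .screening import AttentionIntervals

__all__ = ["SimParams", "SyntheticSession", "simulate_session", "synthesize_ecg", "simulate_egocentric"]

_INTERNAL_FS = 8.0  # Hz; waveform construction grid
TARGET_PREVALENCE = 0.29


def _age_to_base_hr(age_months: float) -> float:
    """Linear infant baseline: 140 bpm at 6 months to 110 bpm at 36 months."""
    return float(np.clip(140.0 - (age_months - 6.0), 105.0, 145.0))


def _truncated_lognormal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    mass = stats.norm.cdf(b) - stats.norm.cdf(a)
    shifted = stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)
    return float(np.exp(mu + sigma**2 / 2) * shifted / mass)


@dataclass
class SimParams:
    """Generation parameters; defaults are the study-like conditions."""

    age_months: float = 12.0
    duration_s: float = 1800.0
    base_hr: float | None = None  # bpm; age map when None
    sa_rate: float | None = None  # episodes / min; prevalence-derived when None
    sa_duration_mu: float = float(np.log(8.0))  # log-seconds
    sa_duration_sigma: float = 0.55
    sa_duration_range: tuple[float, float] = (2.0, 20.0)
    sa_depth_range: tuple[float, float] = (5.0, 15.0)  # bpm, uniform
    hrv_bands: tuple[tuple[float, float], tuple[float, float]] = ((0.03, 0.15), (0.3, 0.6))
    hrv_band_rms: tuple[float, float] = (2.5, 1.5)  # bpm
    acc_coupling: float = 0.3  # sub-0.1 Hz shared-component gain into HR (bpm)
    movement_suppression: float = 0.5  # fractional Acc reduction during SA
    noise_sd: float = 1.0  # bpm white noise on the HR target
    hr_jump_rate: float = 0.3  # mean-shift micro-jumps per second
    hr_jump_sd: float = 2.5  # bpm jump innovation scale
    hr_jump_ar: float = 0.6  # mean reversion of the jump level
    ramp_s: float = 1.5  # raised-cosine transition length
    refractory_s: float = 5.0  # minimum gap after each episode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_hr is None:
            self.base_hr = _age_to_base_hr(self.age_months)
        if self.sa_rate is None:
            mean_dur = self.mean_sa_duration()
            self.sa_rate = 60.0 * TARGET_PREVALENCE / mean_dur
        cycle = 60.0 / self.sa_rate
        if cycle - self.mean_sa_duration() - self.refractory_s <= 0:
            raise ValueError("infeasible SA prevalence: rate x duration too high")
        if self.sa_depth_range[0] < 5.0:
            raise ValueError("sa_depth below the 5 bpm screening floor")
        if self.sa_duration_range[0] < 2.0:
            raise ValueError("sa durations must be at least 2 s")

    def mean_sa_duration(self) -> float:
        return _truncated_lognormal_mean(
            self.sa_duration_mu, self.sa_duration_sigma, *self.sa_duration_range
        )


@dataclass
class SyntheticSession:
    beats: BeatSeries
    acc_mag: UniformSeries
    truth: AttentionIntervals
    params: SimParams
    session_id: str = "sim"
    ecg: np.ndarray | None = None
    ecg_rate_hz: float = 500.0
    hr_profile: tuple[np.ndarray, np.ndarray] | None = None  # (t, bpm) target
    depths: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_record(self) -> SessionRecord:
        return SessionRecord(
            session_id=self.session_id,
            age_months=self.params.age_months,
            beats=self.beats,
            acc_2hz=self.acc_mag,
            duration_s=self.params.duration_s,
        )


def _band_noise(rng, n: int, fs: float, band: tuple[float, float], rms: float) -> np.ndarray:
    white = rng.standard_normal(n)
    lo, hi = band
    sos = sps.butter(4, [lo, min(hi, 0.49 * fs)], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _slow_component(rng, n: int, fs: float, cutoff: float = 0.1) -> np.ndarray:
    sos = sps.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _draw_episodes(rng, p: SimParams) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Poisson-like arrivals with refractory gap; durations trunc-lognormal."""
    mean_gap = 60.0 / p.sa_rate - p.mean_sa_duration() - p.refractory_s
    lo, hi = p.sa_duration_range
    episodes: list[tuple[float, float]] = []
    depths: list[float] = []
    t = p.ramp_s + rng.exponential(mean_gap)
    while True:
        while True:  # truncated lognormal duration by rejection
            dur = float(rng.lognormal(p.sa_duration_mu, p.sa_duration_sigma))
            if lo <= dur <= hi:
                break
        end = t + dur
        if end > p.duration_s - p.ramp_s:
            break
        episodes.append((t, end))
        depths.append(float(rng.uniform(*p.sa_depth_range)))
        t = end + p.refractory_s + rng.exponential(mean_gap)
    return episodes, np.asarray(depths)


def _sa_profile(tgrid: np.ndarray, episodes, depths, ramp_s: float) -> np.ndarray:
    """0→depth raised-cosine deceleration profile; full depth inside episodes."""
    prof = np.zeros(tgrid.size)
    for (on, off), depth in zip(episodes, depths):
        ramp_in = (tgrid >= on - ramp_s) & (tgrid < on)
        ramp_out = (tgrid >= off) & (tgrid < off + ramp_s)
        inside = (tgrid >= on) & (tgrid < off)
        prof[inside] = np.maximum(prof[inside], depth)
        prof[ramp_in] = np.maximum(
            prof[ramp_in], depth * 0.5 * (1 - np.cos(np.pi * (tgrid[ramp_in] - on + ramp_s) / ramp_s))
        )
        prof[ramp_out] = np.maximum(
            prof[ramp_out], depth * 0.5 * (1 + np.cos(np.pi * (tgrid[ramp_out] - off) / ramp_s))
        )
    return prof


def _jump_process(rng, n: int, fs: float, rate: float, sd: float, ar: float) -> np.ndarray:
    """Piecewise-constant mean-reverting level shifts.

    Emulates the jagged beat-scale texture of infant HR: abrupt small mean
    shifts every few heartbeats, which is what gives change-point detection
    its characteristic per-heartbeat rate on real recordings.
    """
    level = np.zeros(n)
    if rate <= 0 or sd <= 0:
        return level
    cur = 0.0
    i = 0
    while i < n:
        nxt = i + max(1, int(round(rng.exponential(1.0 / rate) * fs)))
        level[i:nxt] = cur
        cur = ar * cur + rng.normal(0.0, sd)
        i = nxt
    return level


def simulate_session(params: SimParams | None = None, **overrides) -> SyntheticSession:
    """Generate one synthetic session (deterministic under params.seed)."""
    p = params if params is not None else SimParams(**overrides)
    rng = np.random.default_rng(p.seed)
    fs = _INTERNAL_FS
    n = int(round(p.duration_s * fs))
    tgrid = np.arange(n) / fs

    episodes, depths = _draw_episodes(rng, p)
    sa_prof = _sa_profile(tgrid, episodes, depths, p.ramp_s)
    sa_frac = np.clip(sa_prof / np.maximum(depths.max(), 1.0), 0, 1) if depths.size else np.zeros(n)

    lf = _band_noise(rng, n, fs, p.hrv_bands[0], p.hrv_band_rms[0])
    hf = _band_noise(rng, n, fs, p.hrv_bands[1], p.hrv_band_rms[1])
    shared = _slow_component(rng, n, fs)
    jumps = _jump_process(rng, n, fs, p.hr_jump_rate, p.hr_jump_sd, p.hr_jump_ar)
    hr_t = (
        p.base_hr + lf + hf + p.acc_coupling * 3.0 * shared - sa_prof + jumps
        + p.noise_sd * rng.standard_normal(n)
    )
    hr_t = np.clip(hr_t, 60.0, 240.0)

    # beat train by integrating the instantaneous rate
    beat_rate = hr_t / 60.0  # beats per second
    cum = np.concatenate([[0.0], np.cumsum((beat_rate[1:] + beat_rate[:-1]) / 2) / fs])
    n_beats = int(np.floor(cum[-1]))
    peak_times = np.interp(np.arange(1, n_beats + 1), cum, tgrid)
    beats = BeatSeries(peak_times=np.unique(peak_times))

    # movement: bursty envelope, suppressed during SA, sharing the slow drive
    burst = uniform_filter1d(np.abs(rng.standard_normal(n)), int(2 * fs))
    burst = burst / max(burst.std(), 1e-12)
    envelope = 0.08 + 0.25 * np.abs(burst) + 0.10 * np.abs(shared + 1.0)
    envelope *= 1.0 - p.movement_suppression * sa_frac
    envelope += 0.05 * shared  # signed shared part drives the HR coupling
    acc = np.abs(envelope)
    acc_series = acc_to_grid(acc, rate_hz=fs, t0=0.0)

    truth = AttentionIntervals(episodes, source="truth", session_id=f"sim-{p.seed}")
    return SyntheticSession(
        beats=beats,
        acc_mag=acc_series,
        truth=truth,
        params=p,
        session_id=f"sim-{p.seed}",
        hr_profile=(tgrid, hr_t),
        depths=depths,
    )


def synthesize_ecg(
    beats: BeatSeries,
    rate_hz: float = 500.0,
    snr: float = 20.0,
    duration_s: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Template ECG: a narrow Gaussian R-wave at each beat plus white noise.

    ``snr`` is the ratio of R-wave amplitude to the noise standard
    deviation.  A zero-beat series yields a flat noise trace.
    """
    rng = np.random.default_rng(seed)
    end = duration_s if duration_s is not None else (
        float(beats.peak_times[-1]) + 1.0 if beats.n_beats else 1.0
    )
    n = int(round(end * rate_hz))
    t = np.arange(n) / rate_hz
    ecg = np.zeros(n)
    width = 0.012  # s, R-wave half-width
    for pt in beats.peak_times:
        lo = max(0, int((pt - 5 * width) * rate_hz))
        hi = min(n, int((pt + 5 * width) * rate_hz) + 1)
        ecg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - pt) / width) ** 2)
    noise_sd = 1.0 / max(snr, 1e-9)
    return ecg + noise_sd * rng.standard_normal(n)


def simulate_egocentric(
    session: SyntheticSession,
    effect: float = 0.5,
    frame_rate: float = 3.0,
    frame_size: tuple[int, int] = (160, 120),
    mask_radius: int = 20,
    n_objects: int = 12,
    seed: int = 0,
):
    """Per-frame smooth scalar maps and a fixation stream.

    During truth-SA windows, the disc of radius ``mask_radius`` around each
    fixation carries map values elevated by ``effect`` within-frame
    standard deviations of the disc-averaged field — the scale at which the
    analysis pipeline measures fixated saliency.  Fixations always last
    longer than 100 ms.  Returns ``(maps, frame_times, fixations)`` with
    ``maps`` of shape (n_frames, height, width) and fixations as
    ``(start_s, end_s, x_px, y_px, label)`` tuples.
    """
    if len(session.truth) == 0:
        raise ValueError("session has no truth intervals")
    rng = np.random.default_rng(seed)
    w, h = frame_size
    dur = session.params.duration_s
    n_frames = int(np.floor(dur * frame_rate))
    frame_times = np.arange(n_frames) / frame_rate

    coarse = rng.standard_normal((n_frames, max(2, h // 8), max(2, w // 8))).astype(np.float32)
    # egocentric scenes persist over seconds: temporal AR-like smoothing so a
    # fixated region keeps its value across the frames of a window
    coarse = gaussian_filter(coarse, sigma=(2.0 * frame_rate, 0, 0))
    maps = np.empty((n_frames, h, w), dtype=np.float32)
    disc = np.empty_like(maps)  # disc-scale smoothed field for placement
    for f in range(n_frames):
        up = np.kron(coarse[f], np.ones((8, 8), dtype=np.float32))[:h, :w]
        maps[f] = gaussian_filter(up, sigma=6.0)
        disc[f] = gaussian_filter(maps[f], sigma=mask_radius / 2.0)

    margin = min(mask_radius, w // 4, h // 4)
    fixations: list[tuple[float, float, int, int, int]] = []
    t = float(rng.uniform(0.0, 0.3))
    while t < dur - 0.2:
        fix_dur = float(np.clip(0.12 + rng.exponential(0.25), 0.101, 2.0))
        f = min(int(t * frame_rate), n_frames - 1)
        field = disc[f]
        mu, sd = float(field.mean()), float(field.std())
        in_sa = bool(session.truth.contains(np.array([t]))[0])
        target = mu + (effect * sd if in_sa else 0.0)
        xs = rng.integers(margin, w - margin, size=128)
        ys = rng.integers(margin, h - margin, size=128)
        j = int(np.argmin(np.abs(field[ys, xs] - target)))
        label = int(rng.integers(0, n_objects))
        fixations.append((t, t + fix_dur, int(xs[j]), int(ys[j]), label))
        t += fix_dur + 0.05 + float(rng.exponential(0.15))
    return maps, frame_times, fixations
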