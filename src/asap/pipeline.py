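"""The full three-step detection chain as a composing estimator.

:class:`AsapDetector` takes preprocessed sessions (beat series plus 2 Hz
acceleration magnitude), runs change-point segmentation and screening
(Step 1), builds the 51-feature matrix and fits the point-wise classifier
against reference attention intervals (Step 2), and refines predictions to
restore temporal structure (Step 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import changepoint as cpd
from . import features as feat
from . import refine as refine_mod
from . import screening
from .classifier import SustainedAttentionClassifier
from .io_signals import SessionRecord, UniformSeries, hr_series, resample_2hz
from .screening import AttentionIntervals

__all__ = ["SessionFeatures", "AsapDetector", "binary_to_intervals"]


def binary_to_intervals(series: UniformSeries, source: str, session_id: str = "") -> AttentionIntervals:
    """Contiguous positive runs of a binary 2 Hz series as intervals."""
    vals = np.nan_to_num(series.values, nan=0.0) >= 0.5
    t = series.times
    step = 1.0 / series.rate_hz
    out = []
    start = None
    for i, v in enumerate(vals):
        if v and start is None:
            start = t[i]
        elif not v and start is not None:
            out.append((start, t[i]))
            start = None
    if start is not None:
        out.append((start, t[-1] + step))
    return AttentionIntervals(out, source=source, session_id=session_id)


@dataclass
class SessionFeatures:
    """Everything Step 1 + feature extraction derive from one session."""

    record: SessionRecord
    segmentation: cpd.ChangePointSegmentation
    step1: AttentionIntervals
    hr_grid: UniformSeries
    matrix: feat.FeatureMatrix


class AsapDetector(BaseEstimator):
    """End-to-end sustained-attention detector.

    Parameters mirror the three stages: WBS2/SDLL change-point detection on
    the beat-indexed HR (``n_intervals``, ``min_seg``, ``sdll_c``), the
    screening thresholds (fixed to the coding-protocol values), the Step-2
    classifier (``threshold``, ``lam``, ``smote``), and Step-3 refinement
    (``max_gap``, ``coverage``, ``cap``).
    """

    def __init__(
        self,
        n_intervals: int = 100,
        min_seg: int = 2,
        sdll_c: float = 1.3,
        threshold: float = 0.03,
        lam: float | str = "auto",
        n_folds: int = 5,
        smote: bool = True,
        max_gap: float = 2.5,
        coverage: float = 0.9,
        cap: float = 50.0,
        random_state: int = 0,
    ):
        self.n_intervals = n_intervals
        self.min_seg = min_seg
        self.sdll_c = sdll_c
        self.threshold = threshold
        self.lam = lam
        self.n_folds = n_folds
        self.smote = smote
        self.max_gap = max_gap
        self.coverage = coverage
        self.cap = cap
        self.random_state = random_state

    # ------------------------------------------------------------------
    def process_session(self, record: SessionRecord, truth: AttentionIntervals | None = None) -> SessionFeatures:
        """Step 1 and feature extraction for one session."""
        beats = record.beats
        seg = cpd.detect_changepoints(
            beats,
            n_intervals=self.n_intervals,
            min_seg=self.min_seg,
            sdll_c=self.sdll_c,
            seed=self.random_state,
        )
        step1 = screening.screen_sa(seg, beats, session_id=record.session_id)

        times, hr = hr_series(beats)
        span = (record.acc_2hz.t0, record.acc_2hz.times[-1])
        hr_grid = resample_2hz(times, hr, span=span)
        acc_grid = record.acc_2hz
        n = min(len(hr_grid), len(acc_grid))
        hr_grid = UniformSeries(hr_grid.t0, hr_grid.rate_hz, hr_grid.values[:n], hr_grid.gap_mask[:n])
        acc_grid = UniformSeries(acc_grid.t0, acc_grid.rate_hz, acc_grid.values[:n], acc_grid.gap_mask[:n])

        wpt_hr = feat.modwpt_bands(hr_grid)
        wpt_acc = feat.modwpt_bands(acc_grid)
        coh = feat.lsw_coherence(hr_grid, acc_grid)
        covars = feat.segment_covariates(step1, hr_grid)
        labels = None
        if truth is not None:
            labels = truth.contains(hr_grid.times).astype(int)
        matrix = feat.assemble(
            hr_grid, acc_grid, wpt_hr, wpt_acc, coh,
            feat.sdrr(beats), covars, record.age_months,
            labels=labels, session_id=record.session_id,
        )
        return SessionFeatures(record, seg, step1, hr_grid, matrix)

    # ------------------------------------------------------------------
    def fit(self, sessions: list[SessionRecord], truths: list[AttentionIntervals]):
        """Train the Step-2 classifier on processed training sessions."""
        if len(sessions) != len(truths):
            raise ValueError("sessions and truths must align")
        processed = [self.process_session(s, t) for s, t in zip(sessions, truths)]
        X = np.vstack([p.matrix.X.to_numpy() for p in processed])
        y = np.concatenate([p.matrix.y for p in processed])
        Xdf = pd.DataFrame(X, columns=list(feat.FEATURE_NAMES))
        self.classifier_ = SustainedAttentionClassifier(
            threshold=self.threshold, lam=self.lam, n_folds=self.n_folds,
            smote=self.smote, random_state=self.random_state,
        ).fit(Xdf, y)
        self.selected_features_ = self.classifier_.selected_features_
        self.lambda_ = self.classifier_.lambda_
        self.train_sessions_ = [s.session_id for s in sessions]
        return self

    # ------------------------------------------------------------------
    def predict_session(self, record: SessionRecord) -> dict:
        """Run all three steps; returns intervals and 2 Hz series per step."""
        sf = self.process_session(record)
        grid = sf.hr_grid
        step1_bin = screening.to_binary(sf.step1, grid)

        out = {
            "session_id": record.session_id,
            "segmentation": sf.segmentation,
            "step1": sf.step1,
            "step1_binary": step1_bin,
            "grid": grid,
            "features": sf.matrix,
        }
        if hasattr(self, "classifier_"):
            proba = self.classifier_.predict_proba(sf.matrix.data)[:, 1]
            labels = (proba >= self.classifier_.decision_threshold).astype(float)
            labels[sf.matrix.row_mask] = np.nan
            step2_bin = UniformSeries(grid.t0, grid.rate_hz, labels, sf.matrix.row_mask.copy())
            step2 = binary_to_intervals(step2_bin, "step2", record.session_id)
            step3 = refine_mod.refine(
                step2, sf.step1, max_gap=self.max_gap, coverage=self.coverage, cap=self.cap
            )
            step3_bin = screening.to_binary(step3, grid)
            out.update(
                step2=step2, step2_binary=step2_bin, step2_proba=proba,
                step3=step3, step3_binary=step3_bin,
            )
        return out

    def predict(self, sessions: list[SessionRecord]) -> list[AttentionIntervals]:
        """Refined (Step-3) attention intervals for each session."""
        return [self.predict_session(s)["step3"] for s in sessions]
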