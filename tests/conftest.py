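"""Shared fixtures.

The expensive end-to-end experiment (20 training + 4 test synthetic
sessions of 30 minutes, full three-step chain) is session-scoped and
shared between the pipeline-level tests; everything else builds its own
small inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

import asap


def beats_from_hr(hr_bpm: np.ndarray, t0: float = 0.0) -> asap.BeatSeries:
    """Beat series whose instantaneous HR equals the given per-interval values."""
    ibis = 60.0 / np.asarray(hr_bpm, dtype=float)
    peaks = t0 + np.concatenate([[0.0], np.cumsum(ibis)])
    return asap.BeatSeries(peak_times=peaks)


@pytest.fixture(scope="session")
def e2e_experiment():
    """Train the full chain on 20 synthetic sessions, predict 4 held-out ones."""
    train = [asap.simulate_session(asap.SimParams(duration_s=1800.0, seed=s)) for s in range(20)]
    test = [asap.simulate_session(asap.SimParams(duration_s=1800.0, seed=100 + s)) for s in range(4)]
    det = asap.AsapDetector(random_state=0)
    det.fit([s.to_record() for s in train], [s.truth for s in train])

    predictions = []
    for sess in test:
        out = det.predict_session(sess.to_record())
        grid = out["grid"]
        truth_series = sess.truth.contains(grid.times).astype(float)
        truth_series[grid.gap_mask] = np.nan
        out["truth"] = sess.truth
        out["truth_binary"] = truth_series
        predictions.append(out)
    return {"detector": det, "train": train, "test": test, "predictions": predictions}
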