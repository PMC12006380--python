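"""Step 3: temporal-structure-preserving refinement of point-wise output.

Point-wise classification fragments long attention spans.  Refinement
first merges predicted segments separated by at most 2.5 s, then promotes
any Step-1 putative SA segment whose predicted coverage exceeds 90 % to a
full SA period — unless promotion would create a contiguous attention span
longer than 50 s, in which case it is vetoed (never truncated).  Both
operations only add positive time, so refined output is a superset of the
input predictions.
"""

from __future__ import annotations

from .screening import AttentionIntervals

__all__ = ["merge_close", "promote", "refine"]

DEFAULT_MAX_GAP_S = 2.5
DEFAULT_COVERAGE = 0.9
DEFAULT_CAP_S = 50.0


def _union(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def merge_close(pred: AttentionIntervals, max_gap: float = DEFAULT_MAX_GAP_S) -> AttentionIntervals:
    """Merge consecutive intervals separated by at most ``max_gap`` seconds."""
    merged: list[tuple[float, float]] = []
    for a, b in pred:
        if merged and a - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return AttentionIntervals(merged, source="step3", session_id=pred.session_id)


def promote(
    pred: AttentionIntervals,
    step1: AttentionIntervals,
    coverage: float = DEFAULT_COVERAGE,
    cap: float = DEFAULT_CAP_S,
) -> AttentionIntervals:
    """Promote well-covered Step-1 SA segments to full SA periods.

    Step-1 segments are considered left-to-right; a segment is promoted when
    predicted-positive time inside it exceeds ``coverage`` of its duration
    and the union with the current prediction creates no contiguous span
    longer than ``cap`` seconds (the cap vetoes, it never truncates).
    """
    current = list(pred.intervals)
    for a, b in step1:
        covered = sum(_overlap(a, b, p0, p1) for p0, p1 in current)
        if covered <= coverage * (b - a):
            continue
        candidate = _union(current + [(a, b)])
        if max((q1 - q0 for q0, q1 in candidate), default=0.0) > cap:
            continue
        current = candidate
    return AttentionIntervals(_union(current), source="step3", session_id=pred.session_id)


def refine(
    pred: AttentionIntervals,
    step1: AttentionIntervals,
    max_gap: float = DEFAULT_MAX_GAP_S,
    coverage: float = DEFAULT_COVERAGE,
    cap: float = DEFAULT_CAP_S,
) -> AttentionIntervals:
    """Full Step 3: merge close segments, then promote covered Step-1 spans."""
    return promote(merge_close(pred, max_gap), step1, coverage, cap)
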