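"""The per-sample detection features J1, J2 and the fused feature J3.

J1 (sum vector magnitude) is the RMS of the sample-to-sample difference of
the three filtered axes -- it responds to impacts:

    J1[k] = sqrt((dax^2 + day^2 + daz^2) / 3)

J2 (standard deviation magnitude) is the RMS across axes of the per-axis
population standard deviation of the first three Kalman states over a 1 s
sliding window (N = 25 samples at 25 Hz) -- it responds to orientation
change:

    J2[k] = sqrt((s1^2 + s2^2 + s3^2) / 3)

J3 fuses them non-linearly through sliding-window maxima (both windows of
length N, since the Kalman states peak later than the raw impact):

    J3[k] = max(J1 window) * max(J2 window)^2

The square prioritizes J2, the more accurate of the two.  A single threshold
on J3 is the fall classifier.  Scaling the raw signal by alpha scales J1 and
J2 by alpha and J3 by alpha^3; all constant conventions (the /3 under the
root, the population std) are absorbed by the trained threshold.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW_N = 25
WARMUP_S = 2.0


@dataclass(frozen=True)
class FeatureFrame:
    """Per-sample feature values at index k."""

    k: int
    J1: float
    J2: float
    J3: float


def j1(delta: np.ndarray) -> float:
    """RMS over the three components of a differenced frame."""
    d = np.asarray(delta, dtype=float)
    return float(np.sqrt(np.mean(d[:3] ** 2)))


def j2(state_window: np.ndarray) -> float:
    """RMS across axes of per-axis population std of Kalman states x1..x3.

    ``state_window`` is an (m, 3) slice of the last m <= N state vectors
    (first three components).  Needs at least 2 samples; returns 0 for fewer.
    """
    w = np.asarray(state_window, dtype=float)
    if w.shape[0] < 2:
        return 0.0
    stds = np.std(w[:, :3], axis=0)  # population (/N) convention
    return float(np.sqrt(np.mean(stds**2)))


def j3(j1_window: np.ndarray, j2_window: np.ndarray) -> float:
    """max of the J1 window times the squared max of the J2 window."""
    return float(np.max(j1_window) * np.max(j2_window) ** 2)


class FeatureExtractor:
    """Streaming computation of J1, J2, J3 with their sliding windows."""

    def __init__(self, window_n: int = WINDOW_N):
        self.window_n = window_n
        self._states: deque[np.ndarray] = deque(maxlen=window_n)
        self._j1w: deque[float] = deque(maxlen=window_n)
        self._j2w: deque[float] = deque(maxlen=window_n)
        self._k = -1

    def push(self, delta: np.ndarray, state: np.ndarray) -> FeatureFrame:
        """Advance one sample: differenced frame + current Kalman state."""
        self._k += 1
        self._states.append(np.asarray(state, dtype=float)[:3])
        v1 = j1(delta)
        v2 = j2(np.array(self._states))
        self._j1w.append(v1)
        self._j2w.append(v2)
        v3 = j3(np.array(self._j1w), np.array(self._j2w))
        return FeatureFrame(k=self._k, J1=v1, J2=v2, J3=v3)

    def run(self, deltas: np.ndarray, states: np.ndarray) -> pd.DataFrame:
        """Batch replay; equals the streaming path sample for sample."""
        rows = [self.push(d, s) for d, s in zip(deltas, states)]
        return pd.DataFrame({
            "J1": [r.J1 for r in rows],
            "J2": [r.J2 for r in rows],
            "J3": [r.J3 for r in rows],
        })


def compose_feature_report(
    feature_candidates: pd.DataFrame,
    labels: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Box-plot style summary supporting the feature-composition recipe.

    ``feature_candidates`` holds one row per file: an ``activity`` column
    plus one column per candidate feature (the per-file maximum of that
    feature); ``labels`` is the per-file fall flag.  Returns per-activity
    quartiles of each candidate and, per candidate, the optimal single-
    feature threshold with its balanced accuracy -- the inputs one inspects
    to pick complementary features, multiply them, and square the stronger.
    """
    from fallkit.evaluate import balanced_accuracy_at, train_threshold

    if "activity" not in feature_candidates.columns:
        raise ValueError("feature_candidates needs an 'activity' column")
    activities = feature_candidates["activity"].unique()
    if len(activities) < 2:
        raise ValueError("need at least 2 activities to compose a report")
    labels = np.asarray(labels, dtype=bool)
    candidates = [c for c in feature_candidates.columns if c != "activity"]
    rows = []
    for feat in candidates:
        scores = feature_candidates[feat].to_numpy(dtype=float)
        thr = train_threshold(scores, labels)
        acc = balanced_accuracy_at(scores, labels, thr)
        for act in activities:
            mask = feature_candidates["activity"] == act
            q1, q2, q3 = np.percentile(scores[mask], [25, 50, 75])
            rows.append(
                {
                    "feature": feat,
                    "activity": act,
                    "q1": q1,
                    "median": q2,
                    "q3": q3,
                    "threshold": thr,
                    "balanced_accuracy": acc,
                }
            )
    return pd.DataFrame(rows)
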