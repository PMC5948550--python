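"""The 4-state identity-transition Kalman smoother.

State-space model (all quantities in ADC bits):

    x[k] = A x[k-1] + eta,    eta ~ N(0, Q)
    y[k] = C x[k]   + eps,    eps ~ N(0, R)

with A = C = I4.  The measurement vector is y = (ax, ay, az, ay - bay):
the three low-pass-filtered axes plus the vertical axis with its running
bias bay removed.  States x1..x3 smooth the orientation (flat during steady
activity, shifting on posture change); x4 recovers a zero-bias
quasi-sinusoid during periodic activities (walk, jog) whose zero crossings
give the gait period.

bay is the mean of the smoothed vertical state x2 over a sliding 1 s
window (25 samples at 25 Hz), updated after every correction step; the
measurement at step k uses the previous step's bay (strictly causal).

Default noise covariances (variances, i.e. squared standard deviations):
Q = 0.001^2 I4 and R = diag(0.05^2, 0.05^2, 0.05^2, 0.01^2).  Small Q and R
flatten the states; scaling both up makes the states track the raw data.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from fallkit.io import BITS_PER_G

N_STATES = 4
BIAS_WINDOW = 25  # samples (1 s at 25 Hz)
REST_VERTICAL_BITS = -256.0  # -1 G on the vertical axis at upright rest


def default_noise() -> tuple[np.ndarray, np.ndarray]:
    """Default (Q, R): variances (0.001^2) I4 and diag(0.05^2 x3, 0.01^2)."""
    q = (0.001**2) * np.eye(N_STATES)
    r = np.diag([0.05**2, 0.05**2, 0.05**2, 0.01**2])
    return q, r


def _check_psd(m: np.ndarray, name: str) -> None:
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(m)
    if eigvals.min() < -1e-12:
        raise ValueError(f"{name} must be positive semi-definite")


@dataclass
class KalmanConfig:
    """Model matrices and initial conditions.

    ``init`` selects the initialization heuristic: "rest" seeds the vertical
    state and bias at -1 G (-256 bits) for fast convergence; "zero" is the
    uninformative prior (x0 = 0, P0 = Q).
    """

    A: np.ndarray = field(default_factory=lambda: np.eye(N_STATES))
    C: np.ndarray = field(default_factory=lambda: np.eye(N_STATES))
    Q: np.ndarray = field(default_factory=lambda: default_noise()[0])
    R: np.ndarray = field(default_factory=lambda: default_noise()[1])
    init: str = "rest"
    bias_window: int = BIAS_WINDOW

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        _check_psd(self.Q, "Q")
        _check_psd(self.R, "R")
        if self.init not in ("rest", "zero"):
            raise ValueError("init must be 'rest' or 'zero'")

    def x0(self) -> np.ndarray:
        if self.init == "rest":
            return np.array([0.0, REST_VERTICAL_BITS, 0.0, 0.0])
        return np.zeros(N_STATES)


@dataclass
class KalmanState:
    """Current estimate: state vector x, covariance P, last gain G."""

    x: np.ndarray
    P: np.ndarray
    G: np.ndarray | None = None


class BiasTracker:
    """Sliding 1 s mean of the smoothed vertical state x2."""

    def __init__(self, window: int = BIAS_WINDOW, initial: float = REST_VERTICAL_BITS):
        self._buf: deque[float] = deque(maxlen=window)
        self._buf.append(float(initial))

    @property
    def bay(self) -> float:
        return float(np.mean(self._buf))

    def push(self, x2: float) -> None:
        self._buf.append(float(x2))

    def __len__(self) -> int:
        return len(self._buf)


def kalman_init(config: KalmanConfig | None = None) -> tuple[KalmanState, BiasTracker]:
    """Initial state (x0, P0 = Q) and bias tracker seeded from x0's vertical."""
    if config is None:
        config = KalmanConfig()
    x0 = config.x0()
    state = KalmanState(x=x0.copy(), P=config.Q.copy())
    tracker = BiasTracker(window=config.bias_window, initial=x0[1])
    return state, tracker


def kalman_step(
    state: KalmanState,
    tracker: BiasTracker,
    measurement: np.ndarray,
    config: KalmanConfig,
) -> KalmanState:
    """One predict/correct cycle on a filtered frame (ax, ay, az).

    Assembles y = (ax, ay, az, ay - bay) with the tracker's current bias,
    applies the standard Kalman recursions, re-symmetrizes P, then pushes the
    updated vertical state into the bias tracker.
    """
    measurement = np.asarray(measurement, dtype=float)
    y = np.array(
        [measurement[0], measurement[1], measurement[2], measurement[1] - tracker.bay]
    )
    A, C, Q, R = config.A, config.C, config.Q, config.R
    x_pred = A @ state.x
    p_pred = A @ state.P @ A.T + Q
    innov_cov = C @ p_pred @ C.T + R
    gain = p_pred @ C.T @ np.linalg.inv(innov_cov)
    x_new = x_pred + gain @ (y - C @ x_pred)
    p_new = (np.eye(N_STATES) - gain @ C) @ p_pred
    p_new = 0.5 * (p_new + p_new.T)
    state.x = x_new
    state.P = p_new
    state.G = gain
    tracker.push(x_new[1])
    return state


class KalmanFilter:
    """Convenience streaming wrapper around the step function."""

    def __init__(self, config: KalmanConfig | None = None):
        self.config = config if config is not None else KalmanConfig()
        self.state, self.tracker = kalman_init(self.config)

    def step(self, measurement: np.ndarray) -> np.ndarray:
        kalman_step(self.state, self.tracker, measurement, self.config)
        return self.state.x.copy()

    def run(self, frames: np.ndarray) -> np.ndarray:
        """Filter an (n, 3) array of filtered frames; returns (n, 4) states."""
        frames = np.asarray(frames, dtype=float)
        out = np.empty((frames.shape[0], N_STATES))
        for k in range(frames.shape[0]):
            out[k] = self.step(frames[k])
        return out


def _zero_crossing_irregularity(x4: np.ndarray) -> float:
    """Coefficient of variation of half-periods of x4 (nan if < 2 crossings)."""
    from fallkit.periodicity import zero_crossings

    crossings = zero_crossings(x4)
    if len(crossings) < 3:
        return float("nan")
    half = np.diff(crossings)
    return float(np.std(half) / np.mean(half))


def tune_heuristic(
    recording_frames: np.ndarray,
    sample_rate: float = 25.0,
    walk_span: tuple[int, int] | None = None,
    scales: tuple[float, ...] = (10.0, 5.0, 2.0),
) -> list[dict]:
    """Advisory noise-tuning schedule: shrink noise std by /10, /5, /2.

    Starting from Q = R = I4, each step divides the per-state standard
    deviations (square roots of the diagonal) of Q and then R by the next
    scale factor, runs the filter over the recording, and reports flatness
    (variance of x1..x3 over the walk span) and sinusoid quality (zero-
    crossing regularity of x4).  Advisory only: it does not auto-select.

    The recording should contain walk and fall segments and span >= 10 s.
    """
    frames = np.asarray(recording_frames, dtype=float)
    if frames.shape[0] / sample_rate < 10.0:
        raise ValueError("recording too short for tuning (< 10 s)")
    if walk_span is None:
        walk_span = (0, frames.shape[0] // 2)
    report: list[dict] = []
    q_std = np.ones(N_STATES)
    r_std = np.ones(N_STATES)
    for scale in scales:
        q_std = q_std / scale
        r_std = r_std / scale
        cfg = KalmanConfig(Q=np.diag(q_std**2), R=np.diag(r_std**2))
        states = KalmanFilter(cfg).run(frames)
        lo, hi = walk_span
        flatness = float(np.mean(np.var(states[lo:hi, :3], axis=0)))
        report.append(
            {
                "scale": scale,
                "q_std": q_std.copy(),
                "r_std": r_std.copy(),
                "flatness_walk": flatness,
                "x4_irregularity": _zero_crossing_irregularity(states[lo:hi, 3]),
            }
        )
    return report
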