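"""Gait-periodicity estimation from x4 zero crossings, and the alarm veto.

During walking or jogging the de-biased vertical Kalman state x4 is a
zero-bias quasi-sinusoid.  Counting samples between consecutive sign changes
gives half-periods; a full gait cycle spans two consecutive half-periods.
A candidate fall is vetoed when the 3 s window that follows it still shows a
stable gait-band oscillation -- a person who has actually fallen does not
keep walking.

Stability (the quantified reading of "periodicity kept stable"): at least
``min_halfperiods`` half-periods observed, every half-period within
``tol_frac`` of their median, and the period inside the gait band
(0.4-2.0 s at 25 Hz, i.e. 10-50 samples, slow walk included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VETO_WINDOW_S = 3.0
MIN_HALFPERIODS = 4
TOL_FRAC = 0.25
GAIT_PERIOD_SAMPLES = (10, 50)  # 0.4-2.0 s at 25 Hz


@dataclass
class PeriodicityConfig:
    veto_window_s: float = VETO_WINDOW_S
    min_halfperiods: int = MIN_HALFPERIODS
    tol_frac: float = TOL_FRAC
    gait_period_samples: tuple[int, int] = GAIT_PERIOD_SAMPLES


@dataclass
class PeriodEstimate:
    """Zero-crossing period estimate over an analysis window.

    ``half_periods`` are sample counts between consecutive sign changes of
    x4; ``period_samples`` is the representative full-cycle span (median of
    sums of consecutive half-period pairs, exact on integer-period
    sinusoids); ``stable`` flags a sustained gait-band oscillation.
    """

    half_periods: np.ndarray
    period_samples: float
    stable: bool


def zero_crossings(x4_window: np.ndarray) -> np.ndarray:
    """Indices k where sign(x4[k]) != sign(x4[k-1]).

    Exact zeros inherit the previous sign so a touch of the axis is not
    double-counted as two crossings.
    """
    x = np.asarray(x4_window, dtype=float)
    if x.size < 2:
        return np.array([], dtype=int)
    signs = np.sign(x)
    # carry the previous sign through exact zeros (leading zeros stay 0)
    for i in range(x.size):
        if signs[i] == 0:
            signs[i] = signs[i - 1] if i > 0 else 0.0
    changed = (signs[1:] != signs[:-1]) & (signs[1:] != 0) & (signs[:-1] != 0)
    return np.nonzero(changed)[0] + 1


def estimate_period(
    x4_window: np.ndarray, config: PeriodicityConfig | None = None
) -> PeriodEstimate:
    """Estimate the gait period over an analysis window of x4.

    Returns ``stable=False`` (never an error) when the window holds too few
    crossings, irregular half-periods, or a period outside the gait band.
    """
    if config is None:
        config = PeriodicityConfig()
    crossings = zero_crossings(x4_window)
    half = np.diff(crossings).astype(float)
    if half.size == 0:
        return PeriodEstimate(half, float("nan"), False)
    if half.size >= 2:
        full = half[:-1] + half[1:]  # spans between alternate crossings
        period = float(np.median(full))
    else:
        period = 2.0 * float(half[0])
    med_half = float(np.median(half))
    lo, hi = config.gait_period_samples
    stable = (
        half.size >= config.min_halfperiods
        and bool(np.all(np.abs(half - med_half) <= config.tol_frac * med_half))
        and lo <= period <= hi
    )
    return PeriodEstimate(half, period, stable)


def veto(
    x4_post_window: np.ndarray,
    sample_rate: float = 25.0,
    config: PeriodicityConfig | None = None,
) -> tuple[str, bool]:
    """Resolve a candidate fall from the 3 s of x4 that follow it.

    Returns ``(status, truncated)`` with status "vetoed" iff the post-window
    shows a stable gait-band periodicity, else "confirmed".  A post-window
    shorter than the veto span (end of stream) confirms with a truncation
    warning flag.
    """
    if config is None:
        config = PeriodicityConfig()
    needed = int(round(config.veto_window_s * sample_rate))
    x = np.asarray(x4_post_window, dtype=float)
    truncated = x.size < needed
    est = estimate_period(x[:needed], config)
    return ("vetoed" if est.stable else "confirmed", truncated)
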