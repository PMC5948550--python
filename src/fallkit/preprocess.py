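"""Downsampling, low-pass filtering and differencing of the raw stream.

The detector runs at 25 Hz.  Higher-rate recordings (SisFall's native
200 Hz) are decimated by plain stride, mirroring a device that samples at
25 Hz directly; the 4th-order Butterworth low-pass (5 Hz cut-off) then runs
at 25 Hz, realized as cascaded second-order sections with zero initial state.
Differencing consecutive filtered samples removes the gravity bias for the
impact feature J1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from fallkit.io import RawRecording

FS_HZ = 25.0
FC_HZ = 5.0
ORDER = 4


def design_lowpass(fc_hz: float = FC_HZ, fs_hz: float = FS_HZ, order: int = ORDER) -> np.ndarray:
    """Butterworth low-pass as second-order sections (shape (order/2, 6))."""
    return signal.butter(order, fc_hz, btype="low", fs=fs_hz, output="sos")


def frequency_response(sos: np.ndarray, f_hz: float, fs_hz: float = FS_HZ) -> complex:
    """Transfer-function value H(e^{j 2 pi f / fs}) of the cascade."""
    _, h = signal.sosfreqz(sos, worN=[2.0 * np.pi * f_hz / fs_hz])
    return complex(h[0])


@dataclass
class FilterState:
    """Streaming state of the per-axis low-pass cascade.

    Holds the section coefficients and one delay-register array per axis so
    that sample-by-sample filtering reproduces batch filtering bit-for-bit.
    """

    sos: np.ndarray = field(default_factory=design_lowpass)
    n_axes: int = 3
    zi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zi is None:
            self.zi = np.zeros((self.n_axes, self.sos.shape[0], 2))

    def push(self, frame: np.ndarray) -> np.ndarray:
        """Filter one (n_axes,) frame, advancing the delay registers."""
        out = np.empty(self.n_axes)
        for a in range(self.n_axes):
            y, self.zi[a] = signal.sosfilt(self.sos, [float(frame[a])], zi=self.zi[a])
            out[a] = y[0]
        return out


def downsample(recording: RawRecording, target_rate: float = FS_HZ) -> RawRecording:
    """Decimate by stride to ``target_rate``; identity if already there.

    The source rate must be an integer multiple of the target rate.  Frames
    are kept starting at index 0 (no anti-alias prefilter: the reference
    device natively samples at 25 Hz).
    """
    ratio = recording.sample_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"sample rate {recording.sample_rate} is not an integer multiple of {target_rate}"
        )
    stride = int(round(ratio))
    if stride == 1:
        return recording
    return RawRecording(
        frames=recording.frames[::stride].copy(),
        sample_rate=target_rate,
        subject_code=recording.subject_code,
        activity_code=recording.activity_code,
        trial=recording.trial,
    )


def lowpass(frames: np.ndarray, state: FilterState | None = None) -> np.ndarray:
    """Batch low-pass of an (n, 3) array, per axis, zero initial conditions."""
    frames = np.asarray(frames, dtype=float)
    if state is None:
        state = FilterState()
    out = np.empty_like(frames)
    for a in range(frames.shape[1]):
        out[:, a], state.zi[a] = signal.sosfilt(state.sos, frames[:, a], zi=state.zi[a])
    return out


def differentiate(frames: np.ndarray) -> np.ndarray:
    """Per-sample difference a[k] - a[k-1]; the k=0 row is zero."""
    frames = np.asarray(frames, dtype=float)
    out = np.zeros_like(frames)
    out[1:] = np.diff(frames, axis=0)
    return out
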