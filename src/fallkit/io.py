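"""Reading and writing SisFall-dialect accelerometer recordings.

The SisFall text dialect is one frame per line, integer ADC counts separated
by commas (or semicolons), accelerometer columns first.  Filenames follow
``<activity>_<subject>_R<trial>`` where a leading ``F`` in the activity code
marks a fall trial and a leading ``D`` an activity of daily living (ADL).

The device convention used throughout: 13-bit two's-complement ADC over
+/-16 G, hence 1 G = 2**13 / 32 = 256 bits, and the vertical (y) axis reads
about -256 bits when the wearer stands upright.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ADC_BITS_DEFAULT = 13
RANGE_G_DEFAULT = 16.0
#: bits per gravity for the default device configuration (2*16 G / 2**13)
BITS_PER_G = 256.0

_FILENAME_RE = re.compile(r"^(?P<activity>[A-Za-z]\d+)_(?P<subject>\w+?)_R(?P<trial>\d+)$")


@dataclass(frozen=True)
class AccelFrame:
    """One triaxial sample in raw ADC bits; y is the vertical axis."""

    ax: int
    ay: int
    az: int

    def as_array(self) -> np.ndarray:
        return np.array([self.ax, self.ay, self.az], dtype=float)


@dataclass
class RawRecording:
    """A labelled triaxial ADC time series.

    ``frames`` is an (n, 3) integer array (columns ax, ay, az); ``is_fall``
    is derived from the activity code prefix ("F..." = fall).
    """

    frames: np.ndarray
    sample_rate: float
    subject_code: str = ""
    activity_code: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 2 or self.frames.shape[1] != 3:
            raise ValueError("frames must be an (n, 3) array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def is_fall(self) -> bool:
        return self.activity_code.startswith("F")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate

    def frame(self, k: int) -> AccelFrame:
        ax, ay, az = (int(v) for v in self.frames[k])
        return AccelFrame(ax, ay, az)


def parse_filename_metadata(path: str | Path) -> dict:
    """Extract activity/subject/trial from ``<activity>_<subject>_R<trial>``.

    Unrecognised names yield empty metadata rather than an error.
    """
    stem = Path(path).stem
    m = _FILENAME_RE.match(stem)
    if m is None:
        return {"activity_code": "", "subject_code": "", "trial": 0}
    return {
        "activity_code": m.group("activity"),
        "subject_code": m.group("subject"),
        "trial": int(m.group("trial")),
    }


def read_recording(
    path: str | Path,
    column_map: tuple[int, int, int] = (0, 1, 2),
    sample_rate: float = 200.0,
) -> RawRecording:
    """Read a SisFall-dialect text file into a :class:`RawRecording`.

    Parameters
    ----------
    path:
        Plain-text file, one frame per line, comma- or semicolon-separated
        signed integer tokens.
    column_map:
        0-based indices of the (ax, ay, az) columns.  SisFall files carry
        nine sensor columns; the first accelerometer occupies columns 0-2.
    sample_rate:
        Acquisition rate in Hz (SisFall native rate is 200 Hz).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    needed = max(column_map) + 1
    rows: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().rstrip(";,")
            if not line:
                continue
            tokens = [t.strip() for t in re.split(r"[;,]", line)]
            if len(tokens) < needed:
                raise ValueError(
                    f"{path.name}:{lineno}: expected >= {needed} columns, got {len(tokens)}"
                )
            try:
                rows.append(tuple(int(tokens[i]) for i in column_map))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed integer token") from exc
    if not rows:
        raise ValueError(f"{path.name}: empty recording")
    meta = parse_filename_metadata(path)
    return RawRecording(
        frames=np.array(rows, dtype=np.int64),
        sample_rate=sample_rate,
        **meta,
    )


def write_recording(recording: RawRecording, path: str | Path) -> None:
    """Write frames back out in the SisFall text dialect (comma-separated)."""
    with open(path, "w") as fh:
        for row in recording.frames:
            fh.write(",".join(str(int(v)) for v in row) + "\n")


def bits_to_g(
    bits: float | np.ndarray,
    adc_bits: int = ADC_BITS_DEFAULT,
    range_g: float = RANGE_G_DEFAULT,
) -> float | np.ndarray:
    """Convert raw ADC counts to gravities: ``bits * 2*range_g / 2**adc_bits``.

    With the default +/-16 G 13-bit configuration one gravity is exactly
    256 bits.  Linear and sign-preserving; used for reporting only -- the
    pipeline itself computes in bits.
    """
    if adc_bits < 2:
        raise ValueError("adc_bits must be >= 2")
    if range_g <= 0:
        raise ValueError("range_g must be positive")
    scale = 2.0 * range_g / float(2**adc_bits)
    return bits * scale


def g_to_bits(
    g: float | np.ndarray,
    adc_bits: int = ADC_BITS_DEFAULT,
    range_g: float = RANGE_G_DEFAULT,
) -> float | np.ndarray:
    """Inverse of :func:`bits_to_g` (not rounded)."""
    return g * float(2**adc_bits) / (2.0 * range_g)


def write_trace(
    recording: RawRecording,
    features: pd.DataFrame,
    events: Sequence,
    path: str | Path,
) -> None:
    """Persist a per-sample pipeline trace as CSV.

    One row per 25 Hz sample: index, raw ax/ay/az, Kalman states x1..x4,
    J1, J2, J3, and a 0/1 event flag set at the sample index of each event.
    ``features`` must carry columns x1..x4, J1, J2, J3 aligned with frames.
    """
    n = recording.n_frames
    for col in ("x1", "x2", "x3", "x4", "J1", "J2", "J3"):
        if col not in features.columns:
            raise ValueError(f"features missing column {col!r}")
        if len(features[col]) != n:
            raise ValueError("feature series length must equal frame count")
    flag = np.zeros(n, dtype=int)
    for ev in events:
        idx = getattr(ev, "sample_index", ev)
        if 0 <= idx < n:
            flag[idx] = 1
    out = pd.DataFrame(
        {
            "k": np.arange(n),
            "ax": recording.frames[:, 0],
            "ay": recording.frames[:, 1],
            "az": recording.frames[:, 2],
        }
    )
    for col in ("x1", "x2", "x3", "x4", "J1", "J2", "J3"):
        out[col] = np.asarray(features[col])
    out["event"] = flag
    out.to_csv(path, index=False)


def read_trace(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(events: Sequence, path: str | Path) -> None:
    """Write detection events as a JSON list with sorted keys."""
    payload = []
    for ev in events:
        payload.append(
            {
                "sample_index": int(ev.sample_index),
                "J3_at_event": float(ev.J3_at_event),
                "status": str(ev.status),
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")
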