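"""Seeded generator of labelled SisFall-dialect recordings.

Emulates the signal morphology a waist-mounted +/-16 G, 13-bit, 25 Hz
accelerometer sees (1 G = 256 bits; the vertical y axis rests at -256):

- rest: -1 G vertical bias plus sensor noise;
- walk / jog / stairs: a quasi-sinusoid of gait period and amplitude riding
  on the -1 G bias, with smaller harmonics on x and z;
- posture transitions (sit, bed turn): a smooth gravity rotation between
  axes with no large impact;
- jump: a short high-amplitude impact after which the bias returns to -1 G;
- falls: an impact followed by a *sustained* gravity rotation onto the
  post-fall axis (y -256 -> 0, x 0 -> +/-256);
- jog_trip_fall: a jog segment that ends in a fall (the classic trip);
- jog_spike: jogging with one isolated impact after which jogging resumes
  (the false-positive shape the periodicity veto exists for).

Noise is i.i.d. Gaussian rounded to integer bits.  Every sample path is
fixed by the spec's seed; corpora derive per-file seeds reproducibly from a
corpus seed.  200 Hz output is the 25 Hz path with each frame repeated
eight times, so stride-8 decimation recovers the identical frames.

Default amplitudes (jog 150 bits at 0.8 s period, walk 40 bits at 1.2 s,
impacts 1500 bits) mirror the jog-versus-fall margin of the reference
device recordings: with the default pipeline, fall files peak above the
40,000 deployment threshold and ADL files stay below 20,000.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from fallkit.io import RawRecording, write_recording

ADC_MIN, ADC_MAX = -(2**12), 2**12 - 1
REST_Y = -256.0

ACTIVITIES = (
    "rest",
    "walk",
    "jog",
    "stairs",
    "sit_transition",
    "bed_turn",
    "jump",
    "fall_forward",
    "fall_backward",
    "jog_trip_fall",
    "jog_spike",
)

#: SisFall-style activity codes for generated files (D* = ADL, F* = fall)
ACTIVITY_CODES = {
    "rest": "D01",
    "walk": "D02",
    "jog": "D03",
    "stairs": "D04",
    "sit_transition": "D07",
    "bed_turn": "D13",
    "jump": "D06",
    "jog_spike": "D18",
    "fall_forward": "F01",
    "fall_backward": "F02",
    "jog_trip_fall": "F05",
}

FALL_ACTIVITIES = {"fall_forward", "fall_backward", "jog_trip_fall"}


@dataclass
class SyntheticSpec:
    """Everything that fixes one generated recording."""

    activity: str = "walk"
    duration_s: float = 20.0
    gait_period_s: float = 1.2
    gait_amplitude_bits: float = 40.0
    impact_amplitude_bits: float = 1500.0
    post_fall_axis: str = "x"  # axis carrying gravity after a fall
    transition_s: float = 2.0  # posture-change ramp length
    noise_sd_bits: float = 3.0
    seed: int = 0
    sample_rate: float = 25.0

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (0.3 <= self.gait_period_s <= 3.0):
            raise ValueError("gait_period_s must lie in 0.3-3 s")
        if min(self.gait_amplitude_bits, self.impact_amplitude_bits) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.post_fall_axis not in ("x", "z"):
            raise ValueError("post_fall_axis must be 'x' or 'z'")


# per-activity default overrides applied by spec_for()
_ACTIVITY_DEFAULTS: dict[str, dict] = {
    "rest": {"gait_amplitude_bits": 0.0},
    "walk": {"gait_period_s": 1.2, "gait_amplitude_bits": 40.0},
    "jog": {"gait_period_s": 0.8, "gait_amplitude_bits": 150.0},
    "stairs": {"gait_period_s": 1.6, "gait_amplitude_bits": 60.0},
    "sit_transition": {"gait_amplitude_bits": 0.0},
    "bed_turn": {"gait_amplitude_bits": 0.0, "transition_s": 3.0},
    "jump": {"gait_amplitude_bits": 0.0},
    # lateral device impact during jog: big enough that its raw J3 overlaps
    # fall scores -- exactly the false positive the periodicity veto removes
    "jog_spike": {
        "gait_period_s": 0.8,
        "gait_amplitude_bits": 150.0,
        "impact_amplitude_bits": 4000.0,
    },
    "fall_forward": {"gait_amplitude_bits": 0.0},
    "fall_backward": {"gait_amplitude_bits": 0.0, "post_fall_axis": "x"},
    "jog_trip_fall": {"gait_period_s": 0.8, "gait_amplitude_bits": 150.0},
}


def spec_for(activity: str, seed: int = 0, **overrides) -> SyntheticSpec:
    """A SyntheticSpec with the per-activity default morphology."""
    kwargs = dict(_ACTIVITY_DEFAULTS.get(activity, {}))
    kwargs.update(overrides)
    return SyntheticSpec(activity=activity, seed=seed, **kwargs)


def _sigmoid_ramp(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """0 -> 1 logistic ramp centred at t0, ~width seconds wide."""
    return 1.0 / (1.0 + np.exp(-8.0 * (t - t0) / max(width, 1e-6)))


def _gait(t: np.ndarray, spec: SyntheticSpec, phase: float = 0.0) -> np.ndarray:
    """(n, 3) gait oscillation: main sinusoid on y, harmonics on x/z."""
    w = 2.0 * np.pi / spec.gait_period_s
    a = spec.gait_amplitude_bits
    out = np.zeros((t.size, 3))
    out[:, 1] = a * np.sin(w * t + phase)
    out[:, 0] = 0.25 * a * np.sin(2.0 * w * t + phase + 0.7)
    out[:, 2] = 0.15 * a * np.sin(w * t + phase + 1.9)
    return out


def _impact(n: int, k0: int, amplitude: float, axis: int = 1) -> np.ndarray:
    """3-sample jolt (+A, -0.6A, +0.3A) on one axis starting at sample k0."""
    out = np.zeros((n, 3))
    for j, frac in enumerate((1.0, -0.6, 0.3)):
        if 0 <= k0 + j < n:
            out[k0 + j, axis] = frac * amplitude
    return out


def _rotation(t: np.ndarray, t0: float, width: float, target: np.ndarray) -> np.ndarray:
    """Gravity vector path from (0, -256, 0) to ``target`` via a ramp."""
    ramp = _sigmoid_ramp(t, t0, width)[:, None]
    start = np.array([0.0, REST_Y, 0.0])
    return start + ramp * (target - start)


def gen_recording(spec: SyntheticSpec) -> RawRecording:
    """Generate one labelled recording; deterministic per seed."""
    n = int(round(spec.duration_s * 25.0))
    t = np.arange(n) / 25.0
    rng = np.random.default_rng(spec.seed)
    axis_idx = {"x": 0, "z": 2}[spec.post_fall_axis]
    post_fall = np.array([0.0, 0.0, 0.0])
    post_fall[axis_idx] = 256.0 if spec.activity != "fall_backward" else -256.0

    gravity = np.tile([0.0, REST_Y, 0.0], (n, 1))
    osc = np.zeros((n, 3))
    imp = np.zeros((n, 3))

    act = spec.activity
    if act in ("walk", "jog", "stairs"):
        osc = _gait(t, spec)
    elif act == "sit_transition":
        # 45-degree tilt: gravity shared between y and z, magnitude kept
        target = np.array([0.0, -181.0, 181.0])
        gravity = _rotation(t, spec.duration_s / 2.0, spec.transition_s, target)
    elif act == "bed_turn":
        gravity = _rotation(t, spec.duration_s / 2.0, spec.transition_s, post_fall)
    elif act == "jump":
        imp = _impact(n, n // 2, spec.impact_amplitude_bits)
    elif act in ("fall_forward", "fall_backward"):
        k_fall = int(0.6 * n)
        imp = _impact(n, k_fall, spec.impact_amplitude_bits)
        gravity = _rotation(t, t[min(k_fall, n - 1)], 0.3, post_fall)
    elif act == "jog_trip_fall":
        k_fall = int(0.6 * n)
        mask = np.arange(n) < k_fall
        osc = _gait(t, spec) * mask[:, None]
        imp = _impact(n, k_fall, spec.impact_amplitude_bits)
        gravity = _rotation(t, t[min(k_fall, n - 1)], 0.3, post_fall)
    elif act == "jog_spike":
        osc = _gait(t, spec)
        # direct impact to the device: lateral (x) axis, gait undisturbed
        imp = _impact(n, n // 2, spec.impact_amplitude_bits, axis=0)
    # rest: gravity only

    clean = gravity + osc + imp
    noise = rng.normal(0.0, spec.noise_sd_bits, size=(n, 3)) if spec.noise_sd_bits else 0.0
    frames = np.clip(np.rint(clean + noise), ADC_MIN, ADC_MAX).astype(np.int64)

    if spec.sample_rate == 200.0:
        frames = np.repeat(frames, 8, axis=0)
    elif spec.sample_rate != 25.0:
        raise ValueError("sample_rate must be 25 or 200 Hz")

    return RawRecording(
        frames=frames,
        sample_rate=spec.sample_rate,
        subject_code="SY00",
        activity_code=ACTIVITY_CODES[act],
        trial=1,
    )


def gen_corpus(
    mix: dict[str, int],
    base_spec: SyntheticSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    overrides: dict | None = None,
) -> tuple[list[RawRecording], pd.DataFrame]:
    """Generate a labelled corpus from per-activity counts.

    Per-file seeds are derived reproducibly from the corpus seed.  When
    ``out_dir`` is given, SisFall-dialect text files plus a
    ``manifest.csv`` (filename, activity, is_fall) are written there.
    """
    total = sum(mix.values())
    if total < 2:
        raise ValueError("corpus needs at least 2 files")
    base = base_spec if base_spec is not None else SyntheticSpec()
    ss = np.random.SeedSequence(seed)
    file_seeds = [int(s) % (2**31) for s in ss.generate_state(total)]
    recordings: list[RawRecording] = []
    rows = []
    i = 0
    for activity in sorted(mix):
        for trial in range(1, mix[activity] + 1):
            kwargs = {
                "duration_s": base.duration_s,
                "noise_sd_bits": base.noise_sd_bits,
                "sample_rate": base.sample_rate,
            }
            if overrides:
                kwargs.update(overrides)
            spec = spec_for(activity, seed=file_seeds[i], **kwargs)
            rec = gen_recording(spec)
            rec.trial = trial
            rec.subject_code = f"SY{i % 10:02d}"
            recordings.append(rec)
            fname = f"{rec.activity_code}_{rec.subject_code}_R{trial:02d}.txt"
            rows.append({"filename": fname, "activity": activity, "is_fall": rec.is_fall})
            i += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(recordings, rows):
            write_recording(rec, out_dir / row["filename"])
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return recordings, manifest


#: the default separable evaluation corpus: 40 ADLs across all ADL types, 20 falls
DEFAULT_MIX = {
    "rest": 5,
    "walk": 6,
    "jog": 6,
    "stairs": 5,
    "sit_transition": 6,
    "bed_turn": 6,
    "jump": 6,
    "fall_forward": 7,
    "fall_backward": 6,
    "jog_trip_fall": 7,
}

#: the "hard" corpus: false-positive shapes (spikes during jog, fast bed turns)
HARD_MIX = {
    "jog_spike": 8,
    "bed_turn": 6,
    "jog": 4,
    "walk": 4,
    "sit_transition": 4,
    "fall_forward": 5,
    "fall_backward": 4,
    "jog_trip_fall": 5,
}


def default_corpus(seed: int = 0, **base_overrides) -> tuple[list[RawRecording], pd.DataFrame]:
    base = SyntheticSpec(**base_overrides) if base_overrides else None
    return gen_corpus(DEFAULT_MIX, base, seed=seed)


def hard_corpus(seed: int = 0, **base_overrides) -> tuple[list[RawRecording], pd.DataFrame]:
    base = SyntheticSpec(**base_overrides) if base_overrides else None
    # fast bed turns exercise the posture-change false-positive path
    return gen_corpus(HARD_MIX, base, seed=seed, overrides={"transition_s": 1.0})
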