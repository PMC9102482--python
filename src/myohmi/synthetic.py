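"""Seeded synthetic single-channel surface-EMG sessions with ground truth.

Real biceps-brachii sEMG under isometric contraction looks, to first order,
like band-limited Gaussian noise (20–450 Hz) whose envelope follows the
contraction: amplitudes between 0.1 and 5 mV, sampled at 10 kHz, with
contractions of roughly 1, 3 or 5 s separated by 5 s of rest.  This module
generates such sessions from a seed, together with the exact burst
intervals and class labels, so the whole downstream pipeline (filtering,
segmentation, classification, state machine, robot) is testable without a
recorded dataset.

Four signal classes are produced:

``SMP``
    sharp muscle pulse, a ~1 s voluntary contraction;
``SMP3`` / ``SMP5``
    smooth muscle pulses sustained ~3 s / ~5 s;
``NIM``
    noise / involuntary movements — rest-level activity with erratic
    sub-voluntary bursts and slow baseline wander; the class the
    classifier must learn to reject as a command.

The burst model is deliberately simple (amplitude-modulated filtered
noise); it reproduces the amplitude, bandwidth and timing structure of the
protocol, not motor-unit physiology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal

from .recording import DEFAULT_SAMPLE_RATE_HZ, EmgRecording, concatenate

#: default signal band of voluntary contractions, Hz
DEFAULT_BAND_HZ = (20.0, 450.0)
#: envelope rise/fall time of a voluntary burst, seconds
ENVELOPE_RAMP_S = 0.1
#: default RMS of the rest-noise floor, mV
REST_NOISE_RMS_MV = 0.05
#: guard band added to the nominal amplitude when bounding samples, mV
NOISE_MARGIN_MV = 5.0 * REST_NOISE_RMS_MV


class ContractionClass(Enum):
    """The four contraction classes, with their integer labels.

    The integer coding (NIM = 0, then SMP, SMP3, SMP5 by duration) is the
    package-wide convention used for one-hot targets and the state-machine
    input word.
    """

    NIM = 0
    SMP = 1
    SMP3 = 2
    SMP5 = 3

    @property
    def nominal_duration_s(self) -> float | None:
        """Nominal contraction duration; None for the rest/noise class."""
        return {"SMP": 1.0, "SMP3": 3.0, "SMP5": 5.0}.get(self.name)

    @property
    def is_voluntary(self) -> bool:
        return self is not ContractionClass.NIM


#: duration of the activity slot rendered for a NIM event, seconds
NIM_SLOT_DURATION_S = 3.0


@dataclass(frozen=True)
class LabelInterval:
    """Ground-truth annotation: one class active on [start_s, end_s)."""

    start_s: float
    end_s: float
    cls: ContractionClass

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def save_labels(intervals: list[LabelInterval], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {"start_s": iv.start_s, "end_s": iv.end_s, "class": iv.cls.name}
                for iv in intervals
            ],
            fh,
            indent=1,
        )


def load_labels(path) -> list[LabelInterval]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        LabelInterval(d["start_s"], d["end_s"], ContractionClass[d["class"]])
        for d in raw
    ]


@dataclass(frozen=True)
class SessionPlan:
    """Recipe for a synthetic session.

    ``events`` is an ordered list of (class, contraction_duration_s,
    rest_duration_s) tuples; a duration of None uses the class nominal.
    All stochastic choices derive from ``seed``.
    """

    events: tuple = ()
    seed: int = 0
    amplitude_mv: float = 2.0
    duration_jitter_fraction: float = 0.15
    rest_duration_s: float = 5.0
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    band_hz: tuple = DEFAULT_BAND_HZ
    rest_noise_rms_mv: float = REST_NOISE_RMS_MV

    def __post_init__(self):
        if not 0 < self.amplitude_mv <= 5.0:
            raise ValueError(
                f"amplitude_mv must be in (0, 5] mV, got {self.amplitude_mv}"
            )
        if self.rest_duration_s < 0:
            raise ValueError("rest_duration_s must be >= 0")
        for ev in self.events:
            cls, dur, _rest = _normalize_event(ev)
            if dur is not None and dur <= 0:
                raise ValueError(f"non-positive contraction duration for {cls.name}")

    @property
    def noise_margin_mv(self) -> float:
        return 5.0 * self.rest_noise_rms_mv


def _normalize_event(ev):
    if isinstance(ev, ContractionClass):
        return ev, None, None
    cls, dur, rest = ev
    return ContractionClass[cls] if isinstance(cls, str) else cls, dur, rest


def balanced_plan(
    n_per_class: int,
    seed: int,
    classes: tuple = (
        ContractionClass.SMP,
        ContractionClass.SMP3,
        ContractionClass.SMP5,
        ContractionClass.NIM,
    ),
    **kwargs,
) -> SessionPlan:
    """Plan with ``n_per_class`` repetitions of each class, shuffled by seed."""
    events = [cls for cls in classes for _ in range(n_per_class)]
    np.random.default_rng(seed).shuffle(events)
    return SessionPlan(events=tuple(events), seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# waveform synthesis


def _bandlimited_noise(n: int, fs: float, band: tuple, rng: np.random.Generator):
    """White Gaussian noise band-passed to the sEMG signal band.

    The design corners sit slightly inside the nominal band so that, with
    the finite roll-off, >= 95% of the power stays within the band itself.
    """
    lo, hi = band
    sos = signal.butter(8, [1.25 * lo, 0.955 * hi], btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfilt(sos, rng.standard_normal(n))


def _trapezoid_envelope(n: int, fs: float, ramp_s: float = ENVELOPE_RAMP_S):
    """Unit-height trapezoid: linear ramps of ``ramp_s`` inside the burst."""
    n_ramp = min(int(round(ramp_s * fs)), n // 2)
    env = np.ones(n)
    if n_ramp > 0:
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        env[:n_ramp] = ramp
        env[n - n_ramp :] = ramp[::-1]
    return env


def _render_burst(
    duration_s: float, amplitude_mv: float, plan: SessionPlan, rng
) -> np.ndarray:
    """One voluntary burst, peak-normalized to ``amplitude_mv``."""
    n = max(int(round(duration_s * plan.sample_rate_hz)), 8)
    x = _bandlimited_noise(n, plan.sample_rate_hz, plan.band_hz, rng)
    x *= _trapezoid_envelope(n, plan.sample_rate_hz)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= amplitude_mv / peak
    return x


def _render_nim(duration_s: float, plan: SessionPlan, rng) -> np.ndarray:
    """Rest / involuntary-movement activity.

    Most slots carry short erratic sub-voluntary bursts; some are quiet
    (pure rest plus wander), mirroring the two faces of the class —
    involuntary arm movement and the resting state itself.
    """
    fs = plan.sample_rate_hz
    n = max(int(round(duration_s * fs)), 8)
    x = np.zeros(n)
    t = 0.0
    quiet = rng.random() < 0.35
    while not quiet and t < duration_s - 0.3:
        dur = rng.uniform(0.3, min(1.5, duration_s - t))
        amp = rng.uniform(0.10, 0.40) * plan.amplitude_mv
        burst = _render_burst(dur, amp, plan, rng)
        i0 = int(round(t * fs))
        x[i0 : i0 + burst.size] += burst[: n - i0]
        t += dur + rng.uniform(0.1, 0.6)
    # baseline wander, <= 0.5 Hz
    f_w = rng.uniform(0.1, 0.5)
    x += 0.1 * plan.amplitude_mv * np.sin(
        2 * np.pi * f_w * np.arange(n) / fs + rng.uniform(0, 2 * np.pi)
    )
    return x


def _rest(duration_s: float, plan: SessionPlan, rng) -> np.ndarray:
    n = int(round(duration_s * plan.sample_rate_hz))
    return rng.standard_normal(n) * plan.rest_noise_rms_mv


def _event_duration(cls: ContractionClass, duration_s, plan: SessionPlan, rng):
    if duration_s is None:
        duration_s = cls.nominal_duration_s or NIM_SLOT_DURATION_S
    j = plan.duration_jitter_fraction
    return duration_s * (1.0 + rng.uniform(-j, j)) if j > 0 else duration_s


def _render_session(plan: SessionPlan, rng) -> tuple[EmgRecording, list[LabelInterval]]:
    if not plan.events:
        raise ValueError("session plan has no events")
    chunks = [_rest(plan.rest_duration_s, plan, rng)]
    t = plan.rest_duration_s
    intervals: list[LabelInterval] = []
    for ev in plan.events:
        cls, dur, rest = _normalize_event(ev)
        rest = plan.rest_duration_s if rest is None else rest
        dur = _event_duration(cls, dur, plan, rng)
        if cls.is_voluntary:
            chunk = _render_burst(dur, plan.amplitude_mv, plan, rng)
        else:
            chunk = _render_nim(dur, plan, rng)
        actual = chunk.size / plan.sample_rate_hz
        intervals.append(LabelInterval(t, t + actual, cls))
        chunks.append(chunk)
        chunks.append(_rest(rest, plan, rng))
        t += actual + rest
    samples = np.concatenate(chunks)
    # additive floor noise everywhere, bounded to the stated amplitude guard
    samples = samples + rng.standard_normal(samples.size) * plan.rest_noise_rms_mv
    bound = plan.amplitude_mv + plan.noise_margin_mv
    np.clip(samples, -bound, bound, out=samples)
    return EmgRecording(samples, plan.sample_rate_hz), intervals


# ---------------------------------------------------------------------------
# public API


def generate_contraction(
    cls: ContractionClass,
    plan: SessionPlan | None = None,
    duration_s: float | None = None,
    **plan_kwargs,
) -> tuple[EmgRecording, list[LabelInterval]]:
    """Generate a single labeled contraction with rest before and after.

    Returns the recording and the ground-truth burst interval(s).  Equal
    seeds produce bit-identical output.
    """
    if plan is None:
        plan = SessionPlan(seed=plan_kwargs.pop("seed", 0), **plan_kwargs)
    single = SessionPlan(
        events=((cls, duration_s, None),),
        **{k: getattr(plan, k) for k in (
            "seed", "amplitude_mv", "duration_jitter_fraction", "rest_duration_s",
            "sample_rate_hz", "band_hz", "rest_noise_rms_mv",
        )},
    )
    return generate_session(single)


def generate_session(plan: SessionPlan) -> tuple[EmgRecording, list[LabelInterval]]:
    """Render a full session from a plan: rest / event / rest / event / ...

    Ground-truth intervals mark exactly the rendered activity slots, in
    order; the recording is the concatenation of all parts.
    """
    rng = np.random.default_rng(plan.seed)
    return _render_session(plan, rng)


def inject_interference(
    rec: EmgRecording,
    mains_hz: float = 60.0,
    mains_amp_mv: float = 0.0,
    dc_mv: float = 0.0,
) -> EmgRecording:
    """Add mains-frequency sinusoidal interference and/or a DC offset.

    Emulates electromagnetic pickup (lamps, power lines) and electrode DC
    bias.  Length and rate are unchanged.
    """
    if mains_hz >= rec.sample_rate_hz / 2:
        raise ValueError(
            f"mains_hz={mains_hz} is at or above Nyquist "
            f"({rec.sample_rate_hz / 2} Hz)"
        )
    out = rec.samples + dc_mv
    if mains_amp_mv != 0.0:
        out = out + mains_amp_mv * np.sin(2 * np.pi * mains_hz * rec.times_s)
    return rec.with_samples(out)
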