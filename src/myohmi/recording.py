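"""Uniformly sampled single-channel EMG recordings and their on-disk form.

The recording is the common currency of the package: the synthetic
generator produces one, the digital filter and spectrum stages consume and
return them, and the segmenter cuts them into contraction events.  Samples
are stored in millivolts at a fixed rate (10 kHz by default, the usual
surface-EMG acquisition rate for a 20–450 Hz signal band).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_SAMPLE_RATE_HZ = 10_000.0


@dataclass(frozen=True)
class EmgRecording:
    """A uniformly sampled voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in millivolts.
    sample_rate_hz : float
        Sampling rate in Hz; strictly positive.
    start_time_s : float
        Time offset of the first sample, seconds.
    """

    samples: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.sample_rate_hz > 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt_s(self) -> float:
        """Sampling period T = 1/fs in seconds."""
        return 1.0 / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.sample_rate_hz

    def with_samples(self, samples: np.ndarray) -> "EmgRecording":
        return replace(self, samples=np.asarray(samples, dtype=float))

    def slice_seconds(self, start_s: float, end_s: float) -> "EmgRecording":
        """Extract the sub-recording covering [start_s, end_s) in absolute time."""
        i0 = max(0, int(round((start_s - self.start_time_s) * self.sample_rate_hz)))
        i1 = min(len(self), int(round((end_s - self.start_time_s) * self.sample_rate_hz)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start_s}, {end_s}) of recording")
        return EmgRecording(
            self.samples[i0:i1],
            self.sample_rate_hz,
            self.start_time_s + i0 / self.sample_rate_hz,
        )

    def to_csv(self, path) -> None:
        """Write the recording as a two-column CSV `time_s,voltage_mv`."""
        pd.DataFrame({"time_s": self.times_s, "voltage_mv": self.samples}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "EmgRecording":
        """Read a `time_s,voltage_mv` CSV; the time column must be uniform."""
        df = pd.read_csv(path)
        for col in ("time_s", "voltage_mv"):
            if col not in df.columns:
                raise ValueError(f"CSV is missing required column {col!r}")
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError("recording CSV needs at least two samples")
        dts = np.diff(t)
        dt = float(np.median(dts))
        if dt <= 0 or not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
            raise ValueError("time column is not uniformly sampled")
        return cls(
            df["voltage_mv"].to_numpy(dtype=float),
            sample_rate_hz=1.0 / dt,
            start_time_s=float(t[0]),
        )


def concatenate(recordings: list[EmgRecording]) -> EmgRecording:
    """Join recordings end to end; all must share one sample rate."""
    if not recordings:
        raise ValueError("cannot concatenate an empty list of recordings")
    rates = {rec.sample_rate_hz for rec in recordings}
    if len(rates) != 1:
        raise ValueError(f"mixed sample rates: {sorted(rates)}")
    return EmgRecording(
        np.concatenate([rec.samples for rec in recordings]),
        sample_rate_hz=recordings[0].sample_rate_hz,
        start_time_s=recordings[0].start_time_s,
    )
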