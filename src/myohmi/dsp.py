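"""First-order digital low-pass filtering and DFT spectrum analysis.

The real-time stage uses the cheapest possible IIR smoother, the discrete
first-order low-pass obtained from the analog RC prototype by matching the
pole: with cutoff ``fc`` and sampling period ``T`` the coefficient is
``a = exp(-2*pi*fc*T)`` and the difference equation

    v_o[n] = a * v_o[n-1] + (1 - a) * v_in[n-1]

has unit DC gain and one sample of delay.  The spectrum stage computes a
plain (rectangular-window) DFT magnitude spectrum, locates the dominant
interference component, and places the filter cutoff between the signal
band and that component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .recording import EmgRecording
from .synthetic import DEFAULT_BAND_HZ


@dataclass(frozen=True)
class FilterConfig:
    """Coefficients of the first-order low-pass.

    ``a = exp(-2*pi*fc_hz*T_s)`` is the smoothing coefficient; 0 < a < 1
    for any cutoff below Nyquist, so the filter is always stable.
    """

    fc_hz: float
    T_s: float
    a: float

    def magnitude_response(self, f_hz) -> np.ndarray:
        """Closed-form gain |H(e^{jwT})| = (1-a) / |e^{jwT} - a|."""
        w = 2 * np.pi * np.asarray(f_hz, dtype=float) * self.T_s
        return (1.0 - self.a) / np.abs(np.exp(1j * w) - self.a)


def lowpass_coefficients(fc_hz: float, sample_rate_hz: float) -> FilterConfig:
    """Derive the smoothing coefficient for a cutoff below Nyquist."""
    nyquist = sample_rate_hz / 2.0
    if not 0 < fc_hz < nyquist:
        raise ValueError(
            f"cutoff must satisfy 0 < fc < Nyquist ({nyquist} Hz), got {fc_hz}"
        )
    T = 1.0 / sample_rate_hz
    return FilterConfig(fc_hz=fc_hz, T_s=T, a=float(np.exp(-2.0 * np.pi * fc_hz * T)))


def apply_lowpass(
    rec: EmgRecording, cfg: FilterConfig, initial_output: float = 0.0
) -> EmgRecording:
    """Run the causal difference equation over the whole recording.

    The first output sample is ``initial_output``; thereafter
    v_o[n] = a v_o[n-1] + (1-a) v_in[n-1].
    """
    x = rec.samples
    if x.size == 0:
        raise ValueError("cannot filter an empty recording")
    a = cfg.a
    y = np.empty_like(x)
    y[0] = initial_output
    if x.size > 1:
        # y[n] = (1-a) x[n-1] + a y[n-1] is a one-pole lfilter on the
        # shifted input with state seeded so that y[1] uses y[0].
        y[1:], _ = lfilter([1.0 - a], [1.0, -a], x[:-1], zi=[a * initial_output])
    return rec.with_samples(y)


@dataclass(frozen=True)
class SpectrumResult:
    """One-sided DFT magnitude spectrum of a uniformly sampled series.

    ``energy_per_bin`` is weighted so that its sum equals the time-domain
    energy sum(x^2) exactly (Parseval).
    """

    frequencies_hz: np.ndarray
    magnitudes: np.ndarray
    energy_per_bin: np.ndarray
    sample_rate_hz: float

    @property
    def dominant_hz(self) -> float:
        return dominant_noise_frequency(self)


def compute_spectrum(rec: EmgRecording, window: str = "rect") -> SpectrumResult:
    """DFT magnitude spectrum over [0, Nyquist].

    The default is a plain rectangular window, for which the Parseval
    identity ties the spectrum energies exactly to the raw samples;
    ``window="hann"`` tapers the series first (reduced leakage, energies
    then refer to the tapered series).
    """
    x = rec.samples
    n = x.size
    if n < 2:
        raise ValueError("spectrum needs at least 2 samples")
    if window == "hann":
        x = x * np.hanning(n)
    elif window != "rect":
        raise ValueError(f"unknown window {window!r}; use 'rect' or 'hann'")
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=rec.dt_s)
    mags = np.abs(X)
    # one-sided Parseval weights: interior bins count twice
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    energy = weights * mags**2 / n
    return SpectrumResult(freqs, mags, energy, rec.sample_rate_hz)


def band_energy_fraction(spec: SpectrumResult, lo_hz: float, hi_hz: float) -> float:
    """Fraction of total signal energy inside [lo_hz, hi_hz]."""
    mask = (spec.frequencies_hz >= lo_hz) & (spec.frequencies_hz <= hi_hz)
    total = spec.energy_per_bin.sum()
    return float(spec.energy_per_bin[mask].sum() / total) if total > 0 else 0.0


def dominant_noise_frequency(
    spec: SpectrumResult, exclude_below_hz: float | None = None
) -> float:
    """Bin center carrying the most energy, above an exclusion floor.

    By default only the DC bin is excluded.  Exact ties resolve to the
    lower frequency.
    """
    freqs = spec.frequencies_hz
    if exclude_below_hz is None:
        mask = freqs > 0.0  # drop DC only
    else:
        mask = freqs >= exclude_below_hz
    if not mask.any():
        raise ValueError("exclusion floor removed every spectrum bin")
    energy = np.where(mask, spec.energy_per_bin, -np.inf)
    return float(freqs[int(np.argmax(energy))])  # argmax: first (lowest) bin on ties


def tune_cutoff(
    spec: SpectrumResult,
    signal_band_hz: tuple = DEFAULT_BAND_HZ,
    exclude_below_hz: float | None = None,
) -> FilterConfig:
    """Place the low-pass cutoff from the measured interference spectrum.

    If the dominant component sits above the signal band, the cutoff is
    the geometric mean of the band edge and the interference frequency —
    equidistant from both on a log axis.  Otherwise the cutoff defaults to
    the band edge (with a warning when the interference falls inside the
    band, where a low-pass cannot remove it).
    """
    band_hi = signal_band_hz[1]
    f_noise = dominant_noise_frequency(spec, exclude_below_hz)
    if f_noise > band_hi:
        fc = float(np.sqrt(band_hi * f_noise))
    else:
        if f_noise >= signal_band_hz[0]:
            warnings.warn(
                f"dominant interference at {f_noise:.1f} Hz lies inside the "
                f"signal band {signal_band_hz}; cutoff left at the band edge",
                stacklevel=2,
            )
        fc = float(band_hi)
    return lowpass_coefficients(fc, spec.sample_rate_hz)
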