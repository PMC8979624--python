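"""Analytic time-frequency decomposition with Generalized Morse Wavelets.

The transform convolves each node signal with a bank of analytic Morse
wavelets defined directly in the frequency domain, one wavelet per carrier
frequency on a log2-spaced grid.  Because the Morse window is identically
zero at non-positive frequencies, the coefficients are strictly analytic and
their squared magnitude is a well-defined power envelope.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "CarrierGrid",
    "MorseParams",
    "AnalyticSpectra",
    "carrier_frequencies",
    "morse_filter",
    "morse_half_support",
    "wavelet_transform",
]

#: Filter gain at the carrier frequency.  With unit-amplitude real input the
#: one-sided spectrum carries half the amplitude, so a peak gain of 2 makes
#: the coefficient magnitude track the oscillation amplitude directly.
PEAK_GAIN = 2.0

DEFAULT_MIN_EXP = 0.5
DEFAULT_MAX_EXP = 6.0
DEFAULT_STEP = 0.25


@dataclasses.dataclass(frozen=True)
class CarrierGrid:
    """Log2-spaced carrier frequencies, ``f = 2 ** exponent``."""

    exponents: np.ndarray
    frequencies_hz: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.exponents, dtype=float)
        if e.ndim != 1 or e.size == 0:
            raise ValueError("exponent grid must be a non-empty 1-D array")
        if not np.all(np.diff(e) > 0):
            raise ValueError("carrier exponents must be strictly increasing")
        object.__setattr__(self, "exponents", e)
        object.__setattr__(self, "frequencies_hz", np.asarray(self.frequencies_hz, dtype=float))

    def __len__(self) -> int:
        return self.exponents.size


@dataclasses.dataclass(frozen=True)
class MorseParams:
    """Morse wavelet shape (gamma) and decay (beta) parameters.

    Defaults give gamma = 3 (the symmetric family) with a time-bandwidth
    product P = sqrt(beta * gamma) of 5, i.e. roughly four to five
    oscillation cycles under the envelope.  These defaults are a
    documented choice, not a fitted value.
    """

    gamma: float = 3.0
    beta: float = 25.0 / 3.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError(f"gamma must be finite and positive, got {self.gamma}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and positive, got {self.beta}")

    @property
    def peak_omega(self) -> float:
        """Angular frequency of the unscaled Morse window maximum."""
        return (self.beta / self.gamma) ** (1.0 / self.gamma)

    @property
    def time_bandwidth(self) -> float:
        return float(np.sqrt(self.beta * self.gamma))


@dataclasses.dataclass
class AnalyticSpectra:
    """Complex wavelet coefficients, node x carrier x time, for one subject."""

    coefficients: np.ndarray  # complex, (n_nodes, n_carriers, n_samples)
    fs: float
    grid: CarrierGrid
    valid_mask: np.ndarray  # bool, (n_carriers, n_samples)

    def __post_init__(self) -> None:
        if self.coefficients.ndim != 3:
            raise ValueError("coefficients must be 3-D (node, carrier, time)")
        if self.valid_mask.shape != self.coefficients.shape[1:]:
            raise ValueError("valid_mask shape must be (n_carriers, n_samples)")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients contain non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.coefficients.shape[0]


def carrier_frequencies(
    min_exp: float = DEFAULT_MIN_EXP,
    max_exp: float = DEFAULT_MAX_EXP,
    step: float = DEFAULT_STEP,
) -> CarrierGrid:
    """Build the carrier grid ``2 ** (min_exp : step : max_exp)`` Hz.

    The default grid runs from 2**0.5 (~1.414 Hz) to 2**6 (64 Hz) in
    quarter-octave steps, 23 carriers in total.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    span = max_exp - min_exp
    if span < 0:
        raise ValueError("max_exp must be >= min_exp")
    n_steps = span / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} does not divide the range [{min_exp}, {max_exp}]")
    exponents = min_exp + step * np.arange(round(n_steps) + 1)
    return CarrierGrid(exponents=exponents, frequencies_hz=2.0 ** exponents)


def morse_filter(
    params: MorseParams, carrier_hz: float, n_samples: int, fs: float
) -> np.ndarray:
    """Frequency-domain Morse wavelet response per DFT bin.

    Returns a real nonnegative array of length ``n_samples`` aligned with
    ``numpy.fft.fftfreq`` bin ordering: exactly zero at DC, at the Nyquist
    bin and at all negative-frequency bins, with magnitude peaking at the
    bin nearest ``carrier_hz`` and normalized there to :data:`PEAK_GAIN`.
    """
    if carrier_hz <= 0:
        raise ValueError(f"carrier must be positive, got {carrier_hz}")
    if carrier_hz >= fs / 2:
        raise ValueError(
            f"carrier {carrier_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    omega = 2.0 * np.pi * np.fft.fftfreq(n_samples)  # rad/sample
    omega_c = 2.0 * np.pi * carrier_hz / fs
    scale = params.peak_omega / omega_c

    response = np.zeros(n_samples)
    pos = omega > 0
    if n_samples % 2 == 0:
        pos[n_samples // 2] = False  # fftfreq maps Nyquist to -0.5; keep it zero
    w = scale * omega[pos]
    # log-space evaluation, normalized so the maximum (at w = peak_omega) is PEAK_GAIN
    log_peak = params.beta * np.log(params.peak_omega) - params.peak_omega ** params.gamma
    response[pos] = PEAK_GAIN * np.exp(
        params.beta * np.log(w) - w ** params.gamma - log_peak
    )
    return response


def morse_half_support(params: MorseParams, carrier_hz: float, fs: float) -> int:
    """Half the effective wavelet support, in samples.

    The Morse envelope spans roughly ``P = sqrt(beta * gamma)`` cycles of the
    carrier; we take P / carrier seconds as the half-support used for both
    the edge-effect mask and the minimum-length precondition.
    """
    return int(np.ceil(params.time_bandwidth / carrier_hz * fs))


def wavelet_transform(
    data: np.ndarray,
    fs: float,
    grid: CarrierGrid,
    params: MorseParams | None = None,
    pad: bool = True,
) -> AnalyticSpectra:
    """Analytic Morse-wavelet transform of node x time signals.

    Convolution runs in the frequency domain with zero-padding to the next
    power of two past the signal plus one full wavelet support; samples
    within one half-support of either edge are masked as invalid rather than
    tapered.  ``pad=False`` performs circular convolution at the native
    length (exactly analytic output, appropriate for periodic signals).
    """
    params = params or MorseParams()
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if data.ndim != 2:
        raise ValueError("data must be (n_nodes, n_samples)")
    n_nodes, n_samples = data.shape

    for f in grid.frequencies_hz:
        if f >= fs / 2:
            raise ValueError(f"carrier {f} Hz at or above Nyquist ({fs / 2} Hz)")
        support = 2 * morse_half_support(params, f, fs)
        if n_samples < 4 * support:
            raise ValueError(
                f"signal of {n_samples} samples is shorter than 4x the wavelet "
                f"support ({4 * support} samples) for carrier {f:g} Hz"
            )

    if pad:
        max_half = morse_half_support(params, float(grid.frequencies_hz[0]), fs)
        nfft = 1 << int(np.ceil(np.log2(n_samples + 2 * max_half)))
    else:
        nfft = n_samples
    spectra_in = np.fft.fft(data, n=nfft, axis=1)

    n_carriers = len(grid)
    coeffs = np.empty((n_nodes, n_carriers, n_samples), dtype=complex)
    valid = np.zeros((n_carriers, n_samples), dtype=bool)
    for ci, f in enumerate(grid.frequencies_hz):
        filt = morse_filter(params, float(f), nfft, fs)
        coeffs[:, ci, :] = np.fft.ifft(spectra_in * filt[None, :], axis=1)[:, :n_samples]
        half = morse_half_support(params, float(f), fs)
        valid[ci, half : n_samples - half] = True
    return AnalyticSpectra(coefficients=coeffs, fs=fs, grid=grid, valid_mask=valid)
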