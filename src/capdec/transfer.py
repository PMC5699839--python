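"""Signal-path transfer-function estimation and frequency-domain deconvolution.

The recorded current ``I_R(t)`` is the convolution of the membrane current
``I_M(t)`` with the impulse response ``h(t)`` of the recording path
(amplifier plus output low-pass filter):

    I_R(t) = I_M(t) * h(t)

``h`` is measured by delivering a one-sample voltage impulse to a resistor at
the amplifier input, once grounded (R+C response) and once ungrounded
(C response); the difference of the averaged responses is the net resistive
impulse response.  Its FFT, normalized to unity at DC, is the system
frequency characteristic ``H_S``.  Reconstruction then proceeds in three
steps: FFT of the recorded response, bin-wise division by ``H_S``, inverse
FFT.

Records are assumed to contain an integer number of stimulation periods of a
steady-state periodic stimulus, which makes the circular-convolution model of
the FFT division exact and avoids windowing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .circuit import CurrentTrace
from .filters import DigitalFilter

__all__ = [
    "TransferFunction",
    "ImpulseRecordPair",
    "average_records",
    "impulse_response",
    "compute_H",
    "deconvolve",
    "subtract_cp_record",
]


class DeconvolutionError(ValueError):
    """Degenerate transfer function or mismatched record."""


@dataclass
class TransferFunction:
    """Complex frequency characteristic H_S over a full set of FFT bins."""

    h: np.ndarray
    f_samp: float

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=complex)
        if self.h.ndim != 1 or self.h.size < 2:
            raise DeconvolutionError("H_S needs at least two bins")
        if abs(abs(self.h[0]) - 1.0) > 1e-9:
            raise DeconvolutionError("H_S must be normalized to unity DC gain")

    def __len__(self) -> int:
        return self.h.size

    @property
    def freqs(self) -> np.ndarray:
        """Physical bin frequencies in Hz (negative bins in FFT order)."""
        return np.fft.fftfreq(self.h.size, d=1.0 / self.f_samp)

    @classmethod
    def from_filter(cls, filt: DigitalFilter, nfft: int) -> "TransferFunction":
        """Exact rational frequency response of a known digital filter,
        evaluated on the FFT bin grid.

        For records that were produced by causal recursive filtering of a
        periodic signal this is the exact circular-convolution kernel (the
        aliased impulse response summed over all lags).
        """
        h = np.fft.fft(filt.b, nfft) / np.fft.fft(filt.a, nfft)
        return cls(h / h[0], filt.f_samp)


@dataclass
class ImpulseRecordPair:
    """Averaged responses to the one-sample voltage impulse.

    ``rc_response``: resistor connected between input and ground (R+C);
    ``c_response``: same resistor ungrounded, leaving only the capacitive
    component of pipette/amplifier origin.
    """

    rc_response: CurrentTrace
    c_response: CurrentTrace
    n_averages: int = 1

    def __post_init__(self) -> None:
        if len(self.rc_response) != len(self.c_response):
            raise DeconvolutionError("R+C and C responses must have equal length")
        if abs(self.rc_response.dt - self.c_response.dt) > 1e-15:
            raise DeconvolutionError("R+C and C responses must share dt")


def average_records(records: Sequence[CurrentTrace]) -> CurrentTrace:
    """Pointwise arithmetic mean of repeated records (noise suppression)."""
    if len(records) == 0:
        raise DeconvolutionError("no records to average")
    n = len(records[0])
    dt = records[0].dt
    for r in records[1:]:
        if len(r) != n or abs(r.dt - dt) > 1e-15:
            raise DeconvolutionError("records must share length and dt")
    mean = np.mean([r.samples for r in records], axis=0)
    return records[0].copy_with(mean, n_averages=len(records))


def impulse_response(pair: ImpulseRecordPair) -> CurrentTrace:
    """Net impulse response of the resistive path: (R+C) minus C response."""
    diff = pair.rc_response.samples - pair.c_response.samples
    return pair.rc_response.copy_with(diff, component="R-response")


def compute_H(impulse: CurrentTrace, nfft: int) -> TransferFunction:
    """FFT of the (zero-padded) impulse response normalized to unity DC gain."""
    if nfft < len(impulse):
        raise DeconvolutionError("nfft must cover the impulse record")
    h = np.fft.fft(impulse.samples, nfft)
    if abs(h[0]) == 0.0:
        raise DeconvolutionError("degenerate impulse response: zero DC component")
    return TransferFunction(h / h[0], impulse.f_samp)


def deconvolve(
    trace: CurrentTrace,
    H: TransferFunction,
    epsilon: float = 0.0,
    blank_head: float = 0.0,
) -> CurrentTrace:
    """Reconstruct the input current by bin-wise spectral division.

    With ``epsilon == 0`` the division is plain ``Y / H_S`` and any
    exactly-zero bin raises.  With ``epsilon > 0`` a Tikhonov-style guard is
    used, ``Y * conj(H) / (|H|^2 + epsilon)``, recommended for measured
    (noisy) transfer functions.  The real part of the inverse FFT is
    returned; a residual imaginary part above 1e-9 of the signal RMS flags a
    broken conjugate symmetry and raises.

    ``blank_head`` (seconds) is not applied to the signal; it is recorded in
    the trace metadata so that downstream fitting excludes the first
    ``blank_head`` of every half-period (onset-blanking mode for uncancelled
    parasitic-capacitance ringing).
    """
    if epsilon < 0:
        raise DeconvolutionError("epsilon must be non-negative")
    n = len(H)
    if len(trace) > n:
        raise DeconvolutionError("record longer than the transfer function")
    y = np.fft.fft(trace.samples, n)
    if epsilon == 0.0:
        if np.any(H.h == 0):
            raise DeconvolutionError(
                "H_S has exactly-zero bins; use epsilon > 0 to regularize"
            )
        x = y / H.h
    else:
        x = y * np.conj(H.h) / (np.abs(H.h) ** 2 + epsilon)
    xt = np.fft.ifft(x)
    rms = np.sqrt(np.mean(xt.real**2))
    if rms > 0 and np.max(np.abs(xt.imag)) > 1e-9 * rms:
        raise DeconvolutionError("inverse FFT lost conjugate symmetry")
    return trace.copy_with(xt.real[: len(trace)], deconvolved=True,
                           blank_head=blank_head)


def subtract_cp_record(
    whole_cell: CurrentTrace, cell_attached: CurrentTrace
) -> CurrentTrace:
    """Remove the parasitic charging current recorded in cell-attached
    configuration from a whole-cell record (same stimulus, pointwise
    difference), before deconvolution."""
    if len(whole_cell) != len(cell_attached) or abs(
        whole_cell.dt - cell_attached.dt
    ) > 1e-15:
        raise DeconvolutionError("records must share protocol, dt and length")
    return whole_cell.copy_with(
        whole_cell.samples - cell_attached.samples, cp_subtracted=True
    )
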