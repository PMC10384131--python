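"""Zero-phase FIR band-pass filtering and moving-average smoothing.

Offline EEG analysis can afford non-causal filtering, which removes the
group delay a linear-phase FIR filter would otherwise introduce.  The
scheme implemented here is the classic forward-backward construction

    y = flip(h * flip(h * x))

where ``*`` is convolution and ``flip`` reverses sample order: the signal
is filtered, time-reversed, filtered again and reversed back.  The net
phase response is identically zero and the magnitude response is the
square of the single-pass response.

Filters are Kaiser-window band-pass FIR designs.  The default design
budget is 466 taps, which at 128 samples/s yields roughly a 1 Hz
transition width at 60 dB stopband attenuation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .bands import BandDefinition

#: Default FIR length (number of coefficients).
DEFAULT_N_TAPS = 466

#: Kaiser shape parameter giving ~60 dB sidelobe attenuation.
DEFAULT_KAISER_BETA = float(_sig.kaiser_beta(60.0))

#: Default box length of the simple moving average (1 s at 128 Hz).
DEFAULT_SMA_WINDOW = 128


def flip(x: np.ndarray) -> np.ndarray:
    """Reverse the sample order of a 1-D signal.

    ``flip(x)[j] == x[M-1-j]`` for a signal of length ``M``; applying it
    twice returns the original signal.
    """
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("cannot flip an empty signal")
    return x[::-1]


@dataclass(frozen=True)
class FilterSpec:
    """A designed band-pass filter: coefficients plus provenance."""

    band_name: str
    low_hz: float
    high_hz: float
    fs: float
    kaiser_beta: float
    coefficients: np.ndarray = field(repr=False)

    @property
    def n_taps(self) -> int:
        return len(self.coefficients)

    def to_json(self) -> str:
        """Serialize design parameters (not the taps) for provenance logs."""
        return json.dumps(
            {
                "band": self.band_name,
                "low_hz": self.low_hz,
                "high_hz": self.high_hz,
                "fs": self.fs,
                "n_taps": self.n_taps,
                "kaiser_beta": self.kaiser_beta,
            },
            sort_keys=True,
        )


def design_bandpass_filter(
    band: BandDefinition,
    fs: float,
    n_taps: int = DEFAULT_N_TAPS,
    kaiser_beta: float = DEFAULT_KAISER_BETA,
) -> FilterSpec:
    """Design a linear-phase Kaiser-window band-pass FIR filter.

    Band edges above the Nyquist limit are capped (see
    :meth:`BandDefinition.effective_edges`); a band entirely above the
    limit raises ``ValueError``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_taps < 3:
        raise ValueError("n_taps must be at least 3")
    low, high = band.effective_edges(fs)
    h = _sig.firwin(
        n_taps,
        [low, high],
        window=("kaiser", kaiser_beta),
        fs=fs,
        pass_zero=False,
    )
    return FilterSpec(
        band_name=band.name,
        low_hz=low,
        high_hz=high,
        fs=fs,
        kaiser_beta=kaiser_beta,
        coefficients=h,
    )


def _odd_reflect_pad(x: np.ndarray, pad: int) -> np.ndarray:
    """Odd-symmetric (point-reflected) extension at both ends.

    Mirrors the samples about the end points and reflects amplitudes
    through them, which keeps the extension continuous in value and slope
    and suppresses filter startup transients on finite records.
    """
    if pad >= len(x):
        raise ValueError(
            f"signal of length {len(x)} too short for padding {pad} "
            f"(need length > pad)"
        )
    left = 2.0 * x[0] - x[pad:0:-1]
    right = 2.0 * x[-1] - x[-2:-pad - 2:-1]
    return np.concatenate([left, x, right])


def forward_backward_filter(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply ``spec`` forward and backward in time (zero net phase).

    The input is extended by odd-symmetric reflection of length
    ``3*(n_taps-1)`` at each end, convolved with the filter, reversed,
    convolved again and reversed back; the extension is then discarded.
    Output length equals input length, and in-band components come out
    with zero lag.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    h = spec.coefficients
    n = len(h)
    pad = 3 * (n - 1)
    if len(x) <= pad:
        raise ValueError(
            f"signal length {len(x)} too short for forward-backward "
            f"filtering with {n} taps (needs > {pad} samples)"
        )
    xp = _odd_reflect_pad(x, pad)
    v = _sig.fftconvolve(xp, h, mode="full")
    y = _sig.fftconvolve(v[::-1], h, mode="full")[::-1]
    # Full convolution twice adds n-1 leading samples per pass; the
    # flip/convolve/flip of the second pass re-aligns so the zero-phase
    # output of xp starts at offset n-1.
    start = (n - 1) + pad
    return y[start:start + len(x)]


def filter_recording(data: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Forward-backward filter each row of a channels x samples array."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        return forward_backward_filter(data, spec)
    return np.vstack([forward_backward_filter(row, spec) for row in data])


def sma_smooth(series, window: int = DEFAULT_SMA_WINDOW) -> np.ndarray:
    """Causal simple moving average with a trailing box of ``window`` samples.

    Output ``j`` is the mean of input samples ``j-window+1 .. j`` of the
    valid region; the result has ``len(series) - window + 1`` samples.
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(x) < window:
        raise ValueError(
            f"series of length {len(x)} shorter than SMA window {window}"
        )
    kernel = np.full(window, 1.0 / window)
    return np.convolve(x, kernel, mode="valid")
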