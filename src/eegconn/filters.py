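"""Zero-phase frequency-domain bandpass filtering.

The filter is applied by masking the real FFT of the signal: unity gain
inside ``[low, high]``, raised-cosine roll-off over a ``transition``-wide
band at each edge, zero outside.  Because the mask is real and applied
symmetrically in the frequency domain, the group delay is exactly zero and
a sinusoid inside the passband keeps its amplitude and phase.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft_bandpass"]


def _bandpass_mask(freqs: np.ndarray, low: float, high: float, transition: float) -> np.ndarray:
    """Raised-cosine bandpass gain evaluated at ``freqs`` (Hz)."""
    gain = np.zeros_like(freqs)
    inside = (freqs >= low) & (freqs <= high)
    gain[inside] = 1.0
    lo_edge = (freqs >= low - transition) & (freqs < low)
    gain[lo_edge] = 0.5 * (1 + np.cos(np.pi * (low - freqs[lo_edge]) / transition))
    hi_edge = (freqs > high) & (freqs <= high + transition)
    gain[hi_edge] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_edge] - high) / transition))
    return gain


def fft_bandpass(x: np.ndarray, sampling_rate: float, low: float, high: float,
                 transition: float = 0.5, axis: int = -1) -> np.ndarray:
    """Zero-phase bandpass of ``x`` along ``axis``.

    Raises if ``high`` reaches the Nyquist frequency or the band is empty.
    """
    nyq = sampling_rate / 2.0
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high cut-off {high} Hz must be below Nyquist {nyq} Hz")
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    gain = _bandpass_mask(freqs, low, high, transition)
    spec = np.fft.rfft(x, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = gain.size
    return np.fft.irfft(spec * gain.reshape(shape), n=n, axis=axis)
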