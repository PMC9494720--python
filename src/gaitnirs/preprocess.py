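"""Pre-movement window extraction, drift removal, normalization, spectra.

The raw hemoglobin traces carry a slow zero drift that corrupts both
power-spectrum analysis and wavelet packet decomposition.  The drift is
estimated with a flat-structuring-element mathematical morphology
filter — the average of the close-open and open-close alternating
filters — and subtracted.  The drift-free window is then rescaled
channel by channel to [-1, 1] to reduce between-subject amplitude
differences:

    xN = 2 * (x - min) / (max - min) - 1

All analysis operates on the 180 samples immediately preceding movement
onset (~23 s at the 0.13 s sampling period), so that every feature is a
property of motion *intention*, not of movement itself.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import grey_dilation, grey_erosion
from scipy.signal import periodogram

from .core import PRE_WINDOW, Recording, Spectrum, ValidationError

#: default flat structuring element length, samples (~4 s at 0.13 s)
SE_LENGTH = 31


def extract_premovement(recording: Recording, n: int = PRE_WINDOW) -> np.ndarray:
    """Return the ``n`` samples before movement onset, per channel.

    The window is half-open: samples at indices
    ``[onset_index - n, onset_index)``.
    """
    if n <= 0:
        raise ValidationError("window length must be positive")
    if recording.onset_index < n:
        raise ValidationError(
            f"pre-movement window of {n} samples requested but onset is at "
            f"index {recording.onset_index}"
        )
    return recording.samples[:, recording.onset_index - n : recording.onset_index]


def _check_se(se_length: int, n: int) -> None:
    if se_length < 3 or se_length % 2 == 0 or se_length >= n:
        raise ValidationError(
            f"structuring element length must be odd, >= 3 and shorter than "
            f"the signal ({n} samples); got {se_length}"
        )


def morphological_baseline(x: np.ndarray, se_length: int = SE_LENGTH) -> np.ndarray:
    """Zero-drift baseline: average of close(open(x)) and open(close(x)).

    Erosion and dilation are sliding minima/maxima over a flat window of
    ``se_length`` samples with replicated edges.  The open-close /
    close-open average balances the downward bias of opening against the
    upward bias of closing.
    """
    x = np.asarray(x, dtype=float)
    _check_se(se_length, x.shape[-1])

    def er(v: np.ndarray) -> np.ndarray:
        return grey_erosion(v, size=se_length, mode="nearest")

    def di(v: np.ndarray) -> np.ndarray:
        return grey_dilation(v, size=se_length, mode="nearest")

    def opening(v: np.ndarray) -> np.ndarray:
        return di(er(v))

    def closing(v: np.ndarray) -> np.ndarray:
        return er(di(v))

    return 0.5 * (closing(opening(x)) + opening(closing(x)))


def remove_zero_drift(x: np.ndarray, se_length: int = SE_LENGTH) -> np.ndarray:
    """Subtract the morphological baseline from ``x``.

    A constant series maps to all zeros, and adding a constant to the
    input does not change the output.
    """
    x = np.asarray(x, dtype=float)
    return x - morphological_baseline(x, se_length)


def normalize_signal(x: np.ndarray) -> np.ndarray:
    """Rescale to [-1, 1]: ``2 * (x - min) / (max - min) - 1``.

    Raises
    ------
    ValidationError
        If the input is constant (zero range).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValidationError("cannot normalize a constant signal (zero range)")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def power_spectrum(x: np.ndarray, sampling_period: float) -> Spectrum:
    """One-sided rectangular-window (i.e. untapered) periodogram.

    The mean is removed before transforming; with ``scaling='spectrum'``
    the bin powers sum to the signal variance (Parseval), which is the
    natural scale for reading off dominant oscillation frequencies.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValidationError(f"need at least 8 samples for a spectrum, got {x.size}")
    freqs, power = periodogram(
        x,
        fs=1.0 / sampling_period,
        window="boxcar",
        detrend="constant",
        scaling="spectrum",
    )
    return Spectrum(frequencies=freqs, power=power)


def preprocess_window(
    recording: Recording,
    window: int = PRE_WINDOW,
    se_length: int = SE_LENGTH,
) -> np.ndarray:
    """Extract, drift-correct and normalize the pre-movement window.

    Returns an ``(n_channels, window)`` matrix; each channel is
    independently drift-corrected and rescaled to [-1, 1] over the
    window (normalizing over the analysis window rather than the whole
    trial, since nothing outside the window is used downstream).
    """
    pre = extract_premovement(recording, window)
    out = np.empty_like(pre)
    for c in range(pre.shape[0]):
        out[c] = normalize_signal(remove_zero_drift(pre[c], se_length))
    return out
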