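"""Wavelet-packet subband decomposition and pre-movement slope features.

The hemodynamic power of interest lives below 0.18 Hz.  A level-7
wavelet packet decomposition of a signal sampled every 0.13 s splits the
0–3.85 Hz range into 128 terminal subbands of ~0.03 Hz each; the six
lowest-frequency leaves tile 0–0.18 Hz (pd1 … pd6).  Each leaf is
reconstructed back to the original time grid (all other leaves zeroed),
and the feature of a (subband, channel) cell is the per-sample slope of
the reconstructed subband averaged over the 8 samples (~1 s) just
before movement onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .core import BandFeatureMatrix, Recording, StageError, ValidationError
from .preprocess import SE_LENGTH, preprocess_window

#: wavelet packet decomposition depth: 2**7 = 128 terminal subbands
LEVEL = 7

#: number of low-frequency subbands kept (they tile 0-0.18 Hz)
N_BANDS = 6

#: default orthogonal wavelet; short support suits 180-sample windows
WAVELET = "db4"

#: default boundary extension mode
MODE = "symmetric"

#: slope values averaged before onset (~1 s at 0.13 s sampling)
N_AVG = 8


def band_edges(
    sampling_period: float, level: int = LEVEL, n_bands: int = N_BANDS
) -> np.ndarray:
    """Frequency edges of the lowest ``n_bands`` terminal subbands.

    Returns an ``(n_bands, 2)`` array of (low, high) Hz; band k spans
    ``((k-1)*w, k*w]`` with ``w = Nyquist / 2**level``.
    """
    nyquist = 0.5 / sampling_period
    width = nyquist / 2**level
    k = np.arange(n_bands)
    return np.column_stack([k * width, (k + 1) * width])


@dataclass
class SubbandSet:
    """Reconstructed terminal subbands of one time series.

    ``signals[k]`` is the reconstruction of frequency-ordered leaf k on
    the original time grid; ``edges[k]`` its (low, high) Hz range.
    """

    signals: np.ndarray
    edges: np.ndarray
    level: int
    wavelet: str


def wavelet_packet_subbands(
    x: np.ndarray,
    sampling_period: float,
    level: int = LEVEL,
    n_bands: int = N_BANDS,
    wavelet: str = WAVELET,
    mode: str = MODE,
) -> SubbandSet:
    """Decompose ``x`` and reconstruct its lowest ``n_bands`` leaves.

    Terminal nodes are taken in *frequency* order (Gray-code corrected),
    so leaf k genuinely spans the k-th 0.03 Hz slice; tree-path order
    would scramble the band indexing.  Reconstructing each leaf with all
    other leaves zeroed is a linear operation, so the sum of all
    ``2**level`` reconstructions equals the input exactly.

    Set ``n_bands=2**level`` to obtain every leaf (e.g. to verify
    perfect reconstruction).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValidationError(f"need at least 64 samples, got {x.size}")
    if not 1 <= n_bands <= 2**level:
        raise ValidationError(f"n_bands must be in 1..{2 ** level}")
    try:
        wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode=mode, maxlevel=level)
        leaves = wp.get_level(level, order="freq")
    except ValueError as exc:
        raise StageError("band_features", f"wavelet {wavelet!r}: {exc}") from exc

    signals = np.empty((n_bands, x.size))
    for k, node in enumerate(leaves[:n_bands]):
        lone = pywt.WaveletPacket(data=None, wavelet=wavelet, mode=mode, maxlevel=level)
        lone[node.path] = node.data
        signals[k] = lone.reconstruct(update=False)[: x.size]
    return SubbandSet(
        signals=signals,
        edges=band_edges(sampling_period, level, n_bands),
        level=level,
        wavelet=wavelet,
    )


def slope_features(
    bands: SubbandSet | np.ndarray, onset_index: int, n_avg: int = N_AVG
) -> np.ndarray:
    """Mean pre-onset slope of each subband, signal units per sample.

    The slope series of a band signal is its one-sample first
    difference ``s[t] = x[t] - x[t-1]``; the feature is the mean of the
    ``n_avg`` slope values at indices ``[onset_index - n_avg,
    onset_index)``.  For a linear ramp ``a * t`` the feature is exactly
    ``a`` at any window position.
    """
    signals = bands.signals if isinstance(bands, SubbandSet) else np.asarray(bands, float)
    if onset_index < n_avg + 1:
        raise ValidationError(
            f"need at least {n_avg + 1} samples before onset, onset is at {onset_index}"
        )
    if onset_index > signals.shape[-1]:
        raise ValidationError("onset_index lies beyond the band signals")
    slopes = np.diff(signals, axis=-1)  # slopes[..., t-1] = x[t] - x[t-1]
    return slopes[..., onset_index - n_avg - 1 : onset_index - 1].mean(axis=-1)


def compute_feature_matrix(
    recording: Recording,
    window: int = 180,
    se_length: int = SE_LENGTH,
    level: int = LEVEL,
    n_bands: int = N_BANDS,
    wavelet: str = WAVELET,
    mode: str = MODE,
    n_avg: int = N_AVG,
) -> BandFeatureMatrix:
    """Full per-trial feature extraction: a 6 x 22 slope matrix.

    Preprocesses the pre-movement window (drift removal, [-1, 1]
    normalization), decomposes each channel into subbands, and reads the
    8-point mean slope of every (subband, channel) cell at the window
    end, i.e. immediately before movement.
    """
    pre = preprocess_window(recording, window, se_length)
    values = np.empty((n_bands, pre.shape[0]))
    for c in range(pre.shape[0]):
        sub = wavelet_packet_subbands(
            pre[c], recording.sampling_period, level, n_bands, wavelet, mode
        )
        values[:, c] = slope_features(sub, onset_index=window, n_avg=n_avg)
    return BandFeatureMatrix(
        values=values,
        subject_id=recording.subject_id,
        state=recording.state,
        signal_kind=recording.signal_kind,
    )
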