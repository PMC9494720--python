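"""Core containers and errors shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import GaitState

#: default sampling period of the optical topography system, seconds
SAMPLING_PERIOD = 0.13

#: number of measurement channels
N_CHANNELS = 22

#: hemoglobin signal kinds analysed: total hemoglobin and the
#: oxygenated-minus-deoxygenated difference
SIGNAL_KINDS = ("totalHb", "oxy_minus_deoxy")

#: pre-movement window length, samples
PRE_WINDOW = 180


class ValidationError(ValueError):
    """Invalid configuration or input data."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for traceability."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class Recording:
    """One subject x gait-state trial of one hemoglobin signal kind.

    Parameters
    ----------
    subject_id
        Subject identifier, e.g. ``"sub01"``.
    state
        The walked gait state.
    signal_kind
        ``"totalHb"`` or ``"oxy_minus_deoxy"``.
    samples
        Array of shape ``(n_channels, n_time)`` in relative
        concentration units.
    sampling_period
        Sampling period in seconds.
    onset_index
        Sample index at which movement starts; everything before it is
        rest carrying the motion intention.
    """

    subject_id: str
    state: GaitState
    signal_kind: str
    samples: np.ndarray
    sampling_period: float = SAMPLING_PERIOD
    onset_index: int = PRE_WINDOW

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValidationError(
                f"unknown signal kind {self.signal_kind!r}; expected one of {SIGNAL_KINDS}"
            )
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a (n_channels, n_time) matrix")
        if self.sampling_period <= 0:
            raise ValidationError("sampling_period must be positive")
        if not (0 < self.onset_index <= self.samples.shape[1]):
            raise ValidationError("onset_index must lie within the recording")
        if np.isnan(self.samples).any():
            raise ValidationError("samples contain missing values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_time(self) -> int:
        return self.samples.shape[1]


@dataclass
class BandFeatureMatrix:
    """Pre-movement slope features: 6 subbands x 22 channels.

    ``values[k, c]`` is the mean slope (signal units per sample) of
    subband ``k+1`` of channel ``c+1`` over the last few samples before
    movement onset.
    """

    values: np.ndarray
    subject_id: str
    state: GaitState
    signal_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (6, N_CHANNELS):
            raise ValidationError(
                f"feature matrix must be 6 x {N_CHANNELS}, got {self.values.shape}"
            )


@dataclass
class Spectrum:
    """One-sided power spectrum."""

    frequencies: np.ndarray
    power: np.ndarray
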