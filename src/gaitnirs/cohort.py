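"""Synthetic fNIRS cohorts with controllable class-discriminative effects.

Real recordings of the walking protocol are not available, so the
pipeline is exercised on synthetic cohorts that reproduce the data's
*statistical* structure: per subject and gait state, 22 channels of
slow-drifting, low-frequency-oscillating hemoglobin-like signal with a
known movement-onset index and at least 180 samples of pre-movement
rest.  Each channel is the sum of

* a constant offset plus a low-frequency random-walk drift (the
  component the morphology filter must remove),
* a broadband oscillatory background: sinusoids at random frequencies
  in 0.005–0.18 Hz with 1/f-weighted amplitudes and random phases,
  normalized to unit standard deviation (the signal-unit scale),
* white measurement noise,
* optionally, class-discriminative effects: a sinusoid at the centre
  frequency of a chosen subband, phase-locked to cross zero at movement
  onset, whose amplitude is chosen so that its per-sample slope at
  onset equals the class's prescribed offset.  The effect therefore
  lands in exactly one (subband, channel, signal kind) cell of the
  slope-feature matrix, scaled per subject by a truncated-normal
  factor.

The generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .bands import band_edges
from .core import N_CHANNELS, Recording, SAMPLING_PERIOD, SIGNAL_KINDS, ValidationError
from .states import STATES, GaitState

#: number of background sinusoids per channel
_N_SINES = 24


@dataclass(frozen=True)
class EffectSpec:
    """A class-discriminative slope effect in one feature cell.

    ``class_offsets`` maps a label — either a full gait-state label like
    ``"SP-LD"`` or a class level like ``"LD"`` / ``"MP"`` — to the
    injected pre-onset slope in signal units per sample.  Lookup
    precedence for a given recording: exact state label, then the
    state's speed level, then its step level; unlisted states get zero.
    """

    subband: int
    channel: int
    signal_kind: str
    class_offsets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.subband <= 6:
            raise ValidationError("subband must be in 1..6 (0-0.18 Hz)")
        if not 1 <= self.channel <= N_CHANNELS:
            raise ValidationError(f"channel must be in 1..{N_CHANNELS}")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValidationError(f"signal_kind must be one of {SIGNAL_KINDS}")
        object.__setattr__(self, "class_offsets", dict(self.class_offsets))

    def offset_for(self, state: GaitState) -> float:
        for key in (state.label, state.speed, state.step):
            if key in self.class_offsets:
                return float(self.class_offsets[key])
        return 0.0

    def to_dict(self) -> dict:
        return {
            "subband": self.subband,
            "channel": self.channel,
            "signal_kind": self.signal_kind,
            "class_offsets": dict(self.class_offsets),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EffectSpec":
        return cls(
            subband=int(d["subband"]),
            channel=int(d["channel"]),
            signal_kind=str(d["signal_kind"]),
            class_offsets={str(k): float(v) for k, v in d["class_offsets"].items()},
        )


@dataclass
class SynthConfig:
    """Study-shaped synthetic cohort settings.

    Defaults mirror the walking protocol: 31 subjects, the six walked
    gait states, 22 channels sampled every 0.13 s, and a rest period of
    300 samples (~39 s) before movement onset.  ``drift_amplitude`` and
    ``noise_sd`` are in units of the oscillatory background's standard
    deviation; ``subject_sd`` scales the between-subject spread of the
    injected effects.
    """

    n_subjects: int = 31
    states: tuple[GaitState, ...] = STATES
    n_channels: int = N_CHANNELS
    sampling_period: float = SAMPLING_PERIOD
    pre_onset_samples: int = 300
    post_onset_samples: int = 60
    drift_amplitude: float = 2.0
    noise_sd: float = 0.3
    effect_map: tuple[EffectSpec, ...] = ()
    subject_sd: float = 0.3
    signal_kinds: tuple[str, ...] = SIGNAL_KINDS
    seed: int = 0

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.effect_map = tuple(self.effect_map)
        self.signal_kinds = tuple(self.signal_kinds)
        if self.n_subjects < 1 or self.n_channels < 1 or self.post_onset_samples < 0:
            raise ValidationError("non-positive cohort dimensions")
        if self.pre_onset_samples < 180:
            raise ValidationError(
                "pre_onset_samples must be >= 180 (pre-movement window requirement)"
            )
        if self.sampling_period <= 0:
            raise ValidationError("sampling_period must be positive")
        if not self.states:
            raise ValidationError("empty state set")
        if len(set(self.states)) != len(self.states):
            raise ValidationError("duplicate gait states")
        if not set(self.signal_kinds) <= set(SIGNAL_KINDS):
            raise ValidationError(f"signal kinds must be among {SIGNAL_KINDS}")
        for eff in self.effect_map:
            if eff.channel > self.n_channels:
                raise ValidationError(
                    f"effect channel {eff.channel} exceeds n_channels={self.n_channels}"
                )

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(f"sub{i + 1:02d}" for i in range(self.n_subjects))


def demo_effect_map(slope: float = 0.15) -> tuple[EffectSpec, ...]:
    """Canonical discriminative effects for demonstrations and validation.

    One effect per classification dimension, each spanning the two
    adjacent subbands pd5-pd6 (where end-of-window slope features are
    most sensitive; see the methods notes) of a single channel, with
    opposite slopes in the two multi-state classes of its dimension:

    * walking speed — totalHb, channel 15: LD -slope, MD +slope, HD 0;
    * step length — oxyHb-deoxyHb, channel 8: SP -slope, MP +slope, LP 0.
    """
    speed = {"LD": -slope, "MD": slope, "HD": 0.0}
    step = {"SP": -slope, "MP": slope, "LP": 0.0}
    return tuple(
        [EffectSpec(subband=b, channel=15, signal_kind="totalHb", class_offsets=speed)
         for b in (5, 6)]
        + [EffectSpec(subband=b, channel=8, signal_kind="oxy_minus_deoxy",
                      class_offsets=step)
           for b in (5, 6)]
    )


def _background(
    rng: np.random.Generator, n_channels: int, n_time: int, dt: float, noise_sd: float,
    drift_amplitude: float,
) -> np.ndarray:
    """Offset + random-walk drift + unit-sd oscillation + white noise."""
    t = np.arange(n_time) * dt
    out = np.empty((n_channels, n_time))
    for c in range(n_channels):
        offset = rng.normal(0.0, drift_amplitude)
        walk = np.cumsum(rng.normal(0.0, 1.0, n_time))
        walk = drift_amplitude * (walk - walk[0]) / np.sqrt(n_time)
        freqs = rng.uniform(0.005, 0.18, _N_SINES)
        phases = rng.uniform(0.0, 2 * np.pi, _N_SINES)
        amps = 1.0 / freqs
        amps *= np.sqrt(2.0 / np.sum(amps**2))  # unit-variance background
        osc = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None])).sum(
            axis=0
        )
        noise = rng.normal(0.0, noise_sd, n_time)
        out[c] = offset + walk + osc + noise
    return out


def generate_cohort(config: SynthConfig) -> list[Recording]:
    """Generate one Recording per (subject, state, signal kind).

    Iteration order — subjects, then states, then signal kinds — is
    fixed, so a given seed always yields a bitwise-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n_time = config.pre_onset_samples + config.post_onset_samples
    centers = band_edges(config.sampling_period).mean(axis=1)
    i = np.arange(n_time)

    recordings: list[Recording] = []
    for subject in config.subject_ids:
        # one multiplicative effect-strength factor per subject
        factor = max(0.0, rng.normal(1.0, config.subject_sd))
        for state in config.states:
            for kind in config.signal_kinds:
                samples = _background(
                    rng,
                    config.n_channels,
                    n_time,
                    config.sampling_period,
                    config.noise_sd,
                    config.drift_amplitude,
                )
                for eff in config.effect_map:
                    if eff.signal_kind != kind:
                        continue
                    slope = eff.offset_for(state) * factor
                    if slope == 0.0:
                        continue
                    # sinusoid at the subband centre frequency crossing zero
                    # at onset with per-sample slope `slope`
                    omega = 2 * np.pi * centers[eff.subband - 1] * config.sampling_period
                    samples[eff.channel - 1] += (slope / omega) * np.sin(
                        omega * (i - config.pre_onset_samples)
                    )
                recordings.append(
                    Recording(
                        subject_id=subject,
                        state=state,
                        signal_kind=kind,
                        samples=samples,
                        sampling_period=config.sampling_period,
                        onset_index=config.pre_onset_samples,
                    )
                )
    return recordings
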