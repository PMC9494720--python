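"""Gait states and their grouping into step-length / walking-speed classes.

The protocol uses six gait states, each a (step length, walking speed)
pair: small/mid/large step (SP, MP, LP) crossed with low/mid/high speed
(LD, MD, HD), of which only six combinations were walked.  For
classification, the six states collapse into three classes along either
dimension: e.g. along walking speed, LD = {SP-LD, MP-LD},
MD = {SP-MD, MP-MD, LP-MD}, HD = {MP-HD}.
"""

from __future__ import annotations

from dataclasses import dataclass

STEPS = ("SP", "MP", "LP")
SPEEDS = ("LD", "MD", "HD")

#: the six walked (step, speed) combinations
VALID_COMBINATIONS = frozenset(
    {("SP", "LD"), ("SP", "MD"), ("MP", "LD"), ("MP", "MD"), ("MP", "HD"), ("LP", "MD")}
)

DIMENSIONS = ("step_length", "walking_speed")


@dataclass(frozen=True, order=True)
class GaitState:
    """One of the six walked gait states, e.g. ``GaitState("SP", "LD")``."""

    step: str
    speed: str

    def __post_init__(self) -> None:
        if (self.step, self.speed) not in VALID_COMBINATIONS:
            raise ValueError(
                f"invalid gait state {self.step}-{self.speed}; "
                f"valid states: {sorted(s + '-' + d for s, d in VALID_COMBINATIONS)}"
            )

    @property
    def label(self) -> str:
        return f"{self.step}-{self.speed}"

    @classmethod
    def from_label(cls, label: str) -> "GaitState":
        step, _, speed = label.partition("-")
        return cls(step, speed)

    def class_of(self, dimension: str) -> str:
        """Class label of this state along ``dimension``.

        Along ``"step_length"`` the class is the step level (SP/MP/LP);
        along ``"walking_speed"`` it is the speed level (LD/MD/HD).
        """
        if dimension == "step_length":
            return self.step
        if dimension == "walking_speed":
            return self.speed
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")


#: canonical ordering of the six states
STATES = tuple(
    GaitState(step, speed)
    for step in STEPS
    for speed in SPEEDS
    if (step, speed) in VALID_COMBINATIONS
)


def dimension_classes(dimension: str) -> tuple[str, ...]:
    """The three class labels of a dimension, in canonical order."""
    if dimension == "step_length":
        return STEPS
    if dimension == "walking_speed":
        return SPEEDS
    raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")


def constituent_states(class_label: str, dimension: str) -> tuple[GaitState, ...]:
    """All gait states belonging to one class of one dimension."""
    if class_label not in dimension_classes(dimension):
        raise ValueError(f"{class_label!r} is not a class of dimension {dimension!r}")
    return tuple(s for s in STATES if s.class_of(dimension) == class_label)
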