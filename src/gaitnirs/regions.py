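"""Spatial regrouping of the 22 optode channels into 22 regions.

To blunt the effect of different head sizes, channels are regrouped
into overlapping three-channel spatial regions (Re1 … Re22); a channel
may belong to several regions.  Selection statistics are counted per
region rather than per fixed channel.
"""

from __future__ import annotations

#: region id (1..22) -> the three member channel ids (1..22)
REGION_MAP: dict[int, tuple[int, int, int]] = {
    1: (1, 3, 6),
    2: (3, 6, 8),
    3: (6, 8, 11),
    4: (8, 11, 13),
    5: (11, 13, 16),
    6: (13, 16, 18),
    7: (16, 18, 21),
    8: (1, 2, 4),
    9: (4, 6, 7),
    10: (6, 7, 9),
    11: (9, 11, 12),
    12: (11, 12, 14),
    13: (14, 16, 17),
    14: (16, 17, 19),
    15: (19, 21, 22),
    16: (2, 5, 7),
    17: (5, 7, 10),
    18: (7, 10, 12),
    19: (10, 12, 15),
    20: (12, 15, 17),
    21: (15, 17, 20),
    22: (17, 20, 22),
}

N_REGIONS = len(REGION_MAP)


def regions_containing(channel: int) -> tuple[int, ...]:
    """All region ids whose three channels include ``channel``."""
    return tuple(r for r, chans in REGION_MAP.items() if channel in chans)
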