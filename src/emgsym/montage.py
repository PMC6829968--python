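"""Electrode montage: the nine bilateral upper-limb muscles and channel labels.

The montage covers nine muscles recorded symmetrically on both body sides
(18 channels): brachioradialis (BR), pronator teres (PT), biceps (B),
triceps (T), anterior deltoid (AD), posterior deltoid (PD), pectoralis (PEC),
infraspinatus (IS) and erector spinae (ES).  Channel label strings take the
form ``"<MUSCLE>_<SIDE>"``, e.g. ``"BR_RIGHT"``; parsing is case-insensitive,
writing is canonical uppercase.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import FormatError

__all__ = [
    "Muscle",
    "Side",
    "ChannelLabel",
    "MUSCLE_ORDER",
    "FULL_MONTAGE",
    "full_montage",
]


class Muscle(str, enum.Enum):
    BR = "BR"  # brachioradialis
    PT = "PT"  # pronator teres
    B = "B"  # biceps
    T = "T"  # triceps
    AD = "AD"  # anterior deltoid
    PD = "PD"  # posterior deltoid
    PEC = "PEC"  # pectoralis
    IS = "IS"  # infraspinatus
    ES = "ES"  # erector spinae


class Side(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"

    @property
    def other(self) -> "Side":
        return Side.LEFT if self is Side.RIGHT else Side.RIGHT


#: Canonical muscle ordering; coefficient vectors are always reported in this
#: order so they are comparable across trials and subjects.
MUSCLE_ORDER: tuple[Muscle, ...] = (
    Muscle.BR,
    Muscle.PT,
    Muscle.B,
    Muscle.T,
    Muscle.AD,
    Muscle.PD,
    Muscle.PEC,
    Muscle.IS,
    Muscle.ES,
)

N_MUSCLES = len(MUSCLE_ORDER)


@dataclass(frozen=True, order=True)
class ChannelLabel:
    """One electrode channel: a (muscle, side) pair."""

    muscle: Muscle
    side: Side

    def __str__(self) -> str:
        return f"{self.muscle.value}_{self.side.value}"

    @classmethod
    def parse(cls, text: str) -> "ChannelLabel":
        """Parse a ``"<MUSCLE>_<SIDE>"`` string (case-insensitive)."""
        parts = text.strip().upper().rsplit("_", 1)
        if len(parts) != 2:
            raise FormatError(f"not a channel label: {text!r}")
        muscle_txt, side_txt = parts
        try:
            return cls(Muscle(muscle_txt), Side(side_txt))
        except ValueError as exc:
            raise FormatError(f"not a channel label: {text!r}") from exc

    @classmethod
    def try_parse(cls, text: str) -> "ChannelLabel | None":
        try:
            return cls.parse(text)
        except FormatError:
            return None


def full_montage() -> tuple[ChannelLabel, ...]:
    """All 18 channels: canonical muscle order, right side first."""
    return tuple(
        ChannelLabel(m, side) for side in (Side.RIGHT, Side.LEFT) for m in MUSCLE_ORDER
    )


FULL_MONTAGE: tuple[ChannelLabel, ...] = full_montage()
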