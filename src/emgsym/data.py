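"""In-memory containers: sessions, trial segments, metadata and index records.

A recording session holds an 18-channel (9 muscles x 2 sides) raw sEMG matrix
at a single sampling rate plus subject metadata and trial annotations.  Trials
are 20-s windows of one of two bimanual symmetric motions (repeated elbow
flexion, or steering half-cycles) paced at 0.25 Hz.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import MontageError, ParameterError, ValidationError
from .montage import FULL_MONTAGE, ChannelLabel, Side

__all__ = [
    "Group",
    "Motion",
    "SubjectMeta",
    "TrialAnnotation",
    "EmgSession",
    "TrialSegment",
    "IndexRecord",
    "NOMINAL_TRIAL_S",
]

#: Protocol trial length in seconds (motion phase only).
NOMINAL_TRIAL_S = 20.0


class Group(str, enum.Enum):
    HEALTHY_YOUNG = "healthy_young"
    HEALTHY_ELDER = "healthy_elder"
    STROKE = "stroke"


class Motion(str, enum.Enum):
    ELBOW_FLEXION = "elbow_flexion"
    STEERING = "steering"


@dataclass(frozen=True)
class SubjectMeta:
    """Subject identity and clinical grouping.

    Stroke subjects carry a SIAS level (1-5, lower = more severe paresis) and
    a paretic side; healthy subjects carry a dominant side instead.
    """

    subject_id: str
    group: Group
    sias_level: int | None = None
    paretic_side: Side | None = None
    dominant_side: Side | None = None

    def __post_init__(self) -> None:
        if self.group is Group.STROKE:
            if self.sias_level is None or self.paretic_side is None:
                raise ValidationError(
                    f"stroke subject {self.subject_id!r} needs sias_level and paretic_side"
                )
            if not 1 <= int(self.sias_level) <= 5:
                raise ValidationError(f"sias_level must be 1-5, got {self.sias_level}")
        else:
            if self.sias_level is not None:
                raise ValidationError(
                    f"healthy subject {self.subject_id!r} must not carry a sias_level"
                )
            if self.dominant_side is None:
                raise ValidationError(
                    f"healthy subject {self.subject_id!r} needs a dominant_side"
                )

    @property
    def affected_side(self) -> Side:
        """Paretic side for stroke subjects, non-dominant side for healthy ones."""
        if self.group is Group.STROKE:
            assert self.paretic_side is not None
            return self.paretic_side
        assert self.dominant_side is not None
        return self.dominant_side.other

    @property
    def reference_side(self) -> Side:
        """Non-paretic (stroke) or dominant (healthy) side."""
        return self.affected_side.other

    @property
    def group_label(self) -> str:
        """Cohort panel label: ``sias_<k>`` for stroke, group name otherwise."""
        if self.group is Group.STROKE:
            return f"sias_{self.sias_level}"
        return self.group.value


@dataclass(frozen=True)
class TrialAnnotation:
    motion: Motion
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_sample < self.end_sample:
            raise ValidationError(
                f"bad annotation bounds: [{self.start_sample}, {self.end_sample})"
            )


def _check_channels(channels: Sequence[ChannelLabel], samples: np.ndarray) -> None:
    if samples.ndim != 2:
        raise ParameterError("samples must be a [channel x time] matrix")
    if len(channels) != samples.shape[0]:
        raise MontageError(
            f"{len(channels)} labels for {samples.shape[0]} sample rows"
        )
    if len(set(channels)) != len(channels):
        raise MontageError("duplicate channel labels")


@dataclass
class EmgSession:
    """One recording session: raw multichannel sEMG plus metadata and annotations."""

    meta: SubjectMeta
    sample_rate: float
    channels: tuple[ChannelLabel, ...]
    samples: np.ndarray  # [channel x time]
    annotations: tuple[TrialAnnotation, ...] = ()
    ground_truth: dict | None = None  # synthetic sessions only

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.annotations = tuple(self.annotations)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be positive, got {self.sample_rate}")
        _check_channels(self.channels, self.samples)
        n = self.samples.shape[1]
        spans = sorted((a.start_sample, a.end_sample) for a in self.annotations)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValidationError("trial annotations overlap")
        if spans and spans[-1][1] > n:
            raise ValidationError(
                f"annotation ends at {spans[-1][1]} but session has {n} samples"
            )
        if not self.montage_complete:
            warnings.warn(
                f"incomplete montage: {len(self.channels)}/18 channels present",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def montage_complete(self) -> bool:
        return set(self.channels) >= set(FULL_MONTAGE)

    def channel(self, label: ChannelLabel | str) -> np.ndarray:
        if isinstance(label, str):
            label = ChannelLabel.parse(label)
        try:
            return self.samples[self.channels.index(label)]
        except ValueError:
            raise MontageError(f"channel {label} not in session") from None

    def extract_trials(self) -> list["TrialSegment"]:
        """Cut the annotated motion windows out of the continuous recording."""
        return [
            TrialSegment(
                motion=a.motion,
                samples=self.samples[:, a.start_sample : a.end_sample].copy(),
                channels=self.channels,
                sample_rate=self.sample_rate,
                meta=self.meta,
            )
            for a in self.annotations
        ]


@dataclass
class TrialSegment:
    """One motion window cut from a session; nominally 20 s."""

    motion: Motion
    samples: np.ndarray  # [channel x time]
    channels: tuple[ChannelLabel, ...]
    sample_rate: float
    meta: SubjectMeta | None = None
    is_envelope: bool = False  # set by preprocessing

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be positive, got {self.sample_rate}")
        _check_channels(self.channels, self.samples)
        if self.is_short:
            warnings.warn(
                f"trial shorter than nominal {NOMINAL_TRIAL_S:g} s "
                f"({self.duration_s:.2f} s)",
                stacklevel=2,
            )

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sample_rate

    @property
    def is_short(self) -> bool:
        return self.duration_s < NOMINAL_TRIAL_S - 0.5 / self.sample_rate

    def channel(self, label: ChannelLabel | str) -> np.ndarray:
        if isinstance(label, str):
            label = ChannelLabel.parse(label)
        try:
            return self.samples[self.channels.index(label)]
        except ValueError:
            raise MontageError(f"channel {label} not in segment") from None

    def with_samples(self, samples: np.ndarray, *, is_envelope: bool | None = None) -> "TrialSegment":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return replace(
                self,
                samples=samples,
                is_envelope=self.is_envelope if is_envelope is None else is_envelope,
            )


@dataclass(frozen=True)
class IndexRecord:
    """Per-trial result: the (ESB, MCS) pair plus identifying fields.

    ``mcs`` is None when undefined (a zero-variance coefficient vector, e.g.
    single-muscle or one-side-silent activity).
    """

    subject_id: str
    group: Group
    sias_level: int | None
    motion: Motion
    trial_index: int
    esb: float
    mcs: float | None

    def __post_init__(self) -> None:
        if not -1.0 <= self.esb <= 1.0:
            raise ValidationError(f"esb out of [-1, 1]: {self.esb}")
        if self.mcs is not None and not -1.0 <= self.mcs <= 1.0:
            raise ValidationError(f"mcs out of [-1, 1]: {self.mcs}")
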