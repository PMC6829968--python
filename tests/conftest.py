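import warnings

import numpy as np
import pytest

from emgsym import (
    FULL_MONTAGE,
    Group,
    Side,
    SubjectMeta,
    TrialSegment,
    Motion,
)


@pytest.fixture
def healthy_meta() -> SubjectMeta:
    return SubjectMeta(
        subject_id="hy_00", group=Group.HEALTHY_YOUNG, dominant_side=Side.RIGHT
    )


@pytest.fixture
def stroke_meta() -> SubjectMeta:
    return SubjectMeta(
        subject_id="st_00", group=Group.STROKE, sias_level=2, paretic_side=Side.LEFT
    )


def montage_segment(
    channel_values: dict,
    duration_s: float = 4.0,
    sample_rate: float = 100.0,
    meta: SubjectMeta | None = None,
    is_envelope: bool = True,
    motion: Motion = Motion.ELBOW_FLEXION,
) -> TrialSegment:
    """Full 18-channel segment with constant (or array) per-channel values.

    Channels not named in ``channel_values`` (keys: label strings) are zero.
    """
    n = int(round(duration_s * sample_rate))
    samples = np.zeros((len(FULL_MONTAGE), n))
    for i, label in enumerate(FULL_MONTAGE):
        value = channel_values.get(str(label), 0.0)
        samples[i] = value
    if meta is None:
        meta = SubjectMeta(
            subject_id="toy", group=Group.HEALTHY_ELDER, dominant_side=Side.RIGHT
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short toy segments are intentional
        return TrialSegment(
            motion=motion,
            samples=samples,
            channels=FULL_MONTAGE,
            sample_rate=sample_rate,
            meta=meta,
            is_envelope=is_envelope,
        )


@pytest.fixture
def make_segment():
    return montage_segment
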