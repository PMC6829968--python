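"""Power-decomposition motion model and the two bilateral symmetry indexes.

The electrical power of a movement is quantized per muscle as the RMS of the
conditioned sEMG envelope, computed over consecutive one-second windows and
averaged over the trial.  The total power of each body side is the sum over
its nine muscles,

    P_r = sum_i P_i(right),   P_l = sum_i P_i(left),

and each muscle's share is a normalized coordination coefficient

    a_i = P_i / P_r,   b_i = P_i / P_l,   sum_i a_i = sum_i b_i = 1.

Two per-trial indexes summarize bilateral motor performance:

* **ESB** (effective strength balance) — the normalized power difference
  ``(P_r - P_l) / (P_r + P_l)`` in [-1, 1]; 0 means both sides contract with
  equal total electrical power, +/-1 total dominance of one side.
* **MCS** (muscle coordination similarity) — the Pearson product-moment
  correlation between the two sides' coefficient vectors (a_i, b_i) over the
  n muscle pairs; 1 is perfect muscle mirroring, values below 0 indicate
  symmetric muscles have switched roles.

The two indexes are deliberately dissociated: rescaling all of one side's
powers moves ESB but leaves MCS untouched (coefficients are scale-free),
while redistributing power among one side's muscles moves MCS but not ESB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import IndexRecord, TrialSegment
from .errors import (
    DegenerateSignalError,
    LengthError,
    MontageError,
    ParameterError,
    UndefinedIndexError,
)
from .montage import MUSCLE_ORDER, ChannelLabel, Muscle, Side

__all__ = [
    "MusclePowers",
    "CoordinationCoefficients",
    "SymmetryIndexes",
    "BoxplotStats",
    "rms_per_second",
    "trial_powers",
    "coordination_coefficients",
    "effective_strength_balance",
    "muscle_coordination_similarity",
    "trial_indexes",
    "boxplot_stats",
    "activity_print",
]


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class MusclePowers:
    """Per-muscle electrical power P_i and the side totals P_r, P_l."""

    powers: Mapping[ChannelLabel, float]

    def __post_init__(self) -> None:
        for label, p in self.powers.items():
            if p < 0:
                raise ParameterError(f"negative power for {label}: {p}")

    def side_vector(self, side: Side) -> np.ndarray:
        """P_i for one side in canonical muscle order."""
        return np.array(
            [self.powers[ChannelLabel(m, side)] for m in MUSCLE_ORDER], dtype=float
        )

    @property
    def total_right(self) -> float:
        return float(self.side_vector(Side.RIGHT).sum())

    @property
    def total_left(self) -> float:
        return float(self.side_vector(Side.LEFT).sum())

    @property
    def n_muscles(self) -> int:
        return len(MUSCLE_ORDER)


@dataclass(frozen=True)
class CoordinationCoefficients:
    """Normalized power shares a (right) and b (left), each summing to 1."""

    a: np.ndarray
    b: np.ndarray
    muscles: tuple[Muscle, ...] = MUSCLE_ORDER

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ParameterError("coefficient vectors must be equal-length 1-D")
        if len(self.muscles) != len(self.a):
            raise ParameterError("muscle order length mismatch")
        for name, v in (("a", self.a), ("b", self.b)):
            if np.any(v < -1e-15):
                raise ParameterError(f"{name} has negative entries")
            if abs(float(v.sum()) - 1.0) > 1e-9:
                raise ParameterError(f"{name} does not sum to 1: {v.sum()!r}")

    def vector(self, side: Side) -> np.ndarray:
        return self.a if side is Side.RIGHT else self.b


@dataclass(frozen=True)
class SymmetryIndexes:
    esb: float
    mcs: float | None


# ---------------------------------------------------------------------------
# power extraction

def rms_per_second(envelope: np.ndarray, sample_rate: float) -> np.ndarray:
    """RMS over consecutive, non-overlapping 1-s windows.

    The trailing partial second is dropped.  Raises if the segment is shorter
    than one second.
    """
    envelope = np.asarray(envelope, dtype=float)
    win = int(round(sample_rate))
    if win <= 0:
        raise ParameterError(f"sample_rate must be positive, got {sample_rate}")
    n = envelope.shape[-1] // win
    if n < 1:
        raise LengthError(
            f"segment of {envelope.shape[-1]} samples shorter than 1 s at {sample_rate:g} Hz"
        )
    trimmed = envelope[..., : n * win]
    windows = trimmed.reshape(*trimmed.shape[:-1], n, win)
    return np.sqrt(np.mean(windows**2, axis=-1))


def trial_powers(segment: TrialSegment, edge_trim_s: float = 1.0) -> MusclePowers:
    """Per-muscle trial power: mean of per-second RMS over the motion window.

    The first and last ``edge_trim_s`` seconds are excluded (filter edge
    transients).  Requires the full 18-channel montage.
    """
    from .montage import FULL_MONTAGE

    missing = [lab for lab in FULL_MONTAGE if lab not in segment.channels]
    if missing:
        raise MontageError(f"missing channels: {', '.join(map(str, missing))}")
    trim = int(round(edge_trim_s * segment.sample_rate))
    stop = segment.samples.shape[1] - trim
    if stop - trim < segment.sample_rate:
        raise LengthError(
            f"trial leaves {max(stop - trim, 0)} samples after {edge_trim_s:g}-s edge trim; "
            "need at least one full second"
        )
    powers: dict[ChannelLabel, float] = {}
    for label in FULL_MONTAGE:
        window = segment.channel(label)[trim:stop]
        powers[label] = float(np.mean(rms_per_second(window, segment.sample_rate)))
    return MusclePowers(powers)


def coordination_coefficients(powers: MusclePowers) -> CoordinationCoefficients:
    """Normalize each side's power vector to its side total: a_i = P_i / P_r."""
    pr, pl = powers.total_right, powers.total_left
    if pr <= 0 or pl <= 0:
        raise DegenerateSignalError(
            f"zero side total (P_r={pr:g}, P_l={pl:g}); coefficients undefined"
        )
    return CoordinationCoefficients(
        a=powers.side_vector(Side.RIGHT) / pr,
        b=powers.side_vector(Side.LEFT) / pl,
    )


# ---------------------------------------------------------------------------
# the two indexes

def effective_strength_balance(p_right: float, p_left: float) -> float:
    """ESB = (P_r - P_l) / (P_r + P_l), in [-1, 1]."""
    if p_right < 0 or p_left < 0:
        raise ParameterError("side powers must be nonnegative")
    total = p_right + p_left
    if total <= 0:
        raise UndefinedIndexError("both side powers are zero; ESB undefined")
    return (p_right - p_left) / total


def muscle_coordination_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """MCS: Pearson product-moment correlation of the n (a_i, b_i) muscle pairs.

    Evaluated in the summation form

        MCS = (n * sum(a*b) - sum(a) * sum(b)) /
              sqrt(n * sum(a^2) - sum(a)^2) / sqrt(n * sum(b^2) - sum(b)^2)

    Raises :class:`UndefinedIndexError` when either vector has zero variance
    (the denominator vanishes) — the index is flagged, never silently 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError(f"vector length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n < 3:
        raise ParameterError(f"need at least 3 muscle pairs, got {n}")
    num = n * float(a @ b) - float(a.sum()) * float(b.sum())
    da = n * float(a @ a) - float(a.sum()) ** 2
    db = n * float(b @ b) - float(b.sum()) ** 2
    # zero-variance guard with a relative floor against rounding noise
    tol = 1e-24 * n * n
    if da <= tol * max(1.0, float(a @ a)) or db <= tol * max(1.0, float(b @ b)):
        raise UndefinedIndexError("zero-variance coefficient vector; MCS undefined")
    r = num / (math.sqrt(da) * math.sqrt(db))
    # rounding can push |r| past 1 by ~1e-16; the index is bounded by construction
    return min(1.0, max(-1.0, r))


def trial_indexes(
    segment: TrialSegment, trial_index: int = 0, edge_trim_s: float = 1.0
) -> IndexRecord:
    """Compute the per-trial (ESB, MCS) record from a conditioned segment.

    A trial with one silent side yields ESB = +/-1 with MCS undefined; a trial
    silent on both sides is rejected.
    """
    if segment.meta is None:
        raise ParameterError("segment carries no subject metadata")
    powers = trial_powers(segment, edge_trim_s=edge_trim_s)
    pr, pl = powers.total_right, powers.total_left
    esb = effective_strength_balance(pr, pl)  # raises if both zero
    mcs: float | None
    if pr <= 0 or pl <= 0:
        mcs = None
    else:
        coeffs = coordination_coefficients(powers)
        try:
            mcs = muscle_coordination_similarity(coeffs.a, coeffs.b)
        except UndefinedIndexError:
            mcs = None
    meta = segment.meta
    return IndexRecord(
        subject_id=meta.subject_id,
        group=meta.group,
        sias_level=meta.sias_level,
        motion=segment.motion,
        trial_index=trial_index,
        esb=esb,
        mcs=mcs,
    )


# ---------------------------------------------------------------------------
# muscle activity print (boxplot statistics of the coefficients)

@dataclass(frozen=True)
class BoxplotStats:
    """Tukey boxplot summary: quartiles, 1.5-IQR whiskers, outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = field(default_factory=tuple)
    n: int = 0


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Quartiles by linear interpolation; whiskers clipped to the most extreme
    points within 1.5 IQR of the quartiles; everything beyond is an outlier."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 1:
        raise ParameterError("no values")
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
        n=int(x.size),
    )


#: side roles of the activity print: "reference" = dominant arm of healthy
#: subjects / non-paretic arm of patients; "affected" = the opposite arm.
SIDE_ROLES = ("reference", "affected")


def activity_print(
    coefficient_sets: Sequence[CoordinationCoefficients],
    affected_sides: Sequence[Side],
    min_trials: int = 4,
) -> dict[tuple[Muscle, str], BoxplotStats]:
    """Distribution of the coordination coefficients across trials.

    Each trial contributes one coefficient per muscle and side; sides are
    mapped to roles via ``affected_sides`` (the paretic arm for patients, the
    non-dominant arm for healthy subjects).  Returns boxplot statistics per
    (muscle, role); quartile convention: linear interpolation between order
    statistics.
    """
    if len(coefficient_sets) != len(affected_sides):
        raise ParameterError("one affected side required per coefficient set")
    if len(coefficient_sets) < min_trials:
        raise ParameterError(
            f"need at least {min_trials} trials, got {len(coefficient_sets)}"
        )
    pooled: dict[tuple[Muscle, str], list[float]] = {
        (m, role): [] for m in MUSCLE_ORDER for role in SIDE_ROLES
    }
    for coeffs, affected in zip(coefficient_sets, affected_sides):
        for role, side in (("affected", affected), ("reference", affected.other)):
            vec = coeffs.vector(side)
            for m, value in zip(coeffs.muscles, vec):
                pooled[(m, role)].append(float(value))
    return {key: boxplot_stats(vals) for key, vals in pooled.items()}
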