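"""Seeded synthetic bimanual sEMG: trials and whole cohorts with ground truth.

The generator produces the statistical features the analysis pipeline
consumes, not a physiological motor-unit simulation.  Each channel is
amplitude-modulated band-limited Gaussian noise — the standard surrogate for
the sEMG interference pattern:

    x_i(t) = gain_side * w_i * E(t) * G_i(t) + noise_floor * G'_i(t)

where ``w_i`` is the side's ground-truth coordination weight (nonnegative,
summing to 1 over the nine muscles), ``E(t)`` a smooth periodic burst
envelope at the motion pacing frequency (0.25 Hz — one cycle per 4 s, bursts
shaped as raised-cosine/Tukey pulses with configurable duty and onset
jitter), and ``G``, ``G'`` independent zero-mean unit-variance noise carriers
band-limited to the 20-450 Hz sEMG band.  Because the trial power extracted
downstream is an RMS amplitude, it is linear in the channel gain: a side
gain ratio g maps to an expected ESB of (g-1)/(g+1), and the recovered
coordination coefficients approach the programmed weights.

Cohort generation layers a simple impairment model on top: per subject, the
paretic side receives a strength gain ratio and a perturbed coordination
vector drawn once from the group's :class:`ImpairmentProfile`; per-trial
noise is fresh.  Severity ladders (SIAS-like levels 1-5) make both the
offsets and the between-subject dispersion grow as the level drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal as _signal
from scipy.signal.windows import tukey

from .data import (
    EmgSession,
    Group,
    Motion,
    SubjectMeta,
    TrialAnnotation,
    TrialSegment,
)
from .errors import ParameterError
from .montage import FULL_MONTAGE, MUSCLE_ORDER, ChannelLabel, Side

__all__ = [
    "TrialSpec",
    "ImpairmentProfile",
    "CohortGroupSpec",
    "generate_trial",
    "generate_cohort",
    "default_profiles",
    "ELBOW_FLEXION_WEIGHTS",
    "STEERING_WEIGHTS",
]

#: Default ground-truth coordination weights (canonical muscle order
#: BR, PT, B, T, AD, PD, PEC, IS, ES).  Elbow flexion loads the elbow flexors
#: (brachioradialis, biceps); steering loads the shoulder girdle.
ELBOW_FLEXION_WEIGHTS = np.array([0.22, 0.10, 0.28, 0.05, 0.12, 0.05, 0.08, 0.05, 0.05])
STEERING_WEIGHTS = np.array([0.10, 0.08, 0.12, 0.10, 0.20, 0.12, 0.15, 0.08, 0.05])

_MOTION_WEIGHTS = {
    Motion.ELBOW_FLEXION: ELBOW_FLEXION_WEIGHTS,
    Motion.STEERING: STEERING_WEIGHTS,
}


@dataclass(frozen=True)
class TrialSpec:
    """Everything needed to synthesize one bimanual trial (protocol defaults)."""

    motion: Motion = Motion.ELBOW_FLEXION
    motion_freq: float = 0.25  # Hz, one cycle per 4 s
    duration_s: float = 20.0
    sample_rate: float = 1000.0
    coordination_right: np.ndarray = field(
        default_factory=lambda: ELBOW_FLEXION_WEIGHTS.copy()
    )
    coordination_left: np.ndarray = field(
        default_factory=lambda: ELBOW_FLEXION_WEIGHTS.copy()
    )
    gain_right: float = 1.0
    gain_left: float = 1.0
    burst_duty: float = 0.5  # fraction of each cycle spent bursting
    # Baseline (electrode/amplifier) noise amplitude per channel relative to
    # unit side gain.  Active channel amplitudes are gain * w_i with the nine
    # weights summing to 1, so 0.005 puts the floor at a few percent of a
    # typical channel's burst amplitude, as in a clean surface recording.
    noise_floor: float = 0.005
    jitter_sd: float = 0.05  # s, burst-onset timing jitter
    mirror_noise: bool = False  # reuse the right side's noise carriers on the left
    seed: int = 0
    meta: SubjectMeta | None = None  # attached to the segment; placeholder if None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coordination_right", np.asarray(self.coordination_right, dtype=float)
        )
        object.__setattr__(
            self, "coordination_left", np.asarray(self.coordination_left, dtype=float)
        )
        for name, v in (
            ("coordination_right", self.coordination_right),
            ("coordination_left", self.coordination_left),
        ):
            if v.shape != (len(MUSCLE_ORDER),):
                raise ParameterError(f"{name} must have length {len(MUSCLE_ORDER)}")
            if np.any(v < 0):
                raise ParameterError(f"{name} has negative weights")
            if abs(float(v.sum()) - 1.0) > 1e-9:
                raise ParameterError(f"{name} must sum to 1, got {v.sum():g}")
        if not 0 < self.burst_duty <= 1:
            raise ParameterError(f"burst_duty must be in (0, 1], got {self.burst_duty}")
        if self.gain_right <= 0 or self.gain_left <= 0:
            raise ParameterError("gains must be positive")
        if self.motion_freq <= 0 or self.duration_s <= 0 or self.sample_rate <= 0:
            raise ParameterError("motion_freq, duration_s, sample_rate must be positive")
        if self.noise_floor < 0 or self.jitter_sd < 0:
            raise ParameterError("noise_floor and jitter_sd must be nonnegative")


def _bandlimited_noise(rng: np.random.Generator, n: int, sample_rate: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian noise band-limited to the sEMG band."""
    low = 20.0
    high = min(450.0, 0.9 * sample_rate / 2.0)
    white = rng.standard_normal(n)
    if high <= low:  # very low sample rates: leave broadband
        x = white
    else:
        sos = _signal.butter(4, [low, high], btype="bandpass", fs=sample_rate, output="sos")
        x = _signal.sosfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _burst_envelope(spec: TrialSpec, rng: np.random.Generator) -> np.ndarray:
    """Periodic raised-cosine bursts at ``motion_freq`` with onset jitter."""
    n = int(round(spec.duration_s * spec.sample_rate))
    env = np.zeros(n)
    period = int(round(spec.sample_rate / spec.motion_freq))
    burst_len = max(2, int(round(spec.burst_duty * period)))
    pulse = tukey(burst_len, alpha=0.5)
    n_cycles = int(np.ceil(n / period)) + 1
    for k in range(n_cycles):
        jitter = int(round(rng.normal(0.0, spec.jitter_sd) * spec.sample_rate))
        onset = k * period + jitter
        lo, hi = max(onset, 0), min(onset + burst_len, n)
        if lo < hi:
            env[lo:hi] = np.maximum(env[lo:hi], pulse[lo - onset : hi - onset])
    return env


def generate_trial(spec: TrialSpec) -> TrialSegment:
    """Synthesize one raw (pre-conditioning) bimanual trial.

    Deterministic for a fixed spec (including seed): same spec, bit-identical
    samples.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate))
    env = _burst_envelope(spec, rng)
    weights = {Side.RIGHT: spec.coordination_right, Side.LEFT: spec.coordination_left}
    gains = {Side.RIGHT: spec.gain_right, Side.LEFT: spec.gain_left}
    samples = np.empty((len(FULL_MONTAGE), n))
    carriers: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for row, label in enumerate(FULL_MONTAGE):
        m_idx = MUSCLE_ORDER.index(label.muscle)
        if spec.mirror_noise and m_idx in carriers:
            g, g_floor = carriers[m_idx]
        else:
            g = _bandlimited_noise(rng, n, spec.sample_rate)
            g_floor = _bandlimited_noise(rng, n, spec.sample_rate)
            carriers[m_idx] = (g, g_floor)
        w = weights[label.side][m_idx]
        samples[row] = gains[label.side] * w * env * g + spec.noise_floor * g_floor
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sub-20-s test trials are intentional
        meta = spec.meta or SubjectMeta(
            subject_id="synthetic", group=Group.HEALTHY_ELDER, dominant_side=Side.RIGHT
        )
        return TrialSegment(
            motion=spec.motion,
            samples=samples,
            channels=FULL_MONTAGE,
            sample_rate=spec.sample_rate,
            meta=meta,
        )


# ---------------------------------------------------------------------------
# impairment profiles and cohorts

@dataclass(frozen=True)
class ImpairmentProfile:
    """Subject-level impairment distribution for one severity group.

    ``strength_ratio`` is the affected/reference side gain ratio (1 = balanced);
    ``coordination_noise_sd`` scales the additive Gaussian perturbation applied
    to the affected side's coordination weights (floored at 0, renormalized).
    Lower SIAS-like levels get ratios further from 1 and larger perturbations
    AND larger between-subject spread, mirroring the dispersion growth seen in
    severe hemiparesis.
    """

    label: str  # "healthy" or "sias_1".."sias_5"
    coordination_noise_sd: float
    strength_ratio_mean: float
    strength_ratio_sd: float
    #: per-trial coordination wobble (measurement/behavioral variability)
    trial_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.coordination_noise_sd < 0 or self.strength_ratio_sd < 0:
            raise ParameterError("spread parameters must be nonnegative")
        if self.strength_ratio_mean <= 0:
            raise ParameterError("strength_ratio_mean must be positive")


def default_profiles() -> dict[str, ImpairmentProfile]:
    """Severity ladder: monotone offsets and dispersion from healthy to SIAS 1."""
    return {
        "healthy": ImpairmentProfile("healthy", 0.02, 0.95, 0.03),
        "sias_5": ImpairmentProfile("sias_5", 0.02, 0.90, 0.03),
        "sias_4": ImpairmentProfile("sias_4", 0.04, 0.80, 0.06),
        "sias_3": ImpairmentProfile("sias_3", 0.08, 0.65, 0.11),
        "sias_2": ImpairmentProfile("sias_2", 0.15, 0.50, 0.18),
        "sias_1": ImpairmentProfile("sias_1", 0.25, 0.35, 0.28),
    }


@dataclass(frozen=True)
class CohortGroupSpec:
    """How many subjects/trials to synthesize for one group."""

    group: Group
    n_subjects: int
    n_trials_per_motion: int
    profile: ImpairmentProfile
    sias_level: int | None = None  # required for stroke groups

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_motion < 1:
            raise ParameterError("need at least one subject and one trial")
        if self.group is Group.STROKE and self.sias_level is None:
            raise ParameterError("stroke group spec needs a sias_level")


def perturb_weights(
    weights: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive Gaussian perturbation, floored at 0 and renormalized to sum 1."""
    w = np.clip(np.asarray(weights, dtype=float) + rng.normal(0.0, sd, size=len(weights)), 0.0, None)
    total = w.sum()
    if total <= 0:  # pathological draw: fall back to a single dominant muscle
        w = np.zeros_like(w)
        w[int(rng.integers(len(w)))] = 1.0
        return w
    return w / total


def _subject_meta(
    group_spec: CohortGroupSpec, idx: int, rng: np.random.Generator
) -> SubjectMeta:
    sid = f"{group_spec.profile.label}_{idx:02d}"
    if group_spec.group is Group.STROKE:
        paretic = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        return SubjectMeta(
            subject_id=sid,
            group=Group.STROKE,
            sias_level=group_spec.sias_level,
            paretic_side=paretic,
        )
    # the validation cohorts were all right-handed
    return SubjectMeta(subject_id=sid, group=group_spec.group, dominant_side=Side.RIGHT)


def generate_cohort(
    group_specs: Mapping[str, CohortGroupSpec],
    seed: int = 0,
    trial_spec: TrialSpec = TrialSpec(),
    rest_s: float = 20.0,
    motions: tuple[Motion, ...] = (Motion.ELBOW_FLEXION, Motion.STEERING),
) -> list[EmgSession]:
    """Synthesize one session per subject for every group.

    Subject-level draws (strength ratio, coordination perturbation, paretic
    side) use a dedicated random stream so the cohort structure is reproducible
    independently of how many trials are generated; per-trial noise is fresh.
    Each session carries a ground-truth dict (gains, true coordination
    vectors per motion) for benchmarking.
    """
    if not group_specs:
        raise ParameterError("no cohort groups given")
    root = np.random.SeedSequence(seed)
    subject_seq, trial_seq = root.spawn(2)
    subject_rng = np.random.default_rng(subject_seq)
    trial_seeds = np.random.default_rng(trial_seq)
    sessions: list[EmgSession] = []
    rest_n = int(round(rest_s * trial_spec.sample_rate))
    trial_n = int(round(trial_spec.duration_s * trial_spec.sample_rate))
    for key in sorted(group_specs):
        gs = group_specs[key]
        for i in range(gs.n_subjects):
            meta = _subject_meta(gs, i, subject_rng)
            ratio = max(
                0.05,
                float(subject_rng.normal(gs.profile.strength_ratio_mean, gs.profile.strength_ratio_sd)),
            )
            affected = meta.affected_side
            gains = {affected: ratio, affected.other: 1.0}
            base_coord = {
                motion: {
                    affected.other: perturb_weights(_MOTION_WEIGHTS[motion], 0.0, subject_rng),
                    affected: perturb_weights(
                        _MOTION_WEIGHTS[motion], gs.profile.coordination_noise_sd, subject_rng
                    ),
                }
                for motion in motions
            }
            chunks: list[np.ndarray] = []
            annotations: list[TrialAnnotation] = []
            cursor = 0
            for motion in motions:
                for _ in range(gs.n_trials_per_motion):
                    t_rng = np.random.default_rng(int(trial_seeds.integers(2**31)))
                    coord = {
                        side: perturb_weights(base_coord[motion][side], gs.profile.trial_noise_sd, t_rng)
                        for side in (Side.RIGHT, Side.LEFT)
                    }
                    spec = replace(
                        trial_spec,
                        motion=motion,
                        coordination_right=coord[Side.RIGHT],
                        coordination_left=coord[Side.LEFT],
                        gain_right=gains[Side.RIGHT],
                        gain_left=gains[Side.LEFT],
                        seed=int(t_rng.integers(2**31)),
                    )
                    seg = generate_trial(spec)
                    chunks.append(seg.samples)
                    annotations.append(
                        TrialAnnotation(motion=motion, start_sample=cursor, end_sample=cursor + trial_n)
                    )
                    cursor += trial_n
                    if rest_n > 0:
                        rest_rng = np.random.default_rng(int(t_rng.integers(2**31)))
                        rest = np.stack(
                            [
                                trial_spec.noise_floor
                                * _bandlimited_noise(rest_rng, rest_n, trial_spec.sample_rate)
                                for _ in FULL_MONTAGE
                            ]
                        )
                        chunks.append(rest)
                        cursor += rest_n
            truth = {
                "gain_right": float(gains[Side.RIGHT]),
                "gain_left": float(gains[Side.LEFT]),
                "strength_ratio": ratio,
                "profile": gs.profile.label,
                "coordination": {
                    motion.value: {
                        side.value.lower(): [float(v) for v in base_coord[motion][side]]
                        for side in (Side.RIGHT, Side.LEFT)
                    }
                    for motion in motions
                },
            }
            sessions.append(
                EmgSession(
                    meta=meta,
                    sample_rate=trial_spec.sample_rate,
                    channels=FULL_MONTAGE,
                    samples=np.concatenate(chunks, axis=1),
                    annotations=tuple(annotations),
                    ground_truth=truth,
                )
            )
    return sessions
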