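"""End-to-end convenience: session in, per-trial index records out."""

from __future__ import annotations

from typing import Sequence

from .data import EmgSession, IndexRecord
from .model import trial_indexes
from .preprocessing import DEFAULT_CONFIG, PreprocessConfig, preprocess_session

__all__ = ["session_indexes", "cohort_indexes"]


def session_indexes(
    session: EmgSession, config: PreprocessConfig = DEFAULT_CONFIG
) -> list[IndexRecord]:
    """Condition, standardize and score every annotated trial of a session.

    Trial indexes are numbered per motion in annotation order.  (Both ESB and
    MCS are invariant to the standardization scalar; it is applied so that
    exported envelopes and powers are in the session's standard units.)
    """
    trials, _ = preprocess_session(session, config)
    counters: dict = {}
    records = []
    for seg in trials:
        k = counters.get(seg.motion, 0)
        counters[seg.motion] = k + 1
        records.append(trial_indexes(seg, trial_index=k, edge_trim_s=config.edge_trim_s))
    return records


def cohort_indexes(
    sessions: Sequence[EmgSession], config: PreprocessConfig = DEFAULT_CONFIG
) -> list[IndexRecord]:
    """Score every session of a cohort."""
    out: list[IndexRecord] = []
    for session in sessions:
        out.extend(session_indexes(session, config))
    return out
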