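"""Group-level statistics: rank-sum comparisons with Holm correction.

Per motion and per index (MCS, and |ESB| so that side balance is assessed
independently of which arm is paretic), every pair of severity groups
(SIAS 1-5, healthy elder, healthy young) is compared with a two-sided
Wilcoxon rank-sum (Mann-Whitney) test at alpha = 0.05, followed by a
step-down Bonferroni-Holm correction across the comparison family of one
(index, motion) panel.  Per-group sample standard deviations (n-1
denominator) accompany each panel: dispersion of both indexes grows with
impairment severity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import IndexRecord, Motion
from .errors import ParameterError

__all__ = [
    "GroupComparison",
    "ranksum_test",
    "holm_adjust",
    "sias_summary",
    "GROUP_LADDER",
]

#: Severity-ordered panel labels (most severe first).
GROUP_LADDER = (
    "sias_1",
    "sias_2",
    "sias_3",
    "sias_4",
    "sias_5",
    "healthy_elder",
    "healthy_young",
)

#: Combined-sample-size threshold below which the exact permutation null of
#: the rank-sum statistic is enumerated (ties force the normal approximation).
EXACT_N_MAX = 20


def ranksum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration of the permutation null when the combined sample size is
    at most ``EXACT_N_MAX`` and there are no ties; otherwise the normal
    approximation with midrank tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ParameterError(
            f"both samples need >= 3 values (got {a.size} and {b.size})"
        )
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0  # maximally central statistic; tie-corrected variance is 0
    has_ties = len(np.unique(pooled)) < pooled.size
    if pooled.size <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def holm_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Bonferroni-Holm correction.

    Returns (significant flags, adjusted p-values), both in the input order.
    Adjusted p_(k) = running max of min(1, (m-k+1) * p_(k)) over the sorted
    sequence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("no p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


@dataclass(frozen=True)
class GroupComparison:
    """One Fig.-style panel: all pairwise comparisons for one index and motion."""

    index: str  # "mcs" or "abs_esb"
    motion: Motion
    pairs: tuple[tuple[str, str], ...]
    p_values: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    significant: tuple[bool, ...]
    group_sd: Mapping[str, float]
    group_n: Mapping[str, int]
    alpha: float = 0.05
    excluded_groups: tuple[str, ...] = ()
    n_undefined_excluded: int = 0

    def pair_result(self, g1: str, g2: str) -> tuple[float, float, bool]:
        for pair, p, padj, sig in zip(self.pairs, self.p_values, self.p_adjusted, self.significant):
            if set(pair) == {g1, g2}:
                return p, padj, sig
        raise KeyError((g1, g2))


def _group_values(
    records: Sequence[IndexRecord], motion: Motion, index: str
) -> tuple[dict[str, np.ndarray], int]:
    """Pool per-trial index values by severity group; count undefined exclusions."""
    values: dict[str, list[float]] = {}
    n_undef = 0
    for r in records:
        if r.motion is not motion:
            continue
        label = (
            f"sias_{r.sias_level}" if r.sias_level is not None else r.group.value
        )
        if index == "mcs":
            if r.mcs is None:
                n_undef += 1
                continue
            v = r.mcs
        elif index == "abs_esb":
            v = abs(r.esb)
        else:
            raise ParameterError(f"unknown index {index!r}")
        values.setdefault(label, []).append(float(v))
    return {k: np.asarray(v) for k, v in values.items()}, n_undef


def sias_summary(
    records: Sequence[IndexRecord],
    alpha: float = 0.05,
    min_group: int = 3,
    pair_family: Sequence[tuple[str, str]] | None = None,
) -> dict[tuple[str, Motion], GroupComparison]:
    """All-vs-all rank-sum panels per (index, motion), Holm-corrected per panel.

    MCS panels drop trials with undefined MCS (counted in the result); ESB is
    assessed as |ESB| so the summary does not depend on which side is paretic.
    Groups with fewer than ``min_group`` defined values are excluded with a
    warning.  ``pair_family`` restricts the comparison family (default: all
    pairs present).
    """
    if not records:
        raise ParameterError("no records")
    motions = sorted({r.motion for r in records}, key=lambda m: m.value)
    out: dict[tuple[str, Motion], GroupComparison] = {}
    for motion in motions:
        for index in ("mcs", "abs_esb"):
            values, n_undef = _group_values(records, motion, index)
            excluded = tuple(
                sorted(g for g, v in values.items() if v.size < min_group)
            )
            if excluded:
                warnings.warn(
                    f"{index}/{motion.value}: groups excluded (<{min_group} values): "
                    f"{', '.join(excluded)}",
                    stacklevel=2,
                )
            kept = {g: v for g, v in values.items() if v.size >= min_group}
            order = [g for g in GROUP_LADDER if g in kept] + sorted(
                set(kept) - set(GROUP_LADDER)
            )
            if pair_family is None:
                pairs = list(combinations(order, 2))
            else:
                pairs = [
                    (g1, g2)
                    for g1, g2 in pair_family
                    if g1 in kept and g2 in kept
                ]
            p_raw = [ranksum_test(kept[g1], kept[g2]) for g1, g2 in pairs]
            if p_raw:
                sig, p_adj = holm_adjust(p_raw, alpha=alpha)
            else:
                sig, p_adj = np.array([], dtype=bool), np.array([])
            out[(index, motion)] = GroupComparison(
                index=index,
                motion=motion,
                pairs=tuple(pairs),
                p_values=tuple(p_raw),
                p_adjusted=tuple(float(x) for x in p_adj),
                significant=tuple(bool(x) for x in sig),
                group_sd={g: float(np.std(v, ddof=1)) if v.size > 1 else 0.0 for g, v in kept.items()},
                group_n={g: int(v.size) for g, v in kept.items()},
                alpha=alpha,
                excluded_groups=excluded,
                n_undefined_excluded=n_undef,
            )
    return out
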