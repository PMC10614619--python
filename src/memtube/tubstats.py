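"""Tubulation-efficiency statistics and group comparisons.

The per-image statistic is the ratio of total tubule area to total
membrane (tubule + vesicle) area, computed after shape-criteria
reassignment. Images with no detected membrane objects yield an
*undefined* result that is excluded from aggregation rather than counted
as zero. Groups are compared with a two-sided Welch t-test (2 groups) or
an ordinary one-way ANOVA (more than 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from memtube.pixelclass import ObjectRecord

__all__ = [
    "TubulationResult",
    "GroupSummary",
    "ComparisonResult",
    "tubulation_ratio",
    "summarize_group",
    "compare_groups",
]


@dataclass
class TubulationResult:
    image_id: str
    tubule_area_nm2: float
    vesicle_area_nm2: float
    ratio: float | None  # None when no membrane objects were found

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass
class GroupSummary:
    label: str
    ratios: list[float] = field(default_factory=list)
    mean: float = float("nan")
    sd: float = float("nan")
    n: int = 0


@dataclass
class ComparisonResult:
    method: str
    statistic: float
    df: tuple[float, ...]
    p_value: float


def tubulation_ratio(objects: list[ObjectRecord], image_id: str = "") -> TubulationResult:
    """Tubule area over total membrane area for one image's objects."""
    tub = sum(o.area_nm2 for o in objects if o.cls == "tubule")
    ves = sum(o.area_nm2 for o in objects if o.cls == "vesicle")
    total = tub + ves
    ratio = tub / total if total > 0 else None
    return TubulationResult(image_id=image_id, tubule_area_nm2=tub, vesicle_area_nm2=ves, ratio=ratio)


def summarize_group(results: list[TubulationResult], label: str = "") -> GroupSummary:
    """Mean and sample SD (n-1 denominator) over defined per-image ratios.

    A single-ratio group gets SD = 0 by convention, flagged via n = 1.
    """
    ratios = [r.ratio for r in results if r.defined]
    if not ratios:
        raise ValueError(f"group {label!r} has no defined tubulation ratios")
    arr = np.asarray(ratios, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(label=label, ratios=ratios, mean=float(arr.mean()), sd=sd, n=arr.size)


def compare_groups(groups: list[GroupSummary], method: str = "auto") -> ComparisonResult:
    """Compare group ratio distributions.

    ``t_test`` (two-sided Welch, unequal variances) for exactly 2 groups;
    ``anova`` (ordinary one-way fixed-effects F-test) for 2 or more;
    ``auto`` picks the t-test for 2 groups and ANOVA otherwise.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2")
    samples = [np.asarray(g.ratios, dtype=float) for g in groups]

    if method == "auto":
        method = "t_test" if len(groups) == 2 else "anova"
    if method == "t_test":
        if len(groups) != 2:
            raise ValueError("t_test requires exactly 2 groups")
        res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        return ComparisonResult(
            method="welch_t",
            statistic=float(res.statistic),
            df=(float(res.df),),
            p_value=float(res.pvalue),
        )
    if method == "anova":
        res = stats.f_oneway(*samples)
        n_total = sum(s.size for s in samples)
        return ComparisonResult(
            method="anova",
            statistic=float(res.statistic),
            df=(float(len(groups) - 1), float(n_total - len(groups))),
            p_value=float(res.pvalue),
        )
    raise ValueError(f"unknown method {method!r}")
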