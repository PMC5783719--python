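"""Cohort-level summaries and group comparison of SV burdens.

Breakpoint counting convention: one count per junction (not per breakend).
Group comparison uses the two-sided Wilcoxon rank-sum test — exact when the
combined sample size is at most 20 and there are no ties, otherwise the
tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .classify import SampleReport

__all__ = ["SampleSummary", "summarize_sample", "compare_groups", "GroupTestResult"]


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    genotype_label: str  # wild_type | rtel1_null | other
    breakpoint_count: int
    deletion_sizes: tuple[int, ...]
    class_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_counts and sum(self.class_counts.values()) != self.breakpoint_count:
            raise ValueError(
                "breakpoint_count must equal the sum of per-class junction counts"
            )

    @property
    def class_proportions(self) -> dict:
        total = sum(self.class_counts.values())
        if total == 0:
            return {}
        return {c: n / total for c, n in self.class_counts.items()}


def summarize_sample(
    report: SampleReport,
    sample_id: str = "sample",
    genotype_label: str = "other",
) -> SampleSummary:
    """Reduce one classification report to cohort-comparable numbers."""
    return SampleSummary(
        sample_id=sample_id,
        genotype_label=genotype_label,
        breakpoint_count=report.n_junctions,
        deletion_sizes=tuple(report.deletion_sizes),
        class_counts=dict(report.junction_class_counts),
    )


@dataclass(frozen=True)
class GroupTestResult:
    metric: str
    statistic: float
    pvalue: float
    method: str
    n_a: int
    n_b: int


def _metric_values(group: list[SampleSummary], metric: str) -> list[float]:
    if metric == "breakpoint_count":
        return [float(s.breakpoint_count) for s in group]
    if metric == "deletion_size":
        return [float(x) for s in group for x in s.deletion_sizes]
    raise ValueError(f"unknown metric {metric!r}")


def compare_groups(
    group_a: list[SampleSummary],
    group_b: list[SampleSummary],
    metric: str = "breakpoint_count",
) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum comparison of a cohort metric.

    ``deletion_size`` pools the per-sample size lists before ranking.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    xa = _metric_values(group_a, metric)
    xb = _metric_values(group_b, metric)
    if not xa or not xb:
        raise ValueError(f"metric {metric!r} has no observations in one group")
    has_ties = len(set(xa + xb)) < len(xa) + len(xb)
    if len(xa) + len(xb) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        xa, xb, alternative="two-sided", method=method, use_continuity=False
    )
    return GroupTestResult(
        metric=metric,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method=f"wilcoxon_rank_sum_{method}",
        n_a=len(xa),
        n_b=len(xb),
    )
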