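"""Cross-metric and cross-dataset analyses.

A selectivity metric is only useful if it ranks compounds consistently and
gives similar values when the same compounds are profiled by different
technologies (binding vs activity assays, different labs). This module
provides the comparisons used to judge that: rank-order differences between
metrics, paired-dataset robustness statistics (R^2, Pearson correlation,
and the squared distance of normalized value pairs to the 1:1 line),
distribution benchmarking of entropies over a compound collection, a
selective/promiscuous classifier, and two-group significance tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .metrics import MetricSettings, selectivity_entropy
from .profiles import (
    ConsistencyStats,
    DataKind,
    MetricReport,
    ProfilePanel,
    SelectivityError,
    effective_ka_vector,
)

__all__ = [
    "GroupComparison",
    "DistributionSummary",
    "rank_difference",
    "cross_dataset_consistency",
    "distribution_benchmark",
    "classify_selectivity",
    "group_compare",
    "hit_prioritization",
]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group location comparison with a two-tailed Welch t-test p-value."""

    group_a_label: str
    group_b_label: str
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    p_value: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class DistributionSummary:
    """Location/spread summary of an entropy distribution.

    ``sd`` is the sample standard deviation (n-1 denominator). The
    ``selectivity_threshold`` is carried along so classification counts
    derived from the summary are self-describing.
    """

    mean: float
    median: float
    sd: float
    n: int
    selectivity_threshold: float = 2.0


def rank_difference(
    reports: Sequence[MetricReport],
    reference_metric: str = "entropy",
) -> dict[str, list[int]]:
    """Per-compound rank deltas of every metric against a reference metric.

    Returns ``{metric: [rank_under_metric - rank_under_reference, ...]}`` in
    compound order. A positive delta means the metric calls the compound
    less selective than the reference does.
    """
    if not reports:
        raise SelectivityError("rank_difference: no reports")
    metrics = list(reports[0].ranks)
    if reference_metric not in metrics:
        raise SelectivityError(
            f"rank_difference: unknown metric {reference_metric!r}; have {metrics}"
        )
    for r in reports:
        if list(r.ranks) != metrics:
            raise SelectivityError(
                f"rank_difference: report {r.compound_id!r} ranked on a different metric set"
            )
    return {
        m: [r.ranks[m] - r.ranks[reference_metric] for r in reports]
        for m in metrics
    }


def _paired(
    values_a: Mapping[str, float],
    values_b: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray, int]:
    shared = [k for k in values_a if k in values_b]
    if len(shared) < 3:
        raise SelectivityError(
            f"cross_dataset_consistency: need >= 3 shared compounds, got {len(shared)}"
        )
    a = np.array([float(values_a[k]) for k in shared])
    b = np.array([float(values_b[k]) for k in shared])
    return a, b, len(shared)


def _normalize(v: np.ndarray, rescale_min: bool) -> np.ndarray:
    if rescale_min:
        v = v - v.min()
    top = v.max()
    if top <= 0:
        raise SelectivityError("cross_dataset_consistency: cannot normalize a nonpositive set")
    return v / top


def cross_dataset_consistency(
    values_a: Mapping[str, float],
    values_b: Mapping[str, float],
    *,
    rescale_min: bool = False,
    metric_name: str = "",
) -> ConsistencyStats:
    """Robustness of one metric across two datasets sharing compounds.

    Pairs values by compound id (``values_a`` is the x dataset), then
    reports the R^2 of the ordinary least-squares regression of b on a, the
    Pearson correlation, and the total squared vertical residual to the
    diagonal y = x after dividing each set by its maximum. ``rescale_min``
    first subtracts each set's minimum — appropriate for metrics like the
    Ka-Gini whose values crowd into a narrow sub-interval of [0, 1].
    """
    a, b, n = _paired(values_a, values_b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise SelectivityError(
            "cross_dataset_consistency: zero variance in one of the value sets"
        )
    fit = stats.linregress(a, b)
    corr = float(stats.pearsonr(a, b).statistic)
    na = _normalize(a, rescale_min)
    nb = _normalize(b, rescale_min)
    distance = float(((nb - na) ** 2).sum())
    return ConsistencyStats(
        metric_name=metric_name,
        r_squared=float(fit.rvalue) ** 2,
        correlation=corr,
        diagonal_distance=distance,
        n_compounds=n,
    )


def distribution_benchmark(
    entropies: Iterable[float],
    selectivity_threshold: float = 2.0,
) -> DistributionSummary:
    """Mean / median / sample SD of a collection of selectivity entropies.

    Over a large diverse compound set the entropy distribution is the
    benchmark that anchors what "average selectivity" means and where the
    selective/promiscuous boundary sits.
    """
    arr = np.asarray(list(entropies), dtype=float)
    if arr.size < 2:
        raise SelectivityError("distribution_benchmark: need at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise SelectivityError("distribution_benchmark: values must be finite")
    return DistributionSummary(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        sd=float(arr.std(ddof=1)),
        n=int(arr.size),
        selectivity_threshold=selectivity_threshold,
    )


def classify_selectivity(s_sel: float, threshold: float = 2.0) -> str:
    """Label an entropy as ``"selective"`` (< threshold) or ``"promiscuous"``.

    The default threshold of 2 nats sits just above the mean of large kinase
    profiling collections; a value exactly at the threshold is classified
    promiscuous.
    """
    if s_sel < 0:
        raise SelectivityError(f"classify_selectivity: negative entropy {s_sel}")
    return "selective" if s_sel < threshold else "promiscuous"


def group_compare(
    values_a: Iterable[float],
    values_b: Iterable[float],
    *,
    label_a: str = "A",
    label_b: str = "B",
) -> GroupComparison:
    """Compare entropy distributions of two labelled compound groups.

    Uses the two-tailed Welch (unequal-variance) t-test, which is safer than
    the pooled test when group sizes differ. Two constant groups with equal
    means give p = 1 by convention (no evidence of difference); constant
    groups with different means give p = 0.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise SelectivityError("group_compare: each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return GroupComparison(
        group_a_label=label_a,
        group_b_label=label_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        p_value=p,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def hit_prioritization(
    panel: ProfilePanel,
    settings: MetricSettings | None = None,
) -> list[tuple[str, float]]:
    """Rank screening hits by selectivity entropy, most selective first.

    Intended for multi-assay dose-response screening data (EC50/IC50 treated
    as Kd). Ties break alphabetically by compound id so the ordering is
    reproducible.
    """
    if panel.data_kind is not DataKind.DISSOCIATION_CONSTANT:
        raise SelectivityError("hit_prioritization needs dose-response potencies")
    if settings is None:
        settings = MetricSettings()
    scored = []
    for profile in panel.compounds:
        vec = effective_ka_vector(
            profile,
            censor_policy="zero" if settings.censor_policy == "drop" else settings.censor_policy,
            missing_policy="zero" if settings.missing_policy == "drop" else settings.missing_policy,
            panel=panel,
        )
        try:
            s = selectivity_entropy(vec).s_sel
        except SelectivityError as exc:
            raise type(exc)(f"compound {profile.compound_id!r}: {exc}") from exc
        scored.append((profile.compound_id, s))
    return sorted(scored, key=lambda item: (item[1], item[0]))
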