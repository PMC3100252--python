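"""Selectivity metrics for panel-profiling data.

The central quantity is the selectivity entropy. Picture a hypothetical
mixture containing every target of the panel and a trace amount of
compound: at equilibrium the compound distributes over the targets in
proportion to its association constants (a Boltzmann distribution over
binding free energies). With fractions

    phi_i = Ka_i / sum_j Ka_j,      Ka_i = 1 / Kd_i,

the broadness of that distribution is the Gibbs/Shannon entropy

    S_sel = -sum_i phi_i ln(phi_i)      (natural log, nats).

S_sel = 0 for a perfectly selective compound and ln(n) for one that hits n
targets with equal potency. Because phi is a ratio of Ka values, S_sel is
invariant to any common rescaling of the affinities — in particular to the
Cheng-Prusoff factor 2 between IC50-at-KM,ATP and Kd.

Alongside it this module implements the scores the entropy is usually
compared against: the partition index Pmax (the largest phi_i), the
cutoff-based selectivity scores S(c) and S(fold), and the Gini coefficient
of a rank-ordered %-inhibition profile together with its Ka-based variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .profiles import (
    AffinityValue,
    Censor,
    DataKind,
    KaVector,
    MetricReport,
    ProfilePanel,
    SelectivityError,
    effective_ka_vector,
)

__all__ = [
    "EntropyResult",
    "MetricSettings",
    "METRIC_ORIENTATION",
    "selectivity_entropy",
    "weighted_entropy",
    "partition_index",
    "selectivity_score_cutoff",
    "selectivity_score_fold",
    "hill_percent_inhibition",
    "gini_from_inhibition",
    "ka_gini",
    "compute_all_metrics",
]


@dataclass(frozen=True)
class EntropyResult:
    """Selectivity entropy plus the target-occupancy fractions behind it.

    ``fractions`` covers only targets with Ka > 0 (zero-Ka targets occupy no
    compound and contribute 0 * ln 0 = 0); it sums to 1. ``n_active`` is the
    number of such targets, so 0 <= s_sel <= ln(n_active).
    """

    s_sel: float
    fractions: np.ndarray
    n_active: int

    def __float__(self) -> float:
        return self.s_sel


def _as_ka_array(kas: Iterable[float] | KaVector, what: str) -> np.ndarray:
    if isinstance(kas, KaVector):
        kas = kas.kas
    arr = np.asarray(list(kas) if not isinstance(kas, np.ndarray) else kas, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise SelectivityError(f"{what}: need a nonempty 1-d vector")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise SelectivityError(f"{what}: association constants must be finite and >= 0")
    return arr


def selectivity_entropy(kas: Iterable[float] | KaVector) -> EntropyResult:
    """Selectivity entropy S_sel = -sum phi_i ln(phi_i) of an association-constant vector.

    Parameters
    ----------
    kas
        Association constants Ka = 1/Kd (1/M), one per panel target. Zero
        entries (non-binding targets) are allowed and do not change the
        result; at least one must be positive.

    Returns
    -------
    EntropyResult
        Entropy in nats plus the occupancy fractions over binding targets.
    """
    arr = _as_ka_array(kas, "selectivity_entropy")
    total = arr.sum()
    if total <= 0:
        raise SelectivityError("selectivity_entropy: no binding (all Ka are zero)")
    active = arr[arr > 0]
    frac = active / active.sum()
    s = float(-(frac * np.log(frac)).sum())
    if s <= 0.0:  # clamp -0.0 / tiny negative round-off
        s = 0.0
    return EntropyResult(s_sel=s, fractions=frac, n_active=int(active.size))


def weighted_entropy(
    kas: Iterable[float] | KaVector,
    weights: Iterable[float],
) -> EntropyResult:
    """Selectivity entropy with per-target importance weights.

    Occupancies become phi_i = w_i Ka_i / sum_j w_j Ka_j, so a weight of 0
    removes a target and unit weights reproduce :func:`selectivity_entropy`
    exactly. Useful when some targets matter more than others (e.g. a
    must-avoid antitarget panel).
    """
    arr = _as_ka_array(kas, "weighted_entropy")
    w = np.asarray(list(weights), dtype=float)
    if w.shape != arr.shape:
        raise SelectivityError(
            f"weighted_entropy: {arr.size} Ka values but {w.size} weights"
        )
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise SelectivityError("weighted_entropy: weights must be finite and >= 0")
    return selectivity_entropy(w * arr)


def partition_index(
    kas: Iterable[float] | KaVector,
    reference: int | None = None,
) -> float:
    """Partition index: fraction of compound bound to the reference target.

    In the hypothetical all-targets mixture this is phi_ref = Ka_ref / sum Ka.
    By default the reference is the most potently hit target (Pmax, the
    largest occupancy fraction; first index wins ties); pass ``reference``
    to score against a specific target instead.
    """
    arr = _as_ka_array(kas, "partition_index")
    total = arr.sum()
    if total <= 0:
        raise SelectivityError("partition_index: no binding (all Ka are zero)")
    if reference is None:
        reference = int(np.argmax(arr))
    if not 0 <= reference < arr.size:
        raise SelectivityError(
            f"partition_index: reference index {reference} out of range 0..{arr.size - 1}"
        )
    return float(arr[reference] / total)


def _measured_kds(affinities: Sequence[AffinityValue | float]) -> list[float]:
    out = []
    for a in affinities:
        if isinstance(a, AffinityValue):
            if a.is_measured:
                out.append(float(a.value))
        else:
            out.append(float(a))
    return out


def selectivity_score_cutoff(
    affinities: Sequence[AffinityValue | float],
    cutoff: float = 3e-6,
    n_tested: int | None = None,
) -> float:
    """Selectivity score S(c): fraction of tested targets hit below ``cutoff``.

    A target is hit when its measured Kd is strictly below the cutoff
    concentration (molar). Censored entries are never counted as hit: with
    limit >= cutoff the true Kd is provably above it, and below the limit
    nothing is known. ``n_tested`` defaults to the length of ``affinities``
    and must cover every measured entry — the denominator is the panel size,
    not the number of measurable cells.
    """
    if cutoff <= 0:
        raise SelectivityError("selectivity_score_cutoff: cutoff must be positive")
    affinities = list(affinities)
    if n_tested is None:
        n_tested = len(affinities)
    if n_tested <= 0:
        raise SelectivityError("selectivity_score_cutoff: n_tested must be positive")
    kds = _measured_kds(affinities)
    if n_tested < len(kds):
        raise SelectivityError(
            f"selectivity_score_cutoff: n_tested={n_tested} smaller than the "
            f"{len(kds)} measured entries"
        )
    return sum(k < cutoff for k in kds) / n_tested


def selectivity_score_fold(
    affinities: Sequence[AffinityValue | float],
    fold: float = 10.0,
    n_tested: int | None = None,
) -> float:
    """Selectivity score S(fold): fraction of targets within ``fold`` x of the best Kd.

    The reference is the most potent measured Kd; targets with measured
    Kd <= fold * reference count as hit (boundary inclusive, so the
    reference itself always counts and S(fold) >= 1/n_tested).
    """
    if fold <= 1:
        raise SelectivityError("selectivity_score_fold: fold must exceed 1")
    affinities = list(affinities)
    if n_tested is None:
        n_tested = len(affinities)
    if n_tested <= 0:
        raise SelectivityError("selectivity_score_fold: n_tested must be positive")
    kds = _measured_kds(affinities)
    if not kds:
        raise SelectivityError("selectivity_score_fold: no measured affinities")
    if n_tested < len(kds):
        raise SelectivityError(
            f"selectivity_score_fold: n_tested={n_tested} smaller than the "
            f"{len(kds)} measured entries"
        )
    ref = min(kds)
    return sum(k <= fold * ref for k in kds) / n_tested


def hill_percent_inhibition(kd: float, test_concentration: float) -> float:
    """%-inhibition of one target at a test concentration, by the Hill expression.

    %-inhibition = 100 / (1 + 10^-(pKd - pconc)) with pKd = -log10(Kd) and
    pconc = -log10(concentration); equivalently 100 * c / (c + Kd), the
    single-site occupancy at concentration c.
    """
    if kd <= 0 or test_concentration <= 0:
        raise SelectivityError("hill_percent_inhibition: kd and concentration must be positive")
    pkd = -math.log10(kd)
    pconc = -math.log10(test_concentration)
    return 100.0 / (1.0 + 10.0 ** (-(pkd - pconc)))


def _lorenz_gini(x: np.ndarray) -> float:
    """Gini = 1 - 2B where B is the trapezoid area under the discrete Lorenz curve."""
    x = np.sort(x)
    n = x.size
    cum = np.cumsum(x) / x.sum()
    prev = np.concatenate(([0.0], cum[:-1]))
    area = float((prev + cum).sum()) / (2 * n)
    return 1.0 - 2.0 * area


def gini_from_inhibition(inhibitions: Iterable[float]) -> float:
    """Gini coefficient of a rank-ordered %-inhibition profile.

    Values are sorted ascending, accumulated and normalized into a Lorenz
    curve with nodes at k/n; the score is one minus twice the trapezoid area
    under it. 0 means every target is inhibited equally; (n-1)/n means all
    signal sits on a single target.
    """
    arr = np.asarray(list(inhibitions), dtype=float)
    if arr.size == 0:
        raise SelectivityError("gini_from_inhibition: empty profile")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 100):
        raise SelectivityError("gini_from_inhibition: values must lie in [0, 100]")
    if arr.sum() <= 0:
        raise SelectivityError("gini_from_inhibition: no inhibition (all zeros)")
    return _lorenz_gini(arr)


def ka_gini(kas: Iterable[float] | KaVector) -> float:
    """Gini coefficient computed directly on association constants.

    Identical Lorenz construction as :func:`gini_from_inhibition` with Ka in
    place of %-inhibition, which removes the dependence on an arbitrary test
    concentration. Zero-Ka (non-binding) panel targets belong in the vector:
    they stretch the flat part of the Lorenz curve and raise the score.
    """
    arr = _as_ka_array(kas, "ka_gini")
    if arr.sum() <= 0:
        raise SelectivityError("ka_gini: no binding (all Ka are zero)")
    return _lorenz_gini(arr)


# ---------------------------------------------------------------------------
# whole-panel driver

#: rank orientation per metric: True where larger values mean *more* selective
#: (Gini-type scores and Pmax), False where larger means more promiscuous.
METRIC_ORIENTATION: dict[str, bool] = {
    "gini": True,
    "s_cutoff": False,
    "s_fold": False,
    "pmax": True,
    "ka_gini": True,
    "entropy": False,
}


@dataclass(frozen=True)
class MetricSettings:
    """Settings for :func:`compute_all_metrics`.

    cutoff
        Concentration (molar) for S(cutoff); 3 uM by default.
    fold
        Fold factor for S(fold); 10 by default.
    gini_test_concentration
        Concentration (molar) at which Kd profiles are converted to
        %-inhibition for the classic Gini score. The choice is arbitrary and
        changes the score, which is why it must always be reported alongside
        Gini values; 1 uM by default.
    censor_policy, missing_policy
        Passed to :func:`selentropy.profiles.effective_ka_vector` for the
        Ka-based metrics. Whatever the policy, rank-ordered metrics (Gini,
        Ka-Gini, entropy, Pmax) are evaluated on the full panel-length Ka
        vector with non-binding targets at Ka = 0, so that panel size is
        respected; ``at_limit`` / ``panel_mean_pkd`` fill censored / missing
        cells with nonzero values first.
    """

    cutoff: float = 3e-6
    fold: float = 10.0
    gini_test_concentration: float = 1e-6
    censor_policy: str = "drop"
    missing_policy: str = "drop"

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.gini_test_concentration <= 0:
            raise SelectivityError("concentrations must be positive")
        if self.fold <= 1:
            raise SelectivityError("fold must exceed 1")


def _ordinal_ranks(values: Sequence[float], descending: bool) -> np.ndarray:
    """Competition-free ordinal ranks 1..n; ties broken by input order."""
    v = np.asarray(values, dtype=float)
    key = -v if descending else v
    order = np.lexsort((np.arange(v.size), key))
    ranks = np.empty(v.size, dtype=int)
    ranks[order] = np.arange(1, v.size + 1)
    return ranks


def _full_panel_kas(
    panel: ProfilePanel,
    profile,
    settings: MetricSettings,
) -> np.ndarray:
    """Panel-length Ka vector: policy-filled values, Ka = 0 where dropped."""
    # map "drop" onto "zero" so the vector keeps panel length
    censor = "zero" if settings.censor_policy == "drop" else settings.censor_policy
    missing = "zero" if settings.missing_policy == "drop" else settings.missing_policy
    vec = effective_ka_vector(
        profile, censor_policy=censor, missing_policy=missing, panel=panel
    )
    return vec.kas


def compute_all_metrics(
    panel: ProfilePanel,
    settings: MetricSettings | None = None,
) -> list[MetricReport]:
    """All six selectivity metrics plus per-metric ranks for every compound.

    Metrics reported per compound: ``gini`` (classic %-inhibition Gini at the
    stated test concentration), ``s_cutoff``, ``s_fold``, ``pmax``,
    ``ka_gini`` and ``entropy``. Ranks are oriented so rank 1 is the most
    selective compound under every metric; ties resolve by input order.
    """
    if settings is None:
        settings = MetricSettings()
    if panel.data_kind is not DataKind.DISSOCIATION_CONSTANT:
        raise SelectivityError(
            "compute_all_metrics needs a dissociation-constant panel; "
            "use gini_from_inhibition directly for %-inhibition data"
        )
    if not panel.compounds:
        raise SelectivityError(f"panel {panel.panel_id!r} has no compounds")
    weights = panel.weight_vector()
    n_tested = panel.n_targets
    reports: list[MetricReport] = []
    for profile in panel.compounds:
        try:
            kas = _full_panel_kas(panel, profile, settings)
            row = panel.affinity_row(profile)
            inhibitions = [
                hill_percent_inhibition(1.0 / ka, settings.gini_test_concentration)
                if ka > 0
                else 0.0
                for ka in kas
            ]
            entropy = (
                weighted_entropy(kas, weights) if weights is not None
                else selectivity_entropy(kas)
            )
            entries = {
                "gini": gini_from_inhibition(inhibitions),
                "s_cutoff": selectivity_score_cutoff(row, settings.cutoff, n_tested),
                "s_fold": selectivity_score_fold(row, settings.fold, n_tested),
                "pmax": partition_index(kas),
                "ka_gini": ka_gini(kas),
                "entropy": entropy.s_sel,
            }
        except SelectivityError as exc:
            raise type(exc)(f"compound {profile.compound_id!r}: {exc}") from exc
        reports.append(
            MetricReport(
                compound_id=profile.compound_id,
                entries=entries,
                n_targets_used=profile.n_measured(),
            )
        )
    for metric, higher_is_selective in METRIC_ORIENTATION.items():
        ranks = _ordinal_ranks(
            [r.entries[metric] for r in reports], descending=higher_is_selective
        )
        for r, rank in zip(reports, ranks):
            r.ranks[metric] = int(rank)
    return reports
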