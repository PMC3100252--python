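"""Deterministic fixtures and a parametric synthetic-profile generator.

Two kinds of data live here. First, small hand-written profiles that make
the behaviour of each metric easy to reason about — a one-target binder, a
two-equal-target binder, and so on — together with their closed-form
expected values, plus the published benchmark of selectivity metrics for 38
kinase inhibitors profiled on a 290-kinase panel. Second, a seeded
generator of synthetic compound profiles: affinities are drawn log-uniform
in pKd space (real panel affinities spread over orders of magnitude, so log
space is the natural scale), with a potent cluster, a weak background, and
optional censoring, which gives property tests profiles with known ground
truth at any size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import (
    AffinityValue,
    CompoundProfile,
    DataKind,
    ProfilePanel,
    SelectivityError,
)

__all__ = [
    "SyntheticSpec",
    "ReferenceFixtures",
    "worked_examples",
    "reference_fixtures",
    "kinome_benchmark",
    "generate_profile",
    "generate_panel",
]

_NM = 1e-9

#: Hand-written example profiles: compound id -> Kd values in molar.
_EXAMPLE_KDS: dict[str, list[float]] = {
    # a perfectly selective 1 nM binder
    "single": [1 * _NM],
    # two equal 1 nM targets ("inhibitor B")
    "two_equal": [1 * _NM, 1 * _NM],
    # 1 nM plus a 1000x weaker second target
    "weak_second": [1 * _NM, 1000 * _NM],
    # three equal 1 nM targets
    "three_equal": [1 * _NM] * 3,
    # three at 1 nM and two at 1 uM
    "five_mixed": [1 * _NM] * 3 + [1000 * _NM] * 2,
    # "inhibitor A": one at 1 nM and ten at 10 nM
    "inhibitor_A": [1 * _NM] + [10 * _NM] * 10,
}

#: Exact expected selectivity entropies (nats) for the example profiles.
EXPECTED_ENTROPY: dict[str, float] = {
    "single": 0.0,
    "two_equal": math.log(2),                       # 0.69 at 2 d.p.
    "weak_second": 0.007900354757641078,            # 0.0079 at 4 d.p.
    "three_equal": math.log(3),
    "five_mixed": 1.1038808353291798,               # direct evaluation
    "inhibitor_A": 1.844439727056968,               # 1.84 at 2 d.p.
}

#: Expected partition indices (Pmax) where they illustrate a point.
EXPECTED_PMAX: dict[str, float] = {
    "single": 1.0,
    "two_equal": 0.5,
    "inhibitor_A": 0.5,
}


def worked_examples() -> dict[str, CompoundProfile]:
    """The hand-written example profiles as :class:`CompoundProfile` objects."""
    out = {}
    for cid, kds in _EXAMPLE_KDS.items():
        affinities = {
            f"K{i + 1:02d}": AffinityValue.measured(kd) for i, kd in enumerate(kds)
        }
        out[cid] = CompoundProfile(cid, affinities)
    return out


@dataclass(frozen=True)
class ReferenceFixtures:
    """Bundle of deterministic fixtures: example panel + benchmark entropies."""

    panel: ProfilePanel
    expected_entropy: dict[str, float]
    expected_pmax: dict[str, float]
    benchmark_entropies: pd.Series


def reference_fixtures() -> ReferenceFixtures:
    """Example profiles on a shared panel plus the published benchmark vector.

    The example compounds are embedded in one 11-target panel (targets a
    compound does not bind are missing cells, which no Ka-based metric under
    the default drop policy is affected by).
    """
    n_targets = max(len(k) for k in _EXAMPLE_KDS.values())
    targets = [f"K{i + 1:02d}" for i in range(n_targets)]
    panel = ProfilePanel(
        panel_id="worked-examples",
        targets=targets,
        compounds=list(worked_examples().values()),
        data_kind=DataKind.DISSOCIATION_CONSTANT,
    )
    return ReferenceFixtures(
        panel=panel,
        expected_entropy=dict(EXPECTED_ENTROPY),
        expected_pmax=dict(EXPECTED_PMAX),
        benchmark_entropies=kinome_benchmark()["entropy"],
    )


#: Published selectivity metrics for 38 kinase inhibitors profiled on a
#: 290-kinase panel: the classic %-inhibition Gini, S(3 uM), S(10x), Pmax,
#: Ka-Gini, and the selectivity entropy (nats). Rows ordered by entropy.
_BENCHMARK_ROWS = [
    # compound        gini  s_3um s_10x pmax  ka_gini entropy
    ("PI-103",        0.41, 0.00, 0.00, 0.97, 0.99, 0.05),
    ("CI-1033",       0.72, 0.15, 0.00, 0.88, 0.99, 0.17),
    ("GW-2580",       0.54, 0.01, 0.00, 0.92, 0.99, 0.26),
    ("VX-745",        0.51, 0.03, 0.00, 0.92, 0.99, 0.28),
    ("Gefitinib",     0.65, 0.07, 0.00, 0.89, 0.99, 0.44),
    ("Lapatinib",     0.57, 0.01, 0.00, 0.70, 0.99, 0.70),
    ("Erlotinib",     0.75, 0.15, 0.00, 0.67, 0.99, 0.88),
    ("EKB-569",       0.78, 0.18, 0.00, 0.67, 0.99, 0.89),
    ("Imatinib",      0.79, 0.07, 0.02, 0.65, 0.99, 1.05),
    ("CP-724714",     0.49, 0.02, 0.01, 0.33, 0.99, 1.10),
    ("CP-690550",     0.66, 0.03, 0.01, 0.50, 0.99, 1.11),
    ("BIRB-796",      0.81, 0.16, 0.00, 0.47, 0.99, 1.15),
    ("PTK-787",       0.71, 0.03, 0.02, 0.44, 0.98, 1.54),
    ("SB-431542",     0.42, 0.02, 0.01, 0.14, 0.98, 1.56),
    ("MLN-518",       0.74, 0.06, 0.01, 0.26, 0.98, 1.58),
    ("LY-333531",     0.76, 0.16, 0.01, 0.42, 0.98, 1.68),
    ("CHIR-258",      0.76, 0.33, 0.01, 0.44, 0.97, 1.80),
    ("AZD1152HQPA",   0.78, 0.10, 0.02, 0.34, 0.98, 1.91),
    ("ABT-869",       0.82, 0.16, 0.01, 0.32, 0.98, 1.93),
    ("MLN-8054",      0.75, 0.13, 0.01, 0.36, 0.97, 1.95),
    ("Roscovitine",   0.33, 0.03, 0.03, 0.12, 0.98, 2.02),
    ("SU-14813",      0.70, 0.51, 0.02, 0.18, 0.97, 2.04),
    ("Sunitinib",     0.67, 0.57, 0.02, 0.11, 0.97, 2.05),
    ("GW-786034",     0.80, 0.21, 0.02, 0.33, 0.97, 2.06),
    ("SB-202190",     0.76, 0.09, 0.02, 0.35, 0.97, 2.08),
    ("Sorafenib",     0.82, 0.18, 0.10, 0.46, 0.97, 2.15),
    ("SB-203580",     0.77, 0.10, 0.02, 0.24, 0.97, 2.26),
    ("AMG-706",       0.82, 0.09, 0.04, 0.22, 0.97, 2.36),
    ("SNS-032",       0.80, 0.13, 0.06, 0.30, 0.97, 2.44),
    ("CHIR265",       0.74, 0.13, 0.12, 0.36, 0.96, 2.47),
    ("Flavopiridol",  0.77, 0.19, 0.17, 0.42, 0.95, 2.50),
    ("AST-487",       0.73, 0.45, 0.04, 0.11, 0.95, 2.74),
    ("ZD-6474",       0.79, 0.27, 0.26, 0.28, 0.94, 2.88),
    ("Staurosporine", 0.35, 0.87, 0.50, 0.02, 0.93, 2.91),
    ("VX-680",        0.76, 0.38, 0.03, 0.15, 0.93, 3.09),
    ("Dasatinib",     0.79, 0.28, 0.10, 0.03, 0.93, 3.21),
    ("PKC-412",       0.71, 0.47, 0.08, 0.10, 0.88, 3.72),
    ("JNJ-7706621",   0.74, 0.37, 0.08, 0.10, 0.87, 3.73),
]


def kinome_benchmark() -> pd.DataFrame:
    """Published benchmark metric values for 38 kinase inhibitors.

    Indexed by compound, columns ``gini``, ``s_3um``, ``s_10x``, ``pmax``,
    ``ka_gini``, ``entropy``. The entropy column anchors the
    average-selectivity benchmark (mean ~1.8, median ~1.9, sd ~1.0) behind
    the default selective/promiscuous threshold of 2.
    """
    frame = pd.DataFrame(
        _BENCHMARK_ROWS,
        columns=["compound", "gini", "s_3um", "s_10x", "pmax", "ka_gini", "entropy"],
    )
    return frame.set_index("compound")


# ---------------------------------------------------------------------------
# parametric generator

@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic compound profile.

    ``n_potent`` targets get pKd drawn uniform in ``potent_pkd_range``
    (default 8-9, i.e. 1-10 nM); the remaining targets draw from
    ``background_pkd_range`` (default 4-6, i.e. 10 uM-100 uM weak binding).
    ``fraction_censored`` of the background entries are replaced by
    above-limit censored cells at the background floor. Generation is fully
    reproducible given ``seed``.
    """

    n_targets: int
    n_potent: int
    potent_pkd_range: tuple[float, float] = (8.0, 9.0)
    background_pkd_range: tuple[float, float] = (4.0, 6.0)
    fraction_censored: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise SelectivityError(f"n_targets must be >= 1, got {self.n_targets}")
        if not 0 <= self.n_potent <= self.n_targets:
            raise SelectivityError(
                f"n_potent must lie in [0, {self.n_targets}], got {self.n_potent}"
            )
        for name, (lo, hi) in (
            ("potent_pkd_range", self.potent_pkd_range),
            ("background_pkd_range", self.background_pkd_range),
        ):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise SelectivityError(f"{name} must be an ordered finite pair, got {(lo, hi)}")
        if not 0.0 <= self.fraction_censored <= 1.0:
            raise SelectivityError(
                f"fraction_censored must lie in [0, 1], got {self.fraction_censored}"
            )


def generate_profile(spec: SyntheticSpec, compound_id: str = "synthetic") -> CompoundProfile:
    """Draw one synthetic compound profile from ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n_back = spec.n_targets - spec.n_potent
    pkds = np.concatenate([
        rng.uniform(*spec.potent_pkd_range, size=spec.n_potent),
        rng.uniform(*spec.background_pkd_range, size=n_back),
    ])
    censored = np.zeros(spec.n_targets, dtype=bool)
    n_cens = int(round(spec.fraction_censored * n_back))
    if n_cens:
        idx = rng.choice(n_back, size=n_cens, replace=False) + spec.n_potent
        censored[idx] = True
    limit = 10.0 ** (-spec.background_pkd_range[0])  # Kd at the background floor
    affinities = {}
    for i in range(spec.n_targets):
        tid = f"T{i + 1:03d}"
        if censored[i]:
            affinities[tid] = AffinityValue.above_limit(limit)
        else:
            affinities[tid] = AffinityValue.measured(10.0 ** (-pkds[i]))
    return CompoundProfile(compound_id, affinities)


def generate_panel(
    spec: SyntheticSpec,
    n_compounds: int,
    panel_id: str = "synthetic-panel",
) -> ProfilePanel:
    """A panel of ``n_compounds`` independent draws from ``spec``.

    Compound ``C001`` uses ``spec.seed``, ``C002`` uses ``spec.seed + 1``,
    and so on, so any sub-panel is reproducible on its own.
    """
    if n_compounds < 1:
        raise SelectivityError(f"n_compounds must be >= 1, got {n_compounds}")
    compounds = []
    for i in range(n_compounds):
        sub = SyntheticSpec(
            n_targets=spec.n_targets,
            n_potent=spec.n_potent,
            potent_pkd_range=spec.potent_pkd_range,
            background_pkd_range=spec.background_pkd_range,
            fraction_censored=spec.fraction_censored,
            seed=spec.seed + i,
        )
        compounds.append(generate_profile(sub, compound_id=f"C{i + 1:03d}"))
    return ProfilePanel(
        panel_id=panel_id,
        targets=[f"T{i + 1:03d}" for i in range(spec.n_targets)],
        compounds=compounds,
        data_kind=DataKind.DISSOCIATION_CONSTANT,
    )
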