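"""Domain containers and file I/O for compound x target affinity panels.

Panel profiling measures one compound against a fixed set of targets (a
kinase panel, a nuclear-receptor panel, a set of parallel screening assays)
and reports an affinity per target: a dissociation constant Kd, an
inhibition constant Ki, or an IC50 measured at [ATP] = KM,ATP, which by the
Cheng-Prusoff relation is ~2x Kd and can be used interchangeably with Kd in
every ratio-based selectivity score.

All concentrations are stored internally in molar. Input files declare
their unit once (default nM); the conversion is an exact power-of-ten
rescaling. Censored entries ("no binding detected up to X") and missing
cells are first-class: every downstream metric declares how it treats them.

The matrix file layout is::

    compound,TARGET1,TARGET2,...
    drug-a,1.2,>10000,
    drug-b,0.5,230,88

where an empty cell is a missing measurement and ``>X`` is a censored
measurement with detection limit X (in the input unit). Tab-separated files
are auto-detected from a ``.tsv`` extension.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SelectivityError",
    "PanelParseError",
    "PanelValidationError",
    "Censor",
    "DataKind",
    "AffinityValue",
    "CompoundProfile",
    "ProfilePanel",
    "MetricReport",
    "ConsistencyStats",
    "KaVector",
    "CONCENTRATION_UNITS",
    "to_molar",
    "read_panel",
    "write_panel",
    "effective_ka_vector",
    "write_report",
    "read_report",
]


class SelectivityError(ValueError):
    """Base class for every domain error raised by this package."""


class PanelParseError(SelectivityError):
    """A matrix file could not be parsed (malformed cell, bad header...)."""


class PanelValidationError(SelectivityError):
    """Parsed data violates a panel invariant (duplicate ids, bad range...)."""


#: Exact scale factors to molar for the accepted concentration units.
CONCENTRATION_UNITS: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def to_molar(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to molar (exact rescaling)."""
    try:
        return value * CONCENTRATION_UNITS[unit]
    except KeyError:
        raise PanelValidationError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(CONCENTRATION_UNITS)}"
        ) from None


class Censor(str, enum.Enum):
    """Measurement status of one affinity cell."""

    MEASURED = "measured"
    ABOVE_LIMIT = "above_limit"  # no binding detected up to `limit`
    MISSING = "missing"          # cell not measured at all


class DataKind(str, enum.Enum):
    """What the numbers in a panel mean."""

    DISSOCIATION_CONSTANT = "dissociation_constant"  # Kd / Ki / IC50-at-KM,ATP
    PERCENT_INHIBITION = "percent_inhibition"


@dataclass(frozen=True)
class AffinityValue:
    """One measured affinity with censoring status.

    ``value`` is a molar concentration for dissociation-constant panels and a
    plain percentage for %-inhibition panels. ``limit`` is the molar detection
    limit and is present iff ``censor`` is ``ABOVE_LIMIT``.
    """

    value: float | None = None
    censor: Censor = Censor.MEASURED
    limit: float | None = None

    def __post_init__(self) -> None:
        if self.censor is Censor.MEASURED:
            if self.value is None or not math.isfinite(self.value) or self.value < 0:
                raise PanelValidationError(
                    f"measured affinity must be a finite nonnegative number, got {self.value!r}"
                )
            if self.limit is not None:
                raise PanelValidationError("measured affinity carries no limit")
        elif self.censor is Censor.ABOVE_LIMIT:
            if self.limit is None or not math.isfinite(self.limit) or self.limit <= 0:
                raise PanelValidationError(
                    f"censored affinity needs a positive detection limit, got {self.limit!r}"
                )
            if self.value is not None:
                raise PanelValidationError("censored affinity carries no point value")
        else:  # MISSING
            if self.value is not None or self.limit is not None:
                raise PanelValidationError("missing affinity carries no value")

    @classmethod
    def measured(cls, kd_molar: float) -> "AffinityValue":
        """A measured dissociation constant (molar, strictly positive)."""
        if kd_molar <= 0:
            raise PanelValidationError(f"affinity must be positive, got {kd_molar!r}")
        return cls(value=float(kd_molar), censor=Censor.MEASURED)

    @classmethod
    def above_limit(cls, limit_molar: float) -> "AffinityValue":
        return cls(censor=Censor.ABOVE_LIMIT, limit=float(limit_molar))

    @classmethod
    def missing(cls) -> "AffinityValue":
        return cls(censor=Censor.MISSING)

    @property
    def is_measured(self) -> bool:
        return self.censor is Censor.MEASURED


_MISSING = AffinityValue.missing()


@dataclass
class CompoundProfile:
    """One compound's affinities across a named target panel (one matrix row)."""

    compound_id: str
    affinities: dict[str, AffinityValue]

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise PanelValidationError("compound_id must be nonempty")
        self.affinities = dict(self.affinities)

    @property
    def target_ids(self) -> tuple[str, ...]:
        return tuple(self.affinities)

    def measured_kds(self) -> list[float]:
        """Point-measured affinities (molar), in profile order."""
        return [a.value for a in self.affinities.values() if a.is_measured]

    def n_measured(self) -> int:
        return sum(a.is_measured for a in self.affinities.values())


@dataclass
class ProfilePanel:
    """A compound x target affinity matrix plus panel metadata.

    The target list is the full tested panel: denominator-based scores
    (fraction of panel hit) divide by its length even when some cells are
    censored or missing, because those targets were tested.
    """

    panel_id: str
    targets: list[str]
    compounds: list[CompoundProfile]
    data_kind: DataKind = DataKind.DISSOCIATION_CONSTANT
    test_concentration: float | None = None
    target_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.data_kind = DataKind(self.data_kind)
        if len(set(self.targets)) != len(self.targets):
            raise PanelValidationError(f"panel {self.panel_id!r}: duplicate target ids")
        ids = [c.compound_id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(
                f"panel {self.panel_id!r}: duplicate compound ids {dup}"
            )
        tset = set(self.targets)
        for c in self.compounds:
            extra = set(c.affinities) - tset
            if extra:
                raise PanelValidationError(
                    f"compound {c.compound_id!r} measured on targets {sorted(extra)} "
                    "absent from the panel"
                )
        if self.data_kind is DataKind.PERCENT_INHIBITION:
            if self.test_concentration is None or self.test_concentration <= 0:
                raise PanelValidationError(
                    "%-inhibition panels require a positive test_concentration (molar)"
                )
            for c in self.compounds:
                for t, a in c.affinities.items():
                    if a.is_measured and not 0.0 <= a.value <= 100.0:
                        raise PanelValidationError(
                            f"compound {c.compound_id!r}, target {t!r}: "
                            f"%-inhibition {a.value} outside [0, 100]"
                        )
        if self.target_weights is not None:
            extra = set(self.target_weights) - tset
            if extra:
                raise PanelValidationError(f"weights refer to unknown targets {sorted(extra)}")
            if any(w < 0 for w in self.target_weights.values()):
                raise PanelValidationError("target weights must be nonnegative")
            if not any(w > 0 for w in self.target_weights.values()):
                raise PanelValidationError("at least one target weight must be positive")

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def compound_ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    def get(self, compound_id: str) -> CompoundProfile:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)

    def affinity_row(self, profile: CompoundProfile) -> list[AffinityValue]:
        """Affinities of ``profile`` in panel target order; absent cells are missing."""
        return [profile.affinities.get(t, _MISSING) for t in self.targets]

    def weight_vector(self) -> np.ndarray | None:
        if self.target_weights is None:
            return None
        return np.array([self.target_weights.get(t, 1.0) for t in self.targets])


@dataclass
class MetricReport:
    """Per-compound values and ranks for all computed selectivity metrics."""

    compound_id: str
    entries: dict[str, float]
    ranks: dict[str, int] = field(default_factory=dict)
    n_targets_used: int = 0


@dataclass
class ConsistencyStats:
    """Cross-dataset robustness numbers for one metric.

    ``r_squared`` and ``correlation`` are computed on the identical paired
    value set; ``diagonal_distance`` is the total squared vertical residual
    to the line y = x after per-set max-normalization.
    """

    metric_name: str
    r_squared: float
    correlation: float
    diagonal_distance: float
    n_compounds: int


@dataclass(frozen=True)
class KaVector:
    """Association constants (1/M) for one compound after censor/missing policy."""

    kas: np.ndarray
    target_ids: tuple[str, ...]
    n_targets_used: int


# ---------------------------------------------------------------------------
# file I/O

def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() == ".tsv" else ","


def _parse_cell(
    text: str,
    compound_id: str,
    target_id: str,
    factor: float,
    data_kind: DataKind,
) -> AffinityValue:
    s = text.strip()
    if s == "":
        return _MISSING
    if s.startswith(">"):
        if data_kind is DataKind.PERCENT_INHIBITION:
            raise PanelParseError(
                f"compound {compound_id!r}, target {target_id!r}: censored token "
                f"{s!r} is not valid in a %-inhibition matrix"
            )
        try:
            x = float(s[1:])
        except ValueError:
            raise PanelParseError(
                f"compound {compound_id!r}, target {target_id!r}: malformed "
                f"censored cell {s!r}"
            ) from None
        if x <= 0:
            raise PanelValidationError(
                f"compound {compound_id!r}, target {target_id!r}: censoring limit "
                f"must be positive, got {s!r}"
            )
        return AffinityValue.above_limit(x * factor)
    try:
        x = float(s)
    except ValueError:
        raise PanelParseError(
            f"compound {compound_id!r}, target {target_id!r}: cell {s!r} is not numeric"
        ) from None
    if data_kind is DataKind.PERCENT_INHIBITION:
        if not 0.0 <= x <= 100.0:
            raise PanelValidationError(
                f"compound {compound_id!r}, target {target_id!r}: %-inhibition "
                f"{x} outside [0, 100]"
            )
        return AffinityValue(value=x, censor=Censor.MEASURED)
    if x <= 0:
        raise PanelValidationError(
            f"compound {compound_id!r}, target {target_id!r}: affinity must be "
            f"positive, got {x}"
        )
    return AffinityValue.measured(x * factor)


def read_panel(
    path: str | Path,
    *,
    unit: str = "nM",
    data_kind: DataKind | str = DataKind.DISSOCIATION_CONSTANT,
    test_concentration: float | None = None,
    panel_id: str | None = None,
    delimiter: str | None = None,
) -> ProfilePanel:
    """Read a compound x target matrix file into a validated :class:`ProfilePanel`.

    Parameters
    ----------
    path
        CSV (or ``.tsv``) file: header row of target ids after a leading
        compound-id column, one row per compound.
    unit
        Concentration unit of the numeric cells (ignored for %-inhibition).
    data_kind
        ``dissociation_constant`` (default) or ``percent_inhibition``.
    test_concentration
        Inhibitor concentration (molar) at which a %-inhibition panel was
        measured; required for that kind, forbidden otherwise.
    """
    path = Path(path)
    data_kind = DataKind(data_kind)
    factor = CONCENTRATION_UNITS.get(unit)
    if factor is None:
        raise PanelValidationError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(CONCENTRATION_UNITS)}"
        )
    sep = _delimiter_for(path, delimiter)
    # check the raw header before pandas de-duplicates repeated column names
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw_header = fh.readline().rstrip("\r\n").split(sep)[1:]
    except OSError as exc:
        raise PanelParseError(f"{path}: {exc}") from exc
    if len(set(raw_header)) != len(raw_header):
        dup = sorted({t for t in raw_header if raw_header.count(t) > 1})
        raise PanelValidationError(f"{path}: duplicate target ids {dup}")
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PanelParseError(f"{path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise PanelParseError(f"{path}: need a compound column plus at least one target")
    targets = [str(t) for t in frame.columns[1:]]
    compounds: list[CompoundProfile] = []
    for _, row in frame.iterrows():
        cid = str(row.iloc[0]).strip()
        if not cid:
            raise PanelParseError(f"{path}: empty compound id")
        affinities = {
            t: _parse_cell(str(row.iloc[j + 1]), cid, t, factor, data_kind)
            for j, t in enumerate(targets)
        }
        compounds.append(CompoundProfile(cid, affinities))
    return ProfilePanel(
        panel_id=panel_id or path.stem,
        targets=targets,
        compounds=compounds,
        data_kind=data_kind,
        test_concentration=test_concentration,
    )


def _format_cell(a: AffinityValue, factor: float, data_kind: DataKind) -> str:
    if a.censor is Censor.MISSING:
        return ""
    if a.censor is Censor.ABOVE_LIMIT:
        return ">" + format(a.limit / factor, ".17g")
    if data_kind is DataKind.PERCENT_INHIBITION:
        return format(a.value, ".17g")
    return format(a.value / factor, ".17g")


def write_panel(
    panel: ProfilePanel,
    path: str | Path,
    *,
    unit: str = "nM",
    delimiter: str | None = None,
) -> None:
    """Write ``panel`` in the standard matrix layout (inverse of :func:`read_panel`)."""
    path = Path(path)
    factor = CONCENTRATION_UNITS[unit]
    sep = _delimiter_for(path, delimiter)
    rows = []
    for c in panel.compounds:
        row = {"compound": c.compound_id}
        for t, a in zip(panel.targets, panel.affinity_row(c)):
            row[t] = _format_cell(a, factor, panel.data_kind)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["compound", *panel.targets])
    try:
        frame.to_csv(path, sep=sep, index=False)
    except OSError as exc:
        raise SelectivityError(f"could not write panel to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# censor / missing policies

CENSOR_POLICIES = ("drop", "zero", "at_limit")
MISSING_POLICIES = ("drop", "zero", "panel_mean_pkd")


def _panel_mean_pkd(panel: ProfilePanel) -> dict[str, float]:
    """Per-target mean pKd (-log10 Kd in molar) over measured entries."""
    out: dict[str, float] = {}
    for t in panel.targets:
        pkds = [
            -math.log10(c.affinities[t].value)
            for c in panel.compounds
            if t in c.affinities and c.affinities[t].is_measured
        ]
        if pkds:
            out[t] = float(np.mean(pkds))
    return out


def effective_ka_vector(
    profile: CompoundProfile,
    *,
    censor_policy: str = "drop",
    missing_policy: str = "drop",
    panel: ProfilePanel | None = None,
) -> KaVector:
    """Association constants Ka = 1/Kd for one compound, policy-resolved.

    ``censor_policy`` handles above-limit entries: ``drop`` removes them,
    ``zero`` keeps them with Ka = 0 (equivalent for the entropy, but they
    then still occupy a slot in rank-ordered scores), ``at_limit`` uses the
    detection limit as if it were the Kd (an optimistic-binding bound).

    ``missing_policy`` handles unmeasured cells: ``drop`` / ``zero`` as
    above, or ``panel_mean_pkd`` which imputes the mean pKd of the measured
    values for that target across the panel (falling back to the compound's
    own measured mean when the target column is empty). The imputing policy
    requires ``panel``.

    When ``panel`` is given the output follows panel target order and
    targets absent from the profile count as missing.
    """
    if censor_policy not in CENSOR_POLICIES:
        raise SelectivityError(f"unknown censor policy {censor_policy!r}")
    if missing_policy not in MISSING_POLICIES:
        raise SelectivityError(f"unknown missing policy {missing_policy!r}")
    if missing_policy == "panel_mean_pkd" and panel is None:
        raise SelectivityError("panel_mean_pkd imputation requires the panel")

    if panel is not None:
        items = list(zip(panel.targets, panel.affinity_row(profile)))
    else:
        items = list(profile.affinities.items())

    target_pkd = _panel_mean_pkd(panel) if missing_policy == "panel_mean_pkd" else {}
    own = profile.measured_kds()
    own_mean_pkd = float(np.mean([-math.log10(k) for k in own])) if own else None

    kas: list[float] = []
    ids: list[str] = []
    for t, a in items:
        if a.censor is Censor.MEASURED:
            if a.value <= 0:
                raise PanelValidationError(
                    f"compound {profile.compound_id!r}, target {t!r}: nonpositive Kd"
                )
            ka = 1.0 / a.value
        elif a.censor is Censor.ABOVE_LIMIT:
            if censor_policy == "drop":
                continue
            ka = 0.0 if censor_policy == "zero" else 1.0 / a.limit
        else:  # MISSING
            if missing_policy == "drop":
                continue
            if missing_policy == "zero":
                ka = 0.0
            else:
                pkd = target_pkd.get(t, own_mean_pkd)
                if pkd is None:
                    raise SelectivityError(
                        f"compound {profile.compound_id!r}: nothing measured, "
                        "cannot impute"
                    )
                ka = 10.0 ** pkd  # Ka = 1/Kd = 10^pKd
        kas.append(ka)
        ids.append(t)
    if not kas:
        raise SelectivityError(
            f"compound {profile.compound_id!r}: empty profile after applying policies"
        )
    return KaVector(np.asarray(kas, dtype=float), tuple(ids), len(kas))


# ---------------------------------------------------------------------------
# metric report I/O

def write_report(reports: Sequence[MetricReport], path: str | Path) -> None:
    """Write metric reports as CSV: one row per compound, value columns then ranks."""
    if not reports:
        raise SelectivityError("cannot write an empty report list")
    metrics = list(reports[0].entries)
    for r in reports:
        if list(r.entries) != metrics:
            raise SelectivityError(
                f"report for {r.compound_id!r} has metric set {list(r.entries)}, "
                f"expected {metrics}"
            )
    rows = []
    for r in reports:
        row: dict[str, object] = {"compound": r.compound_id}
        for m in metrics:
            row[m] = format(r.entries[m], ".6g")
        for m in metrics:
            if m in r.ranks:
                row[f"rank_{m}"] = r.ranks[m]
        row["n_targets_used"] = r.n_targets_used
        rows.append(row)
    frame = pd.DataFrame(rows)
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise SelectivityError(f"could not write report to {path}: {exc}") from exc


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a metric report written by :func:`write_report`."""
    try:
        return pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise SelectivityError(f"could not read report from {path}: {exc}") from exc
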