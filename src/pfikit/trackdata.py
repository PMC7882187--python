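"""Walking-track trial data: prints, trial aggregation, baselines and deficit factors.

Rodent walking-track analysis measures a small set of geometric components on
each inked (or digitized) hind-paw print: print length (PL), total toe spread
(TS, digit I to V), intermediate toe spread (IT, digit II to IV), distance to
the opposite foot (TOF), deviation angle (DA, foot axis against the direction
of travel, 180 deg = parallel to the track edge) and stance width (SW).  Prints
are taken from the experimental (operated) limb and the contralateral limb.

A trial usually leaves about two usable prints per limb; trials are collapsed
into either a *trial maximum* set (largest measurement per component, the
classic de Medinaceli convention) or a *trial average* set (mean per
component).  Components are then normalized into dimensionless "percent
deficit" factors, 100 * (measured - reference) / reference, against either the
same trial's contralateral limb or the animal's own pre-injury (week-0)
baseline.  These factors (EPL ... CSW) feed the composite function indices in
:mod:`pfikit.classic_index` and :mod:`pfikit.index_derivation`.

Units: lengths in mm, angles in degrees, speeds in mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Literal, Mapping, Optional

__all__ = [
    "COMPONENTS",
    "LIMBS",
    "EXPERIMENTAL",
    "CONTRALATERAL",
    "FACTOR_NAMES",
    "TrackDataError",
    "DomainError",
    "MissingLimbError",
    "TrialIntegrityError",
    "MissingReferenceError",
    "PrintMeasurement",
    "TrialSummary",
    "BaselineTable",
    "FactorSet",
    "aggregate_trial",
    "build_baseline",
    "percent_deficit",
    "compute_factors",
    "compute_velocity",
]

COMPONENTS = ("PL", "TS", "IT", "TOF", "DA", "SW")

EXPERIMENTAL = "experimental"
CONTRALATERAL = "contralateral"
LIMBS = (EXPERIMENTAL, CONTRALATERAL)

#: Factor symbols in conventional order: experimental-limb then contralateral-limb.
FACTOR_NAMES = tuple(f"E{c}" for c in COMPONENTS) + tuple(f"C{c}" for c in COMPONENTS)

#: Components that must be strictly positive on every print.
_STRICT_POSITIVE = ("PL", "TS", "IT")

#: Angle convention: DA is stored raw; 180 deg means the foot axis is parallel
#: to the direction of travel.
DA_STRAIGHT = 180.0

Limb = Literal["experimental", "contralateral"]
AggregationMode = Literal["maximum", "average"]
Normalization = Literal["contralateral", "baseline"]
BaselineScope = Literal["per_rat", "cohort"]


class TrackDataError(ValueError):
    """Base class for walking-track data errors."""


class DomainError(TrackDataError):
    """A numeric argument is outside its valid domain."""


class MissingLimbError(TrackDataError):
    """A trial has no prints for one of the two limbs."""


class TrialIntegrityError(TrackDataError):
    """Prints passed as one trial do not share rat/week/trial identity."""


class MissingReferenceError(TrackDataError):
    """A reference value needed for factor computation is absent or invalid."""


@dataclass(frozen=True)
class PrintMeasurement:
    """One paw print's six measured components with its identity.

    Parameters
    ----------
    rat_id, week, trial_id, limb, print_index
        Identity of the print: animal, integer weeks post-injury (0 =
        pre-injury baseline), trial within the time point, which limb, and
        the 1-based index of the print within the limb's sequence.
    PL, TS, IT, TOF, DA, SW
        Component values (mm except DA in degrees).  PL/TS/IT must be
        strictly positive; TOF and SW may be zero; DA lies in (0, 360).
    """

    rat_id: str
    week: int
    trial_id: str
    limb: Limb
    print_index: int
    PL: float
    TS: float
    IT: float
    TOF: float
    DA: float
    SW: float

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise TrackDataError(f"unknown limb {self.limb!r}")
        if self.print_index < 1:
            raise TrackDataError("print_index must be >= 1")
        for name in _STRICT_POSITIVE:
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("TOF", "SW"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 < self.DA < 360.0:
            raise DomainError(f"DA must lie in (0, 360), got {self.DA}")
        if self.IT > self.TS:
            raise DomainError(
                f"IT ({self.IT}) cannot exceed TS ({self.TS}): the intermediate "
                "toe spread lies between the inner digit pads"
            )

    def component(self, name: str) -> float:
        if name not in COMPONENTS:
            raise TrackDataError(f"unknown component {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class TrialSummary:
    """Per-limb aggregated components for one trial, plus trial velocity."""

    rat_id: str
    week: int
    trial_id: str
    mode: AggregationMode
    values: Mapping[str, Mapping[str, float]]  # limb -> component -> value
    n_prints: Mapping[str, int]  # limb -> number of prints aggregated
    velocity: float  # mm/s

    def __post_init__(self) -> None:
        if self.mode not in ("maximum", "average"):
            raise TrackDataError(f"unknown aggregation mode {self.mode!r}")
        if self.velocity <= 0:
            raise DomainError(f"velocity must be > 0, got {self.velocity}")
        for limb in LIMBS:
            if limb not in self.values:
                raise MissingLimbError(f"no aggregated values for {limb} limb")
            if self.n_prints.get(limb, 0) < 1:
                raise MissingLimbError(f"n_prints for {limb} limb must be >= 1")

    def component(self, limb: str, name: str) -> float:
        return self.values[limb][name]


@dataclass(frozen=True)
class BaselineTable:
    """Pre-injury (week-0) component means, per animal or pooled over the cohort.

    ``scope='per_rat'`` keeps each animal as its own pre-injury control (the
    default downstream); ``scope='cohort'`` pools all week-0 trials.
    """

    scope: BaselineScope
    mode: AggregationMode
    #: per_rat: rat_id -> limb -> component -> mean; cohort: single "*" key.
    means: Mapping[str, Mapping[str, Mapping[str, float]]]

    _COHORT_KEY = "*"

    def reference(self, rat_id: str, limb: str, component: str) -> float:
        key = rat_id if self.scope == "per_rat" else self._COHORT_KEY
        try:
            return self.means[key][limb][component]
        except KeyError as exc:
            raise MissingReferenceError(
                f"no baseline for rat={rat_id!r} limb={limb} component={component}"
            ) from exc

    @property
    def rats(self) -> tuple[str, ...]:
        return tuple(self.means)


@dataclass(frozen=True)
class FactorSet:
    """Percent-deficit factors (x100 scale) for one trial at one time point.

    Under contralateral normalization only the six experimental-limb factors
    exist (the contralateral limb is its own reference); under baseline
    normalization all twelve are present.  A factor is exactly 0 when the
    measured value equals its reference.
    """

    rat_id: str
    week: int
    trial_id: str
    normalization: Normalization
    factors: Mapping[str, float]
    velocity: float

    def __getitem__(self, name: str) -> float:
        try:
            return self.factors[name]
        except KeyError as exc:
            raise MissingReferenceError(f"factor {name!r} not present") from exc


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _aggregate_component(values: list[float], component: str, mode: str,
                         da_mode: str) -> float:
    if mode == "average":
        return fmean(values)
    if component == "DA" and da_mode == "deviation":
        # "Largest" deviation angle is ambiguous; default takes the print that
        # deviates most from straight travel (180 deg), preserving its sign.
        return max(values, key=lambda v: abs(v - DA_STRAIGHT))
    return max(values)


def aggregate_trial(
    prints: Iterable[PrintMeasurement],
    mode: AggregationMode,
    velocity: float,
    da_mode: Literal["deviation", "raw"] = "deviation",
) -> TrialSummary:
    """Collapse one trial's prints into a trial-maximum or trial-average summary.

    Each component is aggregated independently per limb.  With
    ``mode='maximum'`` the largest measurement is kept; for DA the default
    ``da_mode='deviation'`` keeps the value furthest from 180 deg (largest
    deviation from straight travel) while ``da_mode='raw'`` takes the plain
    numeric maximum.

    Raises
    ------
    TrialIntegrityError
        If the prints do not all share the same rat/week/trial identity.
    MissingLimbError
        If either limb has no prints.
    """
    prints = list(prints)
    if not prints:
        raise MissingLimbError("no prints supplied")
    ident = (prints[0].rat_id, prints[0].week, prints[0].trial_id)
    for p in prints:
        if (p.rat_id, p.week, p.trial_id) != ident:
            raise TrialIntegrityError(
                f"mixed trial identities: {ident} vs {(p.rat_id, p.week, p.trial_id)}"
            )
    by_limb: dict[str, list[PrintMeasurement]] = {limb: [] for limb in LIMBS}
    for p in prints:
        by_limb[p.limb].append(p)
    for limb, group in by_limb.items():
        if not group:
            raise MissingLimbError(f"trial {ident} has no prints for the {limb} limb")

    values = {
        limb: {
            comp: _aggregate_component([p.component(comp) for p in group], comp,
                                       mode, da_mode)
            for comp in COMPONENTS
        }
        for limb, group in by_limb.items()
    }
    n_prints = {limb: len(group) for limb, group in by_limb.items()}
    return TrialSummary(
        rat_id=ident[0], week=ident[1], trial_id=ident[2], mode=mode,
        values=values, n_prints=n_prints, velocity=velocity,
    )


def build_baseline(
    trials: Iterable[TrialSummary],
    scope: BaselineScope = "per_rat",
    rats: Optional[Iterable[str]] = None,
) -> BaselineTable:
    """Average week-0 trial summaries into a baseline reference table.

    Non-baseline trials in ``trials`` are ignored, so the whole cohort may be
    passed.  With ``rats`` given (per_rat scope), every listed animal must
    contribute at least one week-0 trial.
    """
    week0 = [t for t in trials if t.week == 0]
    if not week0:
        raise TrackDataError("no week-0 trials: cannot build a baseline table")
    modes = {t.mode for t in week0}
    if len(modes) > 1:
        raise TrialIntegrityError(f"mixed aggregation modes in baseline trials: {modes}")
    mode = week0[0].mode

    def _mean_table(group: list[TrialSummary]) -> dict[str, dict[str, float]]:
        return {
            limb: {
                comp: fmean(t.component(limb, comp) for t in group)
                for comp in COMPONENTS
            }
            for limb in LIMBS
        }

    if scope == "cohort":
        means = {BaselineTable._COHORT_KEY: _mean_table(week0)}
    elif scope == "per_rat":
        by_rat: dict[str, list[TrialSummary]] = {}
        for t in week0:
            by_rat.setdefault(t.rat_id, []).append(t)
        if rats is not None:
            missing = sorted(set(rats) - set(by_rat))
            if missing:
                raise TrackDataError(
                    f"rats lacking week-0 trials under per_rat scope: {missing}"
                )
        means = {rat: _mean_table(group) for rat, group in by_rat.items()}
    else:
        raise TrackDataError(f"unknown baseline scope {scope!r}")
    return BaselineTable(scope=scope, mode=mode, means=means)


def percent_deficit(measured: float, reference: float) -> float:
    """Percent deficit of a measurement against its reference, on the x100 scale.

    Defined as ``100 * (measured - reference) / reference``; zero when the
    measurement equals its reference, negative when it falls short of it.
    """
    if reference <= 0:
        raise DomainError(f"reference must be > 0, got {reference}")
    return 100.0 * (measured - reference) / reference


def compute_factors(
    summary: TrialSummary,
    baseline: Optional[BaselineTable] = None,
    normalization: Normalization = "baseline",
) -> FactorSet:
    """Convert an aggregated trial into percent-deficit factors.

    ``normalization='contralateral'`` references each experimental-limb
    component to the same trial's contralateral value (the classic walking
    track convention); no contralateral factors exist in this case.
    ``normalization='baseline'`` references both limbs to the animal's (or
    cohort's) pre-injury means, which also exposes compensatory shifts of the
    uninjured limb.
    """
    factors: dict[str, float] = {}
    if normalization == "contralateral":
        for comp in COMPONENTS:
            ref = summary.component(CONTRALATERAL, comp)
            if ref <= 0:
                raise MissingReferenceError(
                    f"contralateral {comp} is not a valid reference ({ref})"
                )
            factors[f"E{comp}"] = percent_deficit(
                summary.component(EXPERIMENTAL, comp), ref
            )
    elif normalization == "baseline":
        if baseline is None:
            raise MissingReferenceError(
                "baseline normalization requires a BaselineTable"
            )
        if baseline.mode != summary.mode:
            raise TrialIntegrityError(
                f"baseline was built from {baseline.mode} trials but the summary "
                f"is {summary.mode}"
            )
        for limb, prefix in ((EXPERIMENTAL, "E"), (CONTRALATERAL, "C")):
            for comp in COMPONENTS:
                ref = baseline.reference(summary.rat_id, limb, comp)
                if ref <= 0:
                    raise MissingReferenceError(
                        f"baseline {limb} {comp} is not a valid reference ({ref})"
                    )
                factors[f"{prefix}{comp}"] = percent_deficit(
                    summary.component(limb, comp), ref
                )
    else:
        raise TrackDataError(f"unknown normalization {normalization!r}")
    return FactorSet(
        rat_id=summary.rat_id, week=summary.week, trial_id=summary.trial_id,
        normalization=normalization, factors=factors, velocity=summary.velocity,
    )


def compute_velocity(distance: float, elapsed: float) -> float:
    """Trial velocity (mm/s) from corridor sensor distance (mm) and time (s)."""
    if distance <= 0:
        raise DomainError(f"distance must be > 0, got {distance}")
    if elapsed <= 0:
        raise DomainError(f"elapsed time must be > 0, got {elapsed}")
    return distance / elapsed
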