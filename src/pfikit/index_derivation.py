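"""Anchored derivation of a revised peroneal function index.

The classic BMH index misreads peroneal injury on paper substrates (the heel
strikes early, artifactually lengthening the print), so a revised index is
derived directly from the data: trials at the healthy week (0 weeks
post-injury) are assigned an index of 0 and trials at the maximal-dysfunction
(nadir) weeks — 3 and 4 here — an index of -100.  The twelve percent-deficit
factors plus trial velocity are screened against this anchored scale in one
joint ordinary-least-squares regression; candidate terms are then admitted at
tiered significance thresholds (default 0.05 / 0.004 / 0.0001, strict
inequality) to build nested index models, which are finally used to score
every trial at every time point.

Model fitting uses only anchor-week trials (the dependent variable exists
nowhere else); scoring covers all weeks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trackdata import FACTOR_NAMES, FactorSet, MissingReferenceError, TrackDataError

__all__ = [
    "CANDIDATE_TERMS",
    "VELOCITY_TERM",
    "AnchorScheme",
    "ScreeningEntry",
    "ScreeningTable",
    "IndexModel",
    "AnchoringError",
    "RankDeficiencyError",
    "assign_anchors",
    "screen_factors",
    "select_components",
    "fit_index_model",
    "score_trials",
]

VELOCITY_TERM = "velocity"

#: Default screening candidates: the 12 deficit factors plus trial velocity.
CANDIDATE_TERMS = FACTOR_NAMES + (VELOCITY_TERM,)

_ID_COLUMNS = ("rat_id", "week", "trial_id")


class AnchoringError(TrackDataError):
    """The dataset cannot support the requested anchor scheme."""


class RankDeficiencyError(TrackDataError):
    """The regression design matrix is rank-deficient."""

    def __init__(self, message: str, terms: Sequence[str] = ()) -> None:
        super().__init__(message)
        self.terms = tuple(terms)


@dataclass(frozen=True)
class AnchorScheme:
    """Which weeks define the 0 / -100 ends of the regression scale."""

    healthy_week: int = 0
    nadir_weeks: frozenset[int] = frozenset({3, 4})
    healthy_value: float = 0.0
    nadir_value: float = -100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nadir_weeks", frozenset(self.nadir_weeks))
        if self.healthy_week in self.nadir_weeks:
            raise AnchoringError(
                f"healthy week {self.healthy_week} cannot also be a nadir week"
            )
        if not self.nadir_weeks:
            raise AnchoringError("at least one nadir week is required")


@dataclass(frozen=True)
class ScreeningEntry:
    """One candidate term's screening p-value.

    ``censored_below`` holds the bound for results only known as "< x"
    (e.g. a printed "<.0001"); in that case ``p_value`` is None rather than a
    fabricated number.
    """

    term: str
    p_value: Optional[float] = None
    censored_below: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.p_value is None) == (self.censored_below is None):
            raise TrackDataError(
                f"{self.term}: exactly one of p_value / censored_below must be set"
            )
        if self.p_value is not None and not 0.0 < self.p_value <= 1.0:
            raise TrackDataError(f"{self.term}: p-value {self.p_value} outside (0, 1]")
        if self.censored_below is not None and not 0.0 < self.censored_below <= 1.0:
            raise TrackDataError(
                f"{self.term}: censored bound {self.censored_below} outside (0, 1]"
            )

    def passes(self, alpha: float) -> bool:
        if self.censored_below is not None:
            return self.censored_below <= alpha
        return self.p_value < alpha


@dataclass(frozen=True)
class ScreeningTable:
    """Ordered per-term screening p-values (each candidate exactly once)."""

    entries: tuple[ScreeningEntry, ...]

    def __post_init__(self) -> None:
        terms = [e.term for e in self.entries]
        if len(set(terms)) != len(terms):
            raise TrackDataError("duplicate terms in screening table")

    @classmethod
    def from_mapping(cls, pvalues: dict[str, float | str]) -> "ScreeningTable":
        """Build from ``{term: p}`` where censored entries are strings like '<.0001'."""
        entries = []
        for term, p in pvalues.items():
            if isinstance(p, str):
                if not p.startswith("<"):
                    raise TrackDataError(f"{term}: cannot parse p-value {p!r}")
                entries.append(ScreeningEntry(term, censored_below=float(p[1:])))
            else:
                entries.append(ScreeningEntry(term, p_value=float(p)))
        return cls(tuple(entries))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [e.term for e in self.entries],
                "p_value": [e.p_value for e in self.entries],
                "censored_below": [e.censored_below for e in self.entries],
            }
        )

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(e.term for e in self.entries)


@dataclass(frozen=True)
class IndexModel:
    """A fitted revised-index model: intercept + coefficients over selected terms."""

    selected_terms: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    adjusted_R2: float
    model_p_value: float
    tier: Optional[float] = None
    fit_weeks: tuple[int, ...] = ()
    n_obs: int = 0

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.selected_terms):
            raise TrackDataError("coefficients must cover exactly the selected terms")
        vals = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(vals)):
            raise TrackDataError("model parameters must be finite")

    def score(self, factors: "FactorSet | dict | pd.Series") -> float:
        """Score one trial: beta0 + sum(beta_j * factor_j)."""
        total = self.intercept
        for term in self.selected_terms:
            if isinstance(factors, FactorSet):
                value = (factors.velocity if term == VELOCITY_TERM
                         else factors[term])
            else:
                try:
                    value = factors[term]
                except KeyError as exc:
                    raise MissingReferenceError(
                        f"trial lacks required term {term!r}"
                    ) from exc
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise MissingReferenceError(f"trial lacks required term {term!r}")
            total += self.coefficients[term] * float(value)
        return total

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_terms": list(self.selected_terms),
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "adjusted_R2": self.adjusted_R2,
                "model_p_value": self.model_p_value,
                "tier": self.tier,
                "fit_weeks": list(self.fit_weeks),
                "n_obs": self.n_obs,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "IndexModel":
        d = json.loads(text)
        return cls(
            selected_terms=tuple(d["selected_terms"]),
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            adjusted_R2=d["adjusted_R2"],
            model_p_value=d["model_p_value"],
            tier=d.get("tier"),
            fit_weeks=tuple(d.get("fit_weeks", ())),
            n_obs=d.get("n_obs", 0),
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def factors_to_frame(factorsets: Iterable[FactorSet]) -> pd.DataFrame:
    """Tabulate FactorSets: identity columns, factor columns, velocity."""
    rows = []
    for fs in factorsets:
        row = {"rat_id": fs.rat_id, "week": fs.week, "trial_id": fs.trial_id}
        row.update(fs.factors)
        row[VELOCITY_TERM] = fs.velocity
        rows.append(row)
    if not rows:
        raise TrackDataError("no factor sets supplied")
    return pd.DataFrame(rows)


def assign_anchors(
    factorsets: Iterable[FactorSet] | pd.DataFrame,
    scheme: AnchorScheme = AnchorScheme(),
) -> pd.DataFrame:
    """Label anchor-week trials with their dependent index value.

    Healthy-week trials get ``scheme.healthy_value`` (0), nadir-week trials
    ``scheme.nadir_value`` (-100); trials at any other week are excluded from
    the anchored set entirely.
    """
    df = (factorsets if isinstance(factorsets, pd.DataFrame)
          else factors_to_frame(factorsets))
    healthy = df["week"] == scheme.healthy_week
    nadir = df["week"].isin(scheme.nadir_weeks)
    if not healthy.any():
        raise AnchoringError(f"no trials at healthy week {scheme.healthy_week}")
    if not nadir.any():
        raise AnchoringError(f"no trials at nadir weeks {sorted(scheme.nadir_weeks)}")
    anchored = df[healthy | nadir].copy()
    anchored["anchor"] = np.where(
        anchored["week"] == scheme.healthy_week,
        scheme.healthy_value,
        scheme.nadir_value,
    )
    return anchored.reset_index(drop=True)


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise RankDeficiencyError naming constant or collinear columns."""
    constant = [n for n, col in zip(names, X.T) if np.ptp(col) == 0.0]
    if constant:
        raise RankDeficiencyError(
            f"candidate terms constant across all trials: {constant}", constant
        )
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # Identify culprits by greedy incremental rank growth.
        culprits = []
        cols = [np.ones(X.shape[0])]
        for n, col in zip(names, X.T):
            trial = np.column_stack(cols + [col])
            if np.linalg.matrix_rank(trial) == len(cols):
                culprits.append(n)
            else:
                cols.append(col)
        raise RankDeficiencyError(
            f"collinear candidate terms: {culprits}", culprits
        )


def screen_factors(
    anchored: pd.DataFrame,
    candidates: Sequence[str] = CANDIDATE_TERMS,
    method: Literal["joint", "univariate"] = "joint",
) -> ScreeningTable:
    """Screen candidate terms for effect on the anchored index.

    The default fits ONE joint OLS of the anchor value on all candidates and
    reports each coefficient's t-test p-value; ``method='univariate'`` instead
    fits a simple regression per term (provided for comparison).
    """
    missing = [c for c in candidates if c not in anchored.columns]
    if missing:
        raise TrackDataError(f"anchored dataset lacks candidate columns: {missing}")
    if "anchor" not in anchored.columns:
        raise TrackDataError("anchored dataset lacks the 'anchor' column; "
                             "run assign_anchors first")
    if anchored.empty:
        raise TrackDataError("anchored dataset is empty")
    y = anchored["anchor"].to_numpy(float)
    if np.unique(y).size < 2:
        raise AnchoringError("anchored dataset needs >= 2 distinct anchor values")
    X = anchored[list(candidates)].to_numpy(float)

    entries: list[ScreeningEntry] = []
    if method == "joint":
        _check_design(X, candidates)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        for term, p in zip(candidates, fit.pvalues[1:]):
            entries.append(ScreeningEntry(term, p_value=_clip_p(p)))
    elif method == "univariate":
        for term, col in zip(candidates, X.T):
            if np.ptp(col) == 0.0:
                raise RankDeficiencyError(
                    f"candidate term constant across all trials: [{term!r}]", [term]
                )
            fit = sm.OLS(y, sm.add_constant(col)).fit()
            entries.append(ScreeningEntry(term, p_value=_clip_p(fit.pvalues[1])))
    else:
        raise TrackDataError(f"unknown screening method {method!r}")
    return ScreeningTable(tuple(entries))


def _clip_p(p: float) -> float:
    # Guard against p underflowing to exactly 0 with strong signals.
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def select_components(table: ScreeningTable, alpha: float) -> list[str]:
    """Terms passing the significance tier, in stable input order.

    The inequality is strict (p < alpha), so a term at exactly the threshold
    is excluded; censored "< x" entries pass iff their bound x <= alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise TrackDataError(f"alpha must lie in (0, 1), got {alpha}")
    return [e.term for e in table.entries if e.passes(alpha)]


def fit_index_model(
    anchored: pd.DataFrame,
    terms: Sequence[str],
    tier: Optional[float] = None,
) -> IndexModel:
    """OLS fit of the anchored index on the selected terms (with intercept)."""
    terms = list(terms)
    if anchored.empty:
        raise TrackDataError("anchored dataset is empty")
    n = len(anchored)
    if n < len(terms) + 2:
        raise TrackDataError(
            f"underdetermined fit: {n} anchored trials for {len(terms)} terms "
            f"(need >= {len(terms) + 2})"
        )
    y = anchored["anchor"].to_numpy(float)
    fit_weeks = tuple(sorted(anchored["week"].unique().tolist()))
    if not terms:
        intercept = float(np.mean(y))
        return IndexModel(
            selected_terms=(), intercept=intercept, coefficients={},
            adjusted_R2=0.0, model_p_value=float("nan"),
            tier=tier, fit_weeks=fit_weeks, n_obs=n,
        )
    missing = [t for t in terms if t not in anchored.columns]
    if missing:
        raise TrackDataError(f"anchored dataset lacks selected terms: {missing}")
    X = anchored[terms].to_numpy(float)
    _check_design(X, terms)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    coeffs = {t: float(b) for t, b in zip(terms, fit.params[1:])}
    return IndexModel(
        selected_terms=tuple(terms),
        intercept=float(fit.params[0]),
        coefficients=coeffs,
        adjusted_R2=float(fit.rsquared_adj),
        model_p_value=float(fit.f_pvalue),
        tier=tier,
        fit_weeks=fit_weeks,
        n_obs=n,
    )


def score_trials(
    model: IndexModel,
    factorsets: Iterable[FactorSet] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every trial at every time point with a fitted index model.

    Returns ``(per_trial, weekly)``: per-trial scores with identity columns,
    and per-week mean +/- SEM over all weeks present (not just anchor weeks).
    """
    df = (factorsets if isinstance(factorsets, pd.DataFrame)
          else factors_to_frame(factorsets))
    missing = [t for t in model.selected_terms if t not in df.columns]
    if missing:
        raise MissingReferenceError(f"trials lack required terms: {missing}")
    per_trial = df[list(_ID_COLUMNS)].copy()
    scores = np.full(len(df), model.intercept, dtype=float)
    for term in model.selected_terms:
        col = df[term].to_numpy(float)
        if np.isnan(col).any():
            bad = df.loc[np.isnan(col), list(_ID_COLUMNS)].iloc[0].tolist()
            raise MissingReferenceError(
                f"term {term!r} missing for trial {tuple(bad)}"
            )
        scores += model.coefficients[term] * col
    per_trial["pfi"] = scores
    weekly = (
        per_trial.groupby("week")["pfi"]
        .agg(mean_pfi="mean",
             sem_pfi=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v)))
             if len(v) > 1 else 0.0,
             n_trials="size")
        .reset_index()
        .sort_values("week", ignore_index=True)
    )
    return per_trial, weekly
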