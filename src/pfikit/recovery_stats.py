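"""Longitudinal hypothesis tests for recovery time courses.

Three tools cover the reporting conventions of walking-track studies: one-way
ANOVA for an overall effect of time, Tukey HSD all-pairs comparisons
summarised as a compact letter display (groups sharing no letter differ
significantly), and Dunnett many-to-one comparisons of each post-injury week
against the pre-injury baseline.

Repeated trials within an animal are pseudo-replicates; by default callers
should collapse them to one value per rat x week (see
:func:`collapse_trials`) before testing.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "LetterGroups",
    "DunnettResult",
    "DegenerateDataError",
    "one_way_anova",
    "tukey_letters",
    "dunnett_vs_baseline",
    "collapse_trials",
]


class DegenerateDataError(ValueError):
    """The groups cannot support the requested test."""


@dataclass(frozen=True)
class AnovaResult:
    F_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class LetterGroups:
    """Compact letter display: labels sharing no letter differ significantly."""

    letters: dict[str, str]  # group label -> sorted letter string
    alpha: float
    p_values: dict[tuple[str, str], float]  # unordered pair -> Tukey p

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


@dataclass(frozen=True)
class DunnettResult:
    """Adjusted p-values and significance flags vs the baseline group."""

    p_values: dict[str, float]  # comparison label -> adjusted p
    flags: dict[str, bool]  # True where adjusted p < alpha
    alpha: float
    method: str


def _validate_groups(groups: Sequence[Sequence[float]], min_groups: int = 2
                     ) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < min_groups:
        raise DegenerateDataError(f"need >= {min_groups} groups, got {len(arrays)}")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise DegenerateDataError(f"group {i} has n={a.size}; need n >= 2")
        if not np.all(np.isfinite(a)):
            raise DegenerateDataError(f"group {i} contains non-finite values")
    return arrays


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classic (non-Welch) one-way ANOVA across two or more groups.

    Uses the between/within sums-of-squares decomposition with the F-tail
    from scipy's F distribution.  Zero pooled within-group variance is a
    degenerate input (F would be undefined).
    """
    arrays = _validate_groups(groups)
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = all_values.size - len(arrays)
    if ss_within <= 0:
        raise DegenerateDataError("zero within-group variance: F is undefined")
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), df_between, df_within, max(p, np.finfo(float).tiny))


def _compact_letters(labels: Sequence[str],
                     sig_pairs: set[frozenset[str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Start from one letter column holding every group; for each significant
    pair occupying a common column, split the column into two copies lacking
    one member each, then absorb columns that became subsets of others.  By
    construction non-significant pairs always retain a shared column and
    significant pairs never do.
    """
    columns: list[set[str]] = [set(labels)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for child in (col - {a}, col - {b}):
                if child and not any(child <= other for other in columns):
                    columns.append(child)
        # absorb columns that are now redundant subsets
        columns = [
            c for i, c in enumerate(columns)
            if not any(c < other or (c == other and i > j)
                       for j, other in enumerate(columns))
        ]
    # Order columns by the first label (in input order) they contain.
    order = {lab: i for i, lab in enumerate(labels)}
    columns.sort(key=lambda c: min(order[lab] for lab in c))
    alphabet = string.ascii_lowercase
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for i, col in enumerate(columns):
        letter = alphabet[i] if i < 26 else f"z{i}"
        for lab in col:
            letters[lab].append(letter)
    return {lab: "".join(sorted(ls)) for lab, ls in letters.items()}


def tukey_letters(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> LetterGroups:
    """All-pairs Tukey HSD comparisons summarised as a compact letter display."""
    arrays = _validate_groups(groups)
    if labels is None:
        labels = [str(i) for i in range(len(arrays))]
    labels = list(map(str, labels))
    if len(labels) != len(arrays):
        raise DegenerateDataError("labels must match the number of groups")
    if sum(((a - a.mean()) ** 2).sum() for a in arrays) <= 0:
        raise DegenerateDataError("zero within-group variance")
    res = stats.tukey_hsd(*arrays)
    p_values: dict[tuple[str, str], float] = {}
    sig_pairs: set[frozenset[str]] = set()
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p = float(res.pvalue[i, j])
            p_values[(labels[i], labels[j])] = p
            if p < alpha:
                sig_pairs.add(frozenset((labels[i], labels[j])))
    letters = _compact_letters(labels, sig_pairs)
    return LetterGroups(letters=letters, alpha=alpha, p_values=p_values)


def dunnett_vs_baseline(
    baseline: Sequence[float],
    others: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    method: str = "auto",
    random_state: Optional[int] = None,
) -> DunnettResult:
    """Dunnett many-to-one comparisons of each group against the baseline.

    ``method='auto'`` uses the multivariate-t criterion (scipy's Dunnett
    test); ``method='bonferroni'`` is the documented conservative fallback
    (two-sample pooled t-tests with Bonferroni adjustment).
    """
    base = _validate_groups([baseline], min_groups=1)[0]
    arrays = _validate_groups(others, min_groups=1)
    if labels is None:
        labels = [str(i + 1) for i in range(len(arrays))]
    labels = list(map(str, labels))
    if len(labels) != len(arrays):
        raise DegenerateDataError("labels must match the number of groups")

    if method in ("auto", "dunnett"):
        rng = np.random.default_rng(random_state)
        res = stats.dunnett(*arrays, control=base, alternative="two-sided",
                            random_state=rng)
        adj = {lab: float(min(p, 1.0)) for lab, p in zip(labels, res.pvalue)}
        used = "dunnett"
    elif method == "bonferroni":
        # Same pooled-variance t statistics as Dunnett, Bonferroni-adjusted:
        # always at least as large as the multivariate-t adjusted p.
        k = len(arrays)
        everything = [base] + list(arrays)
        df_w = sum(a.size for a in everything) - len(everything)
        s2 = sum(((a - a.mean()) ** 2).sum() for a in everything) / df_w
        if s2 <= 0:
            raise DegenerateDataError("zero within-group variance")
        adj = {}
        for lab, a in zip(labels, arrays):
            t = (a.mean() - base.mean()) / np.sqrt(
                s2 * (1.0 / a.size + 1.0 / base.size))
            p = 2.0 * float(stats.t.sf(abs(t), df_w))
            adj[lab] = float(min(p * k, 1.0))
        used = "bonferroni"
    else:
        raise ValueError(f"unknown method {method!r}")
    flags = {lab: p < alpha for lab, p in adj.items()}
    return DunnettResult(p_values=adj, flags=flags, alpha=alpha, method=used)


def collapse_trials(
    df: pd.DataFrame,
    value: str,
    by: Sequence[str] = ("rat_id", "week"),
) -> pd.DataFrame:
    """Average repeated trials within rat x week to avoid pseudo-replication."""
    return df.groupby(list(by), as_index=False)[value].mean()
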