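"""Classic Bain–Mackinnon–Hunter peroneal function index (PFI).

The BMH revision of de Medinaceli's walking-track index scores peroneal nerve
function as an affine combination of two deficit ratios,

    PFI = a * (EPL - ref_PL) / ref_PL + b * (ETS - ref_TS) / ref_TS + c,

with the published peroneal coefficients a = 174.9, b = 80.3, c = -13.4
(Bain, Mackinnon & Hunter 1989).  The scale is anchored so that roughly 0 is
normal function and -100 complete dysfunction.  The reference values are
either the same trial's contralateral-limb measurements (the traditional
convention) or the animal's pre-injury baseline means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .trackdata import (
    CONTRALATERAL,
    EXPERIMENTAL,
    BaselineTable,
    DomainError,
    MissingReferenceError,
    Normalization,
    TrackDataError,
    TrialSummary,
)

__all__ = ["ClassicIndexParams", "BMH_PERONEAL", "classic_pfi",
           "classic_pfi_trial", "classic_pfi_timecourse"]


@dataclass(frozen=True)
class ClassicIndexParams:
    """Coefficients of the affine BMH-style index.

    Defaults are the published BMH peroneal coefficients, shipped as external
    constants (they are configurable; nothing downstream assumes them).
    """

    coef_PL: float = 174.9
    coef_TS: float = 80.3
    constant: float = -13.4


#: The published BMH peroneal coefficient set.
BMH_PERONEAL = ClassicIndexParams()


def classic_pfi(
    e_pl: float,
    e_ts: float,
    ref_pl: float,
    ref_ts: float,
    params: ClassicIndexParams = BMH_PERONEAL,
) -> float:
    """Score one trial's PL/TS measurements to the classic PFI.

    Parameters are the experimental-limb print length and toe spread and
    their reference values (contralateral or baseline).  Affine in each
    deficit ratio; returns ``params.constant`` when experimental equals
    reference for both components.
    """
    if ref_pl <= 0:
        raise DomainError(f"ref_PL must be > 0, got {ref_pl}")
    if ref_ts <= 0:
        raise DomainError(f"ref_TS must be > 0, got {ref_ts}")
    return (
        params.coef_PL * (e_pl - ref_pl) / ref_pl
        + params.coef_TS * (e_ts - ref_ts) / ref_ts
        + params.constant
    )


def classic_pfi_trial(
    summary: TrialSummary,
    params: ClassicIndexParams = BMH_PERONEAL,
    normalization: Normalization = "contralateral",
    baseline: Optional[BaselineTable] = None,
) -> float:
    """Classic PFI for one aggregated trial under the chosen normalization."""
    e_pl = summary.component(EXPERIMENTAL, "PL")
    e_ts = summary.component(EXPERIMENTAL, "TS")
    if normalization == "contralateral":
        ref_pl = summary.component(CONTRALATERAL, "PL")
        ref_ts = summary.component(CONTRALATERAL, "TS")
    elif normalization == "baseline":
        if baseline is None:
            raise MissingReferenceError(
                "baseline normalization requires a BaselineTable"
            )
        ref_pl = baseline.reference(summary.rat_id, EXPERIMENTAL, "PL")
        ref_ts = baseline.reference(summary.rat_id, EXPERIMENTAL, "TS")
    else:
        raise TrackDataError(f"unknown normalization {normalization!r}")
    return classic_pfi(e_pl, e_ts, ref_pl, ref_ts, params)


def classic_pfi_timecourse(
    summaries: Iterable[TrialSummary],
    params: ClassicIndexParams = BMH_PERONEAL,
    normalization: Normalization = "contralateral",
    baseline: Optional[BaselineTable] = None,
) -> pd.DataFrame:
    """Per-week mean classic PFI with its standard error.

    Scores every trial with :func:`classic_pfi_trial` and summarises by week.
    Returns a DataFrame indexed 0..k with columns ``week``, ``mean_pfi``,
    ``sem_pfi``, ``n_trials``; weeks with no trials are simply absent.
    """
    rows = []
    for s in summaries:
        rows.append(
            {
                "rat_id": s.rat_id,
                "week": s.week,
                "trial_id": s.trial_id,
                "pfi": classic_pfi_trial(s, params, normalization, baseline),
            }
        )
    if not rows:
        raise TrackDataError("no trials supplied")
    per_trial = pd.DataFrame(rows)
    out = (
        per_trial.groupby("week")["pfi"]
        .agg(mean_pfi="mean", sem_pfi=lambda v: _sem(v.to_numpy()), n_trials="size")
        .reset_index()
        .sort_values("week", ignore_index=True)
    )
    return out


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(values.size))
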