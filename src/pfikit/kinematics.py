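"""Hock-angle kinematics from 2-D sagittal-plane marker traces.

Markers are tattooed on the stifle, tip of the calcaneus, head of the fourth
metatarsal and the pads of digits 2 and 4; a single lateral camera (60 frames
per second by default) yields 2-D positions with x forward and y up, in mm.
The hock (tarsal/ankle) angle is the interior angle at the calcaneus between
the calcaneus->stifle and calcaneus->metatarsal vectors.  Peroneal injury
disables the tarsal flexors, so the hock flexes less during swing and the
mid-swing angle increases.

The pipeline segments a trace into gait cycles by detecting stance (the toe
pad nearly stationary and near the ground) versus swing, reads the hock angle
at the temporal midpoint of each phase, and expresses weekly mid-swing angles
as a recovery fraction of the pre-injury value relative to the worst (nadir)
excursion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKERS",
    "TRACE_COLUMNS",
    "MarkerFrame",
    "GaitCycle",
    "GeometryError",
    "SegmentationError",
    "hock_angle",
    "hock_angle_series",
    "segment_gait_cycles",
    "midphase_angles",
    "recovery_fraction",
]

log = logging.getLogger(__name__)

MARKERS = ("stifle", "calcaneus", "metatarsal4", "digit2", "digit4")

#: Column order of a marker-trace table: time then x/y per marker (mm).
TRACE_COLUMNS = ("t_s",) + tuple(
    f"{m}_{ax}_mm" for m in MARKERS for ax in ("x", "y")
)


class GeometryError(ValueError):
    """Marker geometry is degenerate (coincident points)."""


class SegmentationError(ValueError):
    """No gait cycles can be detected in the trace."""


@dataclass(frozen=True)
class MarkerFrame:
    """Timed 2-D positions of the five hindlimb markers (x forward, y up, mm)."""

    t: float
    stifle: tuple[float, float]
    calcaneus: tuple[float, float]
    metatarsal4: tuple[float, float]
    digit2: tuple[float, float]
    digit4: tuple[float, float]


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle as frame indices into the parent trace.

    Stance spans [contact, toe_off); swing spans [toe_off, next_contact);
    the intervals are contiguous, non-overlapping, and each holds >= 2 frames.
    """

    contact: int
    toe_off: int
    next_contact: int

    def __post_init__(self) -> None:
        if not (self.contact < self.toe_off < self.next_contact):
            raise SegmentationError("cycle indices must be strictly increasing")
        if self.toe_off - self.contact < 2 or self.next_contact - self.toe_off < 2:
            raise SegmentationError("each phase needs >= 2 frames")

    @property
    def stance(self) -> tuple[int, int]:
        return (self.contact, self.toe_off)

    @property
    def swing(self) -> tuple[int, int]:
        return (self.toe_off, self.next_contact)


def _validate_trace(trace: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"marker trace lacks columns: {missing}")
    t = trace["t_s"].to_numpy(float)
    if len(t) < 4:
        raise SegmentationError("trace too short")
    if not np.all(np.diff(t) > 0):
        raise ValueError("trace times must be strictly increasing")
    if not np.all(np.isfinite(trace[list(TRACE_COLUMNS)].to_numpy(float))):
        raise ValueError("trace contains non-finite coordinates")
    return trace


def hock_angle(
    stifle: Sequence[float],
    calcaneus: Sequence[float],
    metatarsal: Sequence[float],
) -> float:
    """Interior hock angle (degrees, [0, 180]) at the calcaneus.

    The angle between the calcaneus->stifle and calcaneus->metatarsal vectors
    via the arccosine of their normalized dot product.  Invariant to rigid
    rotation, translation and uniform scaling of the three points.
    """
    c = np.asarray(calcaneus, float)
    u = np.asarray(stifle, float) - c
    v = np.asarray(metatarsal, float) - c
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("coincident markers: hock angle undefined")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def hock_angle_series(trace: pd.DataFrame) -> np.ndarray:
    """Per-frame hock angle (degrees) over a marker trace."""
    trace = _validate_trace(trace)
    c = trace[["calcaneus_x_mm", "calcaneus_y_mm"]].to_numpy(float)
    u = trace[["stifle_x_mm", "stifle_y_mm"]].to_numpy(float) - c
    v = trace[["metatarsal4_x_mm", "metatarsal4_y_mm"]].to_numpy(float) - c
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise GeometryError("coincident markers in trace")
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def segment_gait_cycles(
    trace: pd.DataFrame,
    speed_fraction: float = 0.15,
    height_fraction: float = 0.2,
) -> list[GaitCycle]:
    """Partition a trace into gait cycles from toe-pad (digit 4) motion.

    A frame belongs to stance when the toe pad's forward speed is below
    ``speed_fraction`` of the reference swing speed (the median of speeds
    above the trace mean) AND its height is within ``height_fraction`` of the
    toe's vertical range above its minimum.  Swing is the complement.  Partial
    first/last cycles are discarded.
    """
    trace = _validate_trace(trace)
    t = trace["t_s"].to_numpy(float)
    x = trace["digit4_x_mm"].to_numpy(float)
    y = trace["digit4_y_mm"].to_numpy(float)

    speed = np.abs(np.gradient(x, t))
    mean_speed = speed.mean()
    moving = speed > mean_speed
    if not moving.any() or np.ptp(y) < 1e-9:
        raise SegmentationError("no detectable toe motion in trace")
    ref_speed = np.median(speed[moving])
    y_thresh = y.min() + height_fraction * np.ptp(y)
    stance = (speed < speed_fraction * ref_speed) & (y <= y_thresh)
    if stance.all() or (~stance).all():
        raise SegmentationError("no stance/swing alternation detected")

    d = np.diff(stance.astype(int))
    contacts = np.flatnonzero(d == 1) + 1  # swing -> stance
    toe_offs = np.flatnonzero(d == -1) + 1  # stance -> swing
    cycles: list[GaitCycle] = []
    for k, contact in enumerate(contacts[:-1]):
        nxt = contacts[k + 1]
        offs = toe_offs[(toe_offs > contact) & (toe_offs < nxt)]
        if offs.size != 1:
            log.debug("skipping irregular cycle at frame %d", contact)
            continue
        toe_off = int(offs[0])
        if toe_off - contact < 2 or nxt - toe_off < 2:
            log.warning("skipping cycle at frame %d: phase shorter than 2 frames",
                        contact)
            continue
        cycles.append(GaitCycle(int(contact), toe_off, int(nxt)))
    if not cycles:
        raise SegmentationError("no complete gait cycles detected")
    return cycles


def _phase_angle(t: np.ndarray, angles: np.ndarray, start: int, stop: int,
                 mode: str) -> float:
    """Angle at the midpoint of the half-open phase [start, stop)."""
    idx = np.arange(start, stop)
    if mode == "midpoint":
        # Temporal midpoint of the phase; stop indexes the exclusive boundary.
        t_mid = 0.5 * (t[start] + t[min(stop, len(t) - 1)])
        dist = np.abs(t[idx] - t_mid)
        best = dist.min()
        nearest = idx[np.isclose(dist, best, rtol=0, atol=1e-12)]
        return float(np.mean(angles[nearest]))
    raise ValueError(f"unknown midphase mode {mode!r}")


def midphase_angles(
    cycles: Iterable[GaitCycle],
    angles: np.ndarray,
    t: np.ndarray,
    mode: str = "midpoint",
) -> pd.DataFrame:
    """Hock angle at the temporal midpoint of each cycle's swing and stance.

    The nearest frame is used; exact ties average the two nearest frames.
    Returns one row per cycle: ``cycle``, ``mid_swing_angle``,
    ``mid_stance_angle``, ``t_toe_off``.
    """
    angles = np.asarray(angles, float)
    t = np.asarray(t, float)
    if angles.shape != t.shape:
        raise ValueError("angle series and time base differ in length")
    rows = []
    for k, cyc in enumerate(cycles):
        rows.append(
            {
                "cycle": k,
                "mid_stance_angle": _phase_angle(t, angles, *cyc.stance, mode),
                "mid_swing_angle": _phase_angle(t, angles, *cyc.swing, mode),
                "t_toe_off": float(t[cyc.toe_off]),
            }
        )
    if not rows:
        raise SegmentationError("no cycles supplied")
    return pd.DataFrame(rows)


def recovery_fraction(
    weekly_angles: Mapping[int, float],
    baseline_angle: float,
    nadir_week: Optional[int] = None,
) -> pd.DataFrame:
    """Weekly recovery as percent of the pre-injury value.

    Recovery at week w is ``100 * (1 - |angle_w - baseline| / |angle_nadir -
    baseline|)``: 100% when the angle returns to baseline, 0% at the nadir
    excursion.  The nadir defaults to the post-baseline week furthest from
    baseline.  If the nadir equals baseline (no excursion) the fraction is
    undefined and reported as NaN; raw angles are always returned alongside.
    """
    if baseline_angle <= 0:
        raise ValueError(f"baseline angle must be > 0, got {baseline_angle}")
    weeks = sorted(weekly_angles)
    if nadir_week is None:
        post = [w for w in weeks if w > 0] or weeks
        nadir_week = max(post, key=lambda w: abs(weekly_angles[w] - baseline_angle))
    excursion = abs(weekly_angles[nadir_week] - baseline_angle)
    rows = []
    for w in weeks:
        angle = float(weekly_angles[w])
        if excursion == 0:
            rec = float("nan")
        else:
            rec = 100.0 * (1.0 - abs(angle - baseline_angle) / excursion)
        rows.append({"week": w, "mid_swing_angle": angle, "recovery_pct": rec})
    out = pd.DataFrame(rows)
    out.attrs["nadir_week"] = nadir_week
    out.attrs["baseline_angle"] = float(baseline_angle)
    return out
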