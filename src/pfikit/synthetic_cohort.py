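"""Seeded simulation of walking-track cohorts and kinematic marker traces.

The study designs emulated here are longitudinal rat cohorts after common
peroneal nerve injury: a paper-substrate study (transection and repair n=12,
critical gap n=6; weeks 0,1,2,3,4,8,12,16,20,24) and a video/kinematic study
(repair n=8, crush n=8, transect-and-ligate n=7; weeks 0,2,4,8,12,16), with
at least three trials per rat per time point and usually two usable prints
per limb per trial.

Each walking-track component follows a deficit-then-recovery trajectory:

    mean(week) = baseline * (1 + amplitude * shape(week)),
    shape(w)   = w / nadir                       for w <= nadir
               = (1 - plateau) + plateau * exp(-rate * (w - nadir))   after,

so the deficit rises linearly to its full amplitude at the nadir week and
then decays exponentially toward a residual deficit of (1 - plateau) times
the amplitude.  ``plateau_fraction = 0`` means no recovery (the ligated
negative control); crush recovers faster than transection-and-repair.  Noise
is Gaussian at three levels: a per-rat random intercept, per-trial noise and
per-print noise, all expressed as fractions of the component baseline.  The
paper-substrate study optionally carries a heel-strike artifact that inflates
the experimental-limb print length after injury (the heel strikes earlier
than the toes, elongating the inked print), which is what breaks the classic
index on paper substrates.

Marker traces are built so that the hock angle of the emitted marker
positions equals a programmed waveform exactly (the stifle is placed by
rotating the foot axis by the target angle), and ground-truth contact and
toe-off times and mid-phase angles are returned alongside for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .trackdata import COMPONENTS, CONTRALATERAL, EXPERIMENTAL, PrintMeasurement
from .kinematics import TRACE_COLUMNS

__all__ = [
    "INJURIES",
    "ComponentProfile",
    "RecoveryProfile",
    "StudyDesign",
    "TrackSimulation",
    "MarkerSimulation",
    "default_profile",
    "paper_study_design",
    "video_study_design",
    "deficit_shape",
    "simulate_tracks",
    "simulate_markers",
]

INJURIES = ("crush", "transect_repair", "critical_gap", "transect_ligate", "sham")


@dataclass(frozen=True)
class ComponentProfile:
    """Baseline and injury response of one walking-track component.

    ``amplitude`` is the peak fractional change of the experimental-limb mean
    at the nadir (signed: toe spreads shrink, stance width grows);
    ``nadir_week`` optionally overrides the profile-level nadir (DA and SW
    reach maximal dysfunction a week later than the print-geometry
    components here).
    """

    baseline: float
    sd: float
    amplitude: float
    nadir_week: Optional[float] = None


@dataclass(frozen=True)
class RecoveryProfile:
    """Injury-specific generator parameters for one cohort."""

    injury: str
    components: Mapping[str, ComponentProfile]
    nadir_week: float = 3.0
    recovery_rate: float = 0.35  # per week, speed of the post-nadir decay
    plateau_fraction: float = 0.85  # fraction of the deficit eventually recovered
    contralateral_compensation: float = 0.12  # C-limb amplitude as fraction of E
    heel_strike_artifact: bool = False
    pl_artifact_amplitude: float = 0.20  # fractional E-PL inflation on paper
    velocity_baseline: float = 280.0  # mm/s
    velocity_sd: float = 30.0
    velocity_drift: float = 0.0  # mm/s per week (paper study: negative)
    rat_sd_fraction: float = 0.03
    trial_sd_fraction: float = 0.04
    print_sd_fraction: float = 0.02
    # Kinematics: healthy mid-swing hock angle and its injury elevation.
    hock_midswing_healthy: float = 85.0  # degrees
    hock_stance_angle: float = 130.0
    hock_deficit_deg: float = 40.0
    hock_rat_sd: float = 2.0
    hock_noise_deg: float = 0.5

    def __post_init__(self) -> None:
        if self.injury not in INJURIES:
            raise ValueError(f"unknown injury {self.injury!r}")
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must lie in [0, 1]")
        if self.nadir_week <= 0:
            raise ValueError("nadir_week must be > 0")
        if self.injury == "transect_ligate" and self.plateau_fraction != 0.0:
            raise ValueError("the ligated negative control must not recover "
                             "(plateau_fraction must be 0)")
        missing = [c for c in COMPONENTS if c not in self.components]
        if missing:
            raise ValueError(f"profile lacks components: {missing}")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: group size, assessment weeks, trials and prints."""

    n_rats: int = 12
    weeks: tuple[int, ...] = (0, 1, 2, 3, 4, 8, 12, 16, 20, 24)
    trials_per_week: int = 3
    prints_per_trial: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if 0 not in self.weeks:
            raise ValueError("assessment weeks must include baseline week 0")
        if self.n_rats < 1 or self.trials_per_week < 1 or self.prints_per_trial < 1:
            raise ValueError("n_rats, trials and prints must all be >= 1")


@dataclass(frozen=True)
class TrackSimulation:
    """Simulated walking-track cohort: prints, per-trial velocities, truth."""

    prints: tuple[PrintMeasurement, ...]
    velocities: dict[tuple[str, int, str], float]  # (rat, week, trial) -> mm/s
    truth: dict


@dataclass(frozen=True)
class MarkerSimulation:
    """Simulated marker traces per rat x week plus generator ground truth."""

    traces: dict[tuple[str, int], pd.DataFrame]
    truth: dict[tuple[str, int], dict]


# ---------------------------------------------------------------------------
# Default profiles and designs
# ---------------------------------------------------------------------------

# Realistic adult-rat walking-track baselines (mm; DA in degrees).
_BASELINES = {
    "PL": ComponentProfile(28.0, 1.2, -0.08),
    "TS": ComponentProfile(11.0, 0.5, -0.35),
    "IT": ComponentProfile(6.0, 0.3, -0.30),
    "TOF": ComponentProfile(45.0, 2.0, 0.15),
    "DA": ComponentProfile(175.0, 4.0, -0.08, nadir_week=4.0),
    "SW": ComponentProfile(14.0, 1.0, 0.20, nadir_week=4.0),
}


def _scaled(components: Mapping[str, ComponentProfile], factor: float
            ) -> dict[str, ComponentProfile]:
    return {k: replace(v, amplitude=v.amplitude * factor)
            for k, v in components.items()}


def default_profile(injury: str, heel_strike_artifact: Optional[bool] = None
                    ) -> RecoveryProfile:
    """Stock generator profile for each injury model.

    Crush recovers fastest and most completely; transection-with-repair is
    slower; a critical gap recovers only marginally; transect-and-ligate is
    the no-recovery negative control; sham has no deficit at all.
    """
    if injury == "sham":
        return RecoveryProfile(
            injury="sham", components=_scaled(_BASELINES, 0.0),
            contralateral_compensation=0.0, hock_deficit_deg=0.0,
            plateau_fraction=1.0,
        )
    if injury == "crush":
        return RecoveryProfile(
            injury="crush", components=_scaled(_BASELINES, 0.8),
            nadir_week=2.0, recovery_rate=1.0, plateau_fraction=0.97,
            heel_strike_artifact=bool(heel_strike_artifact),
            hock_deficit_deg=30.0,
        )
    if injury == "transect_repair":
        return RecoveryProfile(
            injury="transect_repair", components=dict(_BASELINES),
            nadir_week=3.0, recovery_rate=0.35, plateau_fraction=0.85,
            heel_strike_artifact=bool(heel_strike_artifact),
            velocity_drift=-3.0 if heel_strike_artifact else 0.0,
        )
    if injury == "critical_gap":
        return RecoveryProfile(
            injury="critical_gap", components=_scaled(_BASELINES, 1.3),
            nadir_week=4.0, recovery_rate=0.08, plateau_fraction=0.35,
            heel_strike_artifact=bool(heel_strike_artifact),
            velocity_drift=-3.0 if heel_strike_artifact else 0.0,
        )
    if injury == "transect_ligate":
        return RecoveryProfile(
            injury="transect_ligate", components=dict(_BASELINES),
            nadir_week=3.0, recovery_rate=0.0, plateau_fraction=0.0,
            heel_strike_artifact=bool(heel_strike_artifact),
        )
    raise ValueError(f"unknown injury {injury!r}")


def paper_study_design(injury: str = "transect_repair", seed: int = 0) -> StudyDesign:
    """Paper-substrate study layout: n=12 repair / n=6 gap, weeks 0-24."""
    n = {"transect_repair": 12, "critical_gap": 6}.get(injury, 12)
    return StudyDesign(n_rats=n, weeks=(0, 1, 2, 3, 4, 8, 12, 16, 20, 24),
                       trials_per_week=3, prints_per_trial=2, seed=seed)


def video_study_design(injury: str = "transect_repair", seed: int = 0) -> StudyDesign:
    """Video/kinematic study layout: n=8/8/7, weeks 0-16."""
    n = {"transect_repair": 8, "crush": 8, "transect_ligate": 7}.get(injury, 8)
    return StudyDesign(n_rats=n, weeks=(0, 2, 4, 8, 12, 16),
                       trials_per_week=3, prints_per_trial=2, seed=seed)


# ---------------------------------------------------------------------------
# Trajectory shape
# ---------------------------------------------------------------------------


def deficit_shape(week: float, nadir_week: float, rate: float,
                  plateau_fraction: float) -> float:
    """Deficit trajectory in [0, 1]: linear rise to the nadir, exponential decay.

    0 before injury, 1 at the nadir week, then decaying toward the residual
    ``1 - plateau_fraction`` at ``rate`` per week.
    """
    if week <= 0:
        return 0.0
    if week <= nadir_week:
        return week / nadir_week
    return (1.0 - plateau_fraction) + plateau_fraction * np.exp(
        -rate * (week - nadir_week)
    )


def _component_mean(profile: RecoveryProfile, comp: str, week: float,
                    limb: str) -> float:
    cp = profile.components[comp]
    nadir = cp.nadir_week if cp.nadir_week is not None else profile.nadir_week
    shape = deficit_shape(week, nadir, profile.recovery_rate,
                          profile.plateau_fraction)
    if limb == EXPERIMENTAL:
        amp = cp.amplitude
        mean = cp.baseline * (1.0 + amp * shape)
        if comp == "PL" and profile.heel_strike_artifact:
            # Heel-strike artifact: early heel contact elongates the inked
            # experimental print, overriding the true (mild) shortening.
            mean = cp.baseline * (1.0 + profile.pl_artifact_amplitude * shape)
        return mean
    # Contralateral compensation: small same-direction shift for load-bearing
    # components (SW, PL, TOF widen), tiny for spreads.
    amp = cp.amplitude * profile.contralateral_compensation
    return cp.baseline * (1.0 + amp * shape)


# ---------------------------------------------------------------------------
# Walking-track simulation
# ---------------------------------------------------------------------------


def simulate_tracks(
    design: StudyDesign,
    profile: RecoveryProfile,
    seed: Optional[int] = None,
    dropout_probability: float = 0.0,
) -> TrackSimulation:
    """Simulate a walking-track cohort as per-print measurements.

    Reproducible: the same (design, profile, seed) triple yields identical
    output.  ``dropout_probability`` optionally rejects whole trials (rats
    pausing, smeared ink); off by default.  IT is generated as a fraction of
    the same print's TS so the IT <= TS invariant always holds.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    prints: list[PrintMeasurement] = []
    velocities: dict[tuple[str, int, str], float] = {}
    expected: dict[str, dict[int, float]] = {
        comp: {w: _component_mean(profile, comp, w, EXPERIMENTAL)
               for w in design.weeks}
        for comp in COMPONENTS
    }

    for r in range(design.n_rats):
        rat_id = f"{profile.injury}-{r + 1:02d}"
        rat_eff = {
            (limb, comp): rng.normal(
                0.0, profile.rat_sd_fraction * profile.components[comp].baseline
            )
            for limb in (EXPERIMENTAL, CONTRALATERAL)
            for comp in COMPONENTS
        }
        rat_vel = rng.normal(0.0, profile.velocity_sd)
        for week in design.weeks:
            for trial in range(design.trials_per_week):
                trial_id = f"t{trial + 1}"
                if dropout_probability > 0 and rng.random() < dropout_probability:
                    continue
                vel = (profile.velocity_baseline + rat_vel
                       + profile.velocity_drift * week
                       + rng.normal(0.0, 0.3 * profile.velocity_sd))
                velocities[(rat_id, week, trial_id)] = float(max(vel, 20.0))
                trial_eff = {
                    (limb, comp): rng.normal(
                        0.0,
                        profile.trial_sd_fraction
                        * profile.components[comp].baseline,
                    )
                    for limb in (EXPERIMENTAL, CONTRALATERAL)
                    for comp in COMPONENTS
                }
                for limb in (EXPERIMENTAL, CONTRALATERAL):
                    for p in range(design.prints_per_trial):
                        vals = {}
                        for comp in COMPONENTS:
                            base = profile.components[comp].baseline
                            mean = (_component_mean(profile, comp, week, limb)
                                    + rat_eff[(limb, comp)]
                                    + trial_eff[(limb, comp)])
                            noise = rng.normal(
                                0.0, profile.print_sd_fraction * base
                            )
                            vals[comp] = mean + noise
                        # Keep the print physically valid.
                        vals["PL"] = max(vals["PL"], 1.0)
                        vals["TS"] = max(vals["TS"], 1.0)
                        vals["IT"] = float(
                            min(max(vals["IT"], 0.5), 0.95 * vals["TS"])
                        )
                        vals["TOF"] = max(vals["TOF"], 0.0)
                        vals["SW"] = max(vals["SW"], 0.0)
                        vals["DA"] = float(np.clip(vals["DA"], 1.0, 359.0))
                        prints.append(
                            PrintMeasurement(
                                rat_id=rat_id, week=week, trial_id=trial_id,
                                limb=limb, print_index=p + 1, **vals,
                            )
                        )
    truth = {
        "injury": profile.injury,
        "expected_experimental_means": expected,
        "nadir_week": profile.nadir_week,
        "plateau_fraction": profile.plateau_fraction,
    }
    return TrackSimulation(prints=tuple(prints), velocities=velocities, truth=truth)


# ---------------------------------------------------------------------------
# Marker-trace simulation
# ---------------------------------------------------------------------------


def _hock_waveform(phase: float, in_swing: bool, stance_angle: float,
                   midswing_angle: float) -> float:
    if not in_swing:
        return stance_angle
    return stance_angle - (stance_angle - midswing_angle) * np.sin(np.pi * phase)


def simulate_markers(
    design: StudyDesign,
    profile: RecoveryProfile,
    seed: Optional[int] = None,
    fps: float = 60.0,
    n_cycles: int = 6,
    cycle_period: float = 0.5,
    duty_factor: float = 0.6,
    stride_mm: float = 120.0,
) -> MarkerSimulation:
    """Simulate sagittal marker traces with programmed gait events and angles.

    One trace per rat x week.  The toe pad (digit 4) is stationary on the
    ground during stance and follows a smooth arc during swing; the stifle is
    placed by rotating the foot axis about the calcaneus by the programmed
    hock angle, so the emitted geometry reproduces the target waveform
    exactly (before small marker jitter).  Ground truth per trace: contact
    times, toe-off times, and the programmed mid-swing/mid-stance angles.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    stance_dur = duty_factor * cycle_period
    swing_dur = cycle_period - stance_dur
    total = n_cycles * cycle_period
    t = np.arange(0.0, total, 1.0 / fps)
    jitter_sd = 0.05  # mm, digitization noise on every marker coordinate

    traces: dict[tuple[str, int], pd.DataFrame] = {}
    truth: dict[tuple[str, int], dict] = {}
    for r in range(design.n_rats):
        rat_id = f"{profile.injury}-{r + 1:02d}"
        rat_angle_eff = rng.normal(0.0, profile.hock_rat_sd)
        for week in design.weeks:
            shape = deficit_shape(week, profile.nadir_week,
                                  profile.recovery_rate,
                                  profile.plateau_fraction)
            midswing = (profile.hock_midswing_healthy
                        + profile.hock_deficit_deg * shape + rat_angle_eff)
            midswing = min(midswing, profile.hock_stance_angle - 2.0)
            rows = np.empty((len(t), len(TRACE_COLUMNS)))
            swing_h = 12.0  # mm toe clearance
            for i, ti in enumerate(t):
                k = int(ti // cycle_period)
                tau = ti - k * cycle_period
                in_swing = tau >= stance_dur
                x_contact = k * stride_mm
                if in_swing:
                    sphase = (tau - stance_dur) / swing_dur
                    toe_x = x_contact + stride_mm * 0.5 * (1 - np.cos(np.pi * sphase))
                    toe_y = swing_h * np.sin(np.pi * sphase)
                else:
                    sphase = 0.0
                    toe_x, toe_y = x_contact, 0.0
                digit4 = np.array([toe_x, toe_y])
                digit2 = digit4 + np.array([1.5, 0.8])
                metatarsal = digit4 + np.array([-8.0, 3.0])
                foot_axis = digit4 - metatarsal
                foot_axis = foot_axis / np.linalg.norm(foot_axis)
                calcaneus = metatarsal - 14.0 * foot_axis
                u = metatarsal - calcaneus
                u = u / np.linalg.norm(u)
                theta = _hock_waveform(sphase, in_swing,
                                       profile.hock_stance_angle, midswing)
                theta += rng.normal(0.0, profile.hock_noise_deg)
                rad = np.radians(theta)
                rot = np.array([[np.cos(rad), -np.sin(rad)],
                                [np.sin(rad), np.cos(rad)]])
                stifle = calcaneus + 32.0 * (rot @ u)
                coords = np.concatenate([stifle, calcaneus, metatarsal,
                                         digit2, digit4])
                coords += rng.normal(0.0, jitter_sd, size=coords.shape)
                rows[i, 0] = ti
                rows[i, 1:] = coords
            trace = pd.DataFrame(rows, columns=list(TRACE_COLUMNS))
            contact_times = [k * cycle_period for k in range(1, n_cycles)]
            toe_off_times = [k * cycle_period + stance_dur
                             for k in range(n_cycles)]
            traces[(rat_id, week)] = trace
            truth[(rat_id, week)] = {
                "contact_times": contact_times,
                "toe_off_times": toe_off_times,
                "mid_swing_angle": float(midswing),
                "mid_stance_angle": float(profile.hock_stance_angle),
                "fps": fps,
            }
    return MarkerSimulation(traces=traces, truth=truth)
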