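"""Synthetic forepaw behavior: cohorts of mice x days x groups.

The generator emulates the study design this package analyzes: two groups of
head-fixed mice (feedback vs control, 7 per group) trained 30 min/day for 4
days, filmed at ~70 fps, reaching upward with the left forepaw toward a
target ~15 mm above rest. Reaches are minimum-jerk bell profiles (up and
back over ``reach_duration`` seconds) with additive Gaussian jitter,
interleaved with rest; the right paw performs constant-rate non-task
movements that serve as the denominator of the reach ratio.

Learning is planted in two places, mirroring the phenomena the analysis is
built to detect:

* the left-paw reach *rate* grows per day by a multiplicative gain, larger
  in the feedback group (the reach-ratio learning curve), and
* the reach *apex* distribution shifts up and tightens per day in the
  feedback group (the Day-1 vs Day-2+ trajectory-cluster structure).

No distributional parameters for real mouse reach kinematics are published
for this task; every default here is a documented stand-in chosen to look
like plausible head-fixed forelimb behavior (see docs/methods.md). The
generator does not model behavioral plasticity in response to the tone - the
learning effects are planted, not emergent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .pose import Calibration, DEFAULT_BODYPARTS, PoseStream

__all__ = [
    "CohortDesign",
    "LearningParams",
    "PlantedReach",
    "GroundTruth",
    "SimulatedSession",
    "minimum_jerk_pulse",
    "simulate_reach",
    "simulate_session",
    "simulate_cohort",
    "cohort_keys",
    "session_seed",
    "simulate_count_table",
    "synthetic_ratio_table",
]


@dataclass(frozen=True)
class CohortDesign:
    """Study design: group sizes, days, session length, frame rate."""

    n_per_group: int = 7
    n_days: int = 4
    session_length: float = 1800.0
    fps: float = 70.0
    groups: tuple[str, str] = ("feedback", "control")

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_days < 1:
            raise ValueError("n_per_group and n_days must be >= 1")
        if self.fps <= 0 or self.session_length <= 0:
            raise ValueError("fps and session_length must be > 0")

    @property
    def n_sessions(self) -> int:
        return self.n_per_group * len(self.groups) * self.n_days


@dataclass(frozen=True)
class LearningParams:
    """Planted learning dynamics (all kinematic values are stand-ins).

    base_reach_rate
        Left-paw reaches per minute on Day 1.
    rate_gain_feedback / rate_gain_control
        Multiplicative per-day growth of the left reach rate.
    peak_mean_base, peak_mean_gain_*
        Mean reach apex (mm) on Day 1 and its additive per-day growth (mm).
    peak_sd_base, peak_sd_gain_*
        Apex spread (mm) on Day 1 and its multiplicative per-day change;
        < 1 in the feedback group so trajectories become consistent.
    noise_sd
        Kinematic jitter SD (mm) added to the displacement trace.
    right_paw_rate
        Right-paw movement rate (per minute), constant across days.
    """

    base_reach_rate: float = 3.0
    rate_gain_feedback: float = 1.35
    rate_gain_control: float = 1.08
    peak_mean_base: float = 13.0
    peak_mean_gain_feedback: float = 1.5
    peak_mean_gain_control: float = 0.5
    peak_sd_base: float = 4.0
    peak_sd_gain_feedback: float = 0.6
    peak_sd_gain_control: float = 1.0
    noise_sd: float = 0.3
    right_paw_rate: float = 3.0
    right_peak_mean: float = 8.0
    right_peak_sd: float = 2.0
    reach_duration: float = 0.8
    reach_duration_sd: float = 0.1
    min_gap: float = 2.0
    dropout_prob: float = 0.0
    target_offset: float = 15.0

    def __post_init__(self) -> None:
        for name in ("base_reach_rate", "right_paw_rate", "peak_sd_base", "noise_sd",
                     "right_peak_sd", "reach_duration_sd", "min_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rate_gain_feedback", "rate_gain_control", "peak_mean_base",
                     "reach_duration", "target_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")

    # ------------------------------------------------------- per-day values
    def rate_for(self, group: str, day: int) -> float:
        gain = self.rate_gain_feedback if group == "feedback" else self.rate_gain_control
        return self.base_reach_rate * gain ** (day - 1)

    def peak_mean_for(self, group: str, day: int) -> float:
        gain = (
            self.peak_mean_gain_feedback if group == "feedback" else self.peak_mean_gain_control
        )
        return self.peak_mean_base + gain * (day - 1)

    def peak_sd_for(self, group: str, day: int) -> float:
        gain = self.peak_sd_gain_feedback if group == "feedback" else self.peak_sd_gain_control
        return max(self.peak_sd_base * gain ** (day - 1), 0.0)


@dataclass(frozen=True)
class PlantedReach:
    paw: str
    onset: float
    duration: float
    apex: float
    success: bool


@dataclass
class GroundTruth:
    """Per-session list of planted reaches with success flags."""

    target_offset: float
    reaches: list[PlantedReach] = field(default_factory=list)

    def by_paw(self, paw: str) -> list[PlantedReach]:
        return [r for r in self.reaches if r.paw == paw]

    @property
    def left_count(self) -> int:
        return len(self.by_paw("left"))

    @property
    def right_count(self) -> int:
        return len(self.by_paw("right"))

    @property
    def success_count(self) -> int:
        return sum(1 for r in self.reaches if r.paw == "left" and r.success)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"target_offset": self.target_offset}, sort_keys=True) + "\n")
            for r in self.reaches:
                fh.write(json.dumps(
                    {"paw": r.paw, "onset": r.onset, "duration": r.duration,
                     "apex": r.apex, "success": r.success}, sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            lines = [json.loads(s) for s in fh if s.strip()]
        gt = cls(target_offset=lines[0]["target_offset"])
        for o in lines[1:]:
            gt.reaches.append(PlantedReach(o["paw"], o["onset"], o["duration"],
                                           o["apex"], o["success"]))
        return gt


@dataclass
class SimulatedSession:
    mouse: str
    day: int
    group: str
    stream: PoseStream
    truth: GroundTruth
    calibration: Calibration


# ----------------------------------------------------------------------
# Kinematic primitives
# ----------------------------------------------------------------------

def minimum_jerk_pulse(n: int) -> np.ndarray:
    """Symmetric up-and-back minimum-jerk position profile, peak exactly 1.

    The rise and return each follow the minimum-jerk position curve
    ``s(u) = 10u^3 - 15u^4 + 6u^5``; the sampled profile is rescaled so its
    maximum is exactly 1 regardless of where the grid falls.
    """
    if n < 3:
        raise ValueError("need at least 3 samples for a reach pulse")
    tau = np.linspace(0.0, 1.0, n)
    u = np.where(tau <= 0.5, 2 * tau, 2 * (1 - tau))
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    return s / s.max()


def simulate_reach(
    apex: float,
    duration: float,
    fps: float,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """One reach: a minimum-jerk bell scaled to ``apex`` mm plus jitter.

    With ``noise_sd=0`` the segment's maximum equals ``apex`` exactly and
    both endpoints are 0. ``duration`` seconds at ``fps`` yields
    ``round(duration * fps)`` samples.
    """
    if apex <= 0 or duration <= 0 or fps <= 0:
        raise ValueError("apex, duration and fps must all be > 0")
    n = max(int(round(duration * fps)), 3)
    seg = apex * minimum_jerk_pulse(n)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        seg = seg + rng.normal(0.0, noise_sd, n)
    return seg


def _plant_reaches(
    disp: np.ndarray,
    rate_per_min: float,
    apex_mean: float,
    apex_sd: float,
    params: LearningParams,
    design: CohortDesign,
    rng: np.random.Generator,
    paw: str,
    target: float,
) -> list[PlantedReach]:
    """Place non-overlapping reaches into ``disp`` in temporal order."""
    out: list[PlantedReach] = []
    if rate_per_min <= 0:
        return out
    fps = design.fps
    length = design.session_length
    mean_gap = max(60.0 / rate_per_min - params.reach_duration, 0.1)
    t = rng.exponential(mean_gap)
    while True:
        dur = params.reach_duration
        if params.reach_duration_sd > 0:
            dur = max(rng.normal(params.reach_duration, params.reach_duration_sd), 0.2)
        apex = rng.normal(apex_mean, apex_sd)
        apex = max(apex, 3.0)  # keep every planted reach a detectable excursion
        if t + dur > length - 0.5:
            break
        i0 = int(round(t * fps))
        seg = simulate_reach(apex, dur, fps)
        i1 = min(i0 + len(seg), len(disp))
        disp[i0:i1] = np.maximum(disp[i0:i1], seg[: i1 - i0])
        onset = i0 / fps
        out.append(PlantedReach(paw, onset, dur, apex, bool(apex >= target)))
        t = t + dur + params.min_gap + rng.exponential(mean_gap)
    return out


def simulate_session(
    mouse: str,
    day: int,
    group: str,
    params: LearningParams | None = None,
    design: CohortDesign | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    calibration: Calibration | None = None,
) -> tuple[PoseStream, GroundTruth]:
    """Simulate one session: pose stream plus ground-truth reach list.

    Left-paw reaches arrive at the day- and group-dependent planted rate with
    apex ~ N(peak_mean, peak_sd); right-paw movements arrive at a constant
    rate. Displacements are converted to pixel-space pose frames via the
    calibration (y down; upward reach lowers y). Deterministic per seed.
    """
    params = params or LearningParams()
    design = design or CohortDesign()
    if not (1 <= day <= design.n_days):
        raise ValueError(f"day {day} outside [1, {design.n_days}]")
    if group not in design.groups:
        raise ValueError(f"unknown group {group!r}; expected one of {design.groups}")
    cal = calibration or Calibration()
    rng = np.random.default_rng(seed)
    n = int(round(design.session_length * design.fps))
    disp_left = np.zeros(n)
    disp_right = np.zeros(n)
    truth = GroundTruth(target_offset=params.target_offset)
    truth.reaches.extend(
        _plant_reaches(
            disp_left,
            params.rate_for(group, day),
            params.peak_mean_for(group, day),
            params.peak_sd_for(group, day),
            params, design, rng, "left", params.target_offset,
        )
    )
    truth.reaches.extend(
        _plant_reaches(
            disp_right,
            params.right_paw_rate,
            params.right_peak_mean,
            params.right_peak_sd,
            params, design, rng, "right", params.target_offset,
        )
    )
    if params.noise_sd > 0:
        disp_left = disp_left + rng.normal(0.0, params.noise_sd, n)
        disp_right = disp_right + rng.normal(0.0, params.noise_sd, n)

    k = len(DEFAULT_BODYPARTS)
    y = np.empty((n, k))
    x = np.empty((n, k))
    lik = np.full((n, k), 0.99)
    for j, name in enumerate(DEFAULT_BODYPARTS):
        if name.startswith("left"):
            y[:, j] = cal.rest_y_left - disp_left / cal.mm_per_pixel
            x[:, j] = 280.0 + 8.0 * j
        else:
            y[:, j] = cal.rest_y_right - disp_right / cal.mm_per_pixel
            x[:, j] = 320.0 + 8.0 * j
    if params.dropout_prob > 0:
        drop_l = rng.random(n) < params.dropout_prob
        drop_r = rng.random(n) < params.dropout_prob
        for j, name in enumerate(DEFAULT_BODYPARTS):
            lik[drop_l if name.startswith("left") else drop_r, j] = 0.2
    stream = PoseStream(DEFAULT_BODYPARTS, x, y, lik, fps=design.fps)
    return stream, truth


# ----------------------------------------------------------------------
# Cohorts
# ----------------------------------------------------------------------

def cohort_keys(design: CohortDesign) -> Iterator[tuple[str, str, int]]:
    """Yield (group, mouse_id, day) for every session in the design."""
    for gi, group in enumerate(design.groups):
        for mi in range(design.n_per_group):
            mouse = f"{group[0]}{mi}"
            for day in range(1, design.n_days + 1):
                yield group, mouse, day


def session_seed(master_seed: int, design: CohortDesign, group: str, mouse: str, day: int):
    """Deterministic per-session seed derived from the master seed.

    Uses ``SeedSequence(master, spawn_key=(group_index, mouse_index, day))``
    so any session is independently reproducible.
    """
    gi = design.groups.index(group)
    mi = int(mouse[1:]) if mouse[1:].isdigit() else abs(hash(mouse)) % 2**16
    return np.random.SeedSequence(master_seed, spawn_key=(gi, mi, day))


def simulate_cohort(
    design: CohortDesign | None = None,
    params: LearningParams | None = None,
    seed: int = 0,
    calibration: Calibration | None = None,
) -> list[SimulatedSession]:
    """Simulate every session of the design (groups x mice x days)."""
    design = design or CohortDesign()
    params = params or LearningParams()
    cal = calibration or Calibration()
    out: list[SimulatedSession] = []
    for group, mouse, day in cohort_keys(design):
        ss = session_seed(seed, design, group, mouse, day)
        stream, truth = simulate_session(mouse, day, group, params, design, ss, cal)
        out.append(SimulatedSession(mouse, day, group, stream, truth, cal))
    return out


# ----------------------------------------------------------------------
# Table-level shortcuts for statistical calibration
# ----------------------------------------------------------------------

def simulate_count_table(
    design: CohortDesign | None = None,
    params: LearningParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-mouse per-day reach counts from the rate model alone.

    Draws Poisson counts with the same planted rates the full simulator uses,
    skipping kinematics. Columns: mouse, group, day, left_reaches,
    right_reaches. Useful for calibrating the downstream statistics at scale.
    """
    design = design or CohortDesign()
    params = params or LearningParams()
    rng = np.random.default_rng(seed)
    minutes = design.session_length / 60.0
    rows = []
    for group, mouse, day in cohort_keys(design):
        lam_l = params.rate_for(group, day) * minutes
        lam_r = params.right_paw_rate * minutes
        rows.append(
            {
                "mouse": mouse,
                "group": group,
                "day": day,
                "left_reaches": int(rng.poisson(lam_l)),
                "right_reaches": int(rng.poisson(lam_r)),
            }
        )
    return pd.DataFrame(rows)


def synthetic_ratio_table(
    n_per_group: int = 7,
    n_days: int = 4,
    effect_size_d: float = 0.0,
    sigma: float = 0.3,
    seed: int | np.random.Generator = 0,
    groups: tuple[str, str] = ("feedback", "control"),
) -> pd.DataFrame:
    """Normalized reach-ratio table with a controllable group effect.

    Day 1 is identically 1 (the normalization anchor). From Day 2 on, values
    are ``1 + sigma * z`` with an additive offset of ``effect_size_d * sigma``
    for the first group, i.e. the planted between-group effect is exactly
    ``effect_size_d`` pooled standard deviations. Used for type-I error and
    power calibration of the cohort statistics.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for group in groups:
        shift = effect_size_d * sigma if group == groups[0] else 0.0
        for mi in range(n_per_group):
            for day in range(1, n_days + 1):
                val = 1.0 if day == 1 else 1.0 + shift + sigma * rng.standard_normal()
                rows.append(
                    {"mouse": f"{group[0]}{mi}", "group": group, "day": day,
                     "normalized": float(max(val, 1e-6))}
                )
    return pd.DataFrame(rows)
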