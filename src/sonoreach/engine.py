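"""The closed loop: displacement extraction, trial state machine, tone output.

Per frame the engine (i) aggregates the confidence-gated digit positions of
each paw into a vertical displacement in mm, (ii) applies a short causal
moving average, (iii) steps a three-state trial machine (AT_REST -> REACHING
-> REFRACTORY) that emits reach/success/reward events, and (iv) in feedback
mode emits a tone command whose frequency encodes the smoothed displacement.
Control mode runs the identical pipeline with the tone stage disabled.

A reach starts when the left paw rises above ``start_tolerance`` (2 mm); a
success is counted when it crosses ``target_offset`` (15 mm above rest) and
triggers a 5 ul reward; the paw must return to the start band - and the
refractory interval must have elapsed - before the next trial can begin.

Stage timings (acquire / kinematics / fsm / tone) are instrumented per frame;
under a simulated clock with injected delays the reported end-to-end latency
is exact, which is how latency bookkeeping is tested without hardware.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import asdict, dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Tuple

import numpy as np

from .clock import Clock, SimulatedClock, replay_source
from .pose import Calibration, PoseFrame, PoseStream
from .sonification import SonificationConfig, ToneCommand, map_frequency

__all__ = [
    "TrialConfig",
    "KinematicSample",
    "TrialEvent",
    "TrialState",
    "TrialFSM",
    "StageDelays",
    "FrameTiming",
    "EngineMetrics",
    "DisplacementComputer",
    "MovingAverage",
    "SessionRecord",
    "compute_displacement",
    "smooth",
    "step_trial_fsm",
    "run_session",
    "run_stream",
    "measure_latency",
]

REWARD_VOLUME_UL = 5.0


@dataclass(frozen=True)
class TrialConfig:
    """Task geometry and gating parameters.

    target_offset
        Height of the target zone above rest, mm (default 15).
    start_tolerance
        Band around rest within which the paw counts as "at start", mm.
        Rising above it starts a reach; returning below it ends one.
    refractory
        Minimum interval after a success before the next trial can begin, s.
    likelihood_floor
        Tracking-confidence threshold below which a digit is ignored.
    smooth_window
        Causal moving-average window (frames) applied before the FSM.
    """

    target_offset: float = 15.0
    start_tolerance: float = 2.0
    refractory: float = 0.5
    likelihood_floor: float = 0.6
    smooth_window: int = 3
    reward_volume_ul: float = REWARD_VOLUME_UL

    def __post_init__(self) -> None:
        if not (self.target_offset > self.start_tolerance >= 0):
            raise ValueError("need target_offset > start_tolerance >= 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if not (0 <= self.likelihood_floor <= 1):
            raise ValueError("likelihood_floor must be in [0, 1]")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.reward_volume_ul <= 0:
            raise ValueError("reward_volume_ul must be > 0")


@dataclass(frozen=True)
class KinematicSample:
    """Per-frame paw displacements (mm, upward positive) with validity."""

    timestamp: float
    disp_left: float
    disp_right: float
    valid_left: bool
    valid_right: bool


@dataclass(frozen=True)
class TrialEvent:
    kind: str
    timestamp: float
    payload: dict = field(default_factory=dict)


class TrialState(Enum):
    AT_REST = "at_rest"
    REACHING = "reaching"
    REFRACTORY = "refractory"


# ----------------------------------------------------------------------
# Kinematics
# ----------------------------------------------------------------------

class DisplacementComputer:
    """Stateful per-frame displacement extraction with hold-last policy.

    Per paw, the position is the mean y of the digits whose likelihood passes
    the floor; displacement is ``(rest_y - y) * mm_per_pixel`` (upward
    positive). When no digit passes, the sample is invalid and carries the
    last valid displacement so the FSM and tone never see a gap.
    """

    def __init__(
        self,
        calibration: Calibration,
        cfg: TrialConfig | None = None,
        left_prefix: str = "left",
        right_prefix: str = "right",
    ) -> None:
        if calibration is None:
            raise ValueError("calibration is required")
        self.cal = calibration
        self.cfg = cfg or TrialConfig()
        self.left_prefix = left_prefix
        self.right_prefix = right_prefix
        self._idx: tuple[list[int], list[int]] | None = None
        self._last_left = 0.0
        self._last_right = 0.0

    def _resolve(self, names: Sequence[str]) -> tuple[list[int], list[int]]:
        left = [i for i, n in enumerate(names) if n.startswith(self.left_prefix)]
        right = [i for i, n in enumerate(names) if n.startswith(self.right_prefix)]
        if not left or not right:
            raise ValueError(
                f"frame keypoints {names} lack digits with prefixes "
                f"{self.left_prefix!r}/{self.right_prefix!r}"
            )
        return left, right

    def step(self, frame: PoseFrame) -> KinematicSample:
        if self._idx is None:
            self._idx = self._resolve(frame.names)
        left_idx, right_idx = self._idx
        floor = self.cfg.likelihood_floor
        mmpp = self.cal.mm_per_pixel
        y = frame.y
        lik = frame.likelihood

        def paw(idx: list[int], rest_y: float, last: float) -> tuple[float, bool]:
            s = 0.0
            m = 0
            for i in idx:
                li = lik[i]
                yi = y[i]
                if li >= floor and yi == yi and math.isfinite(yi):
                    s += yi
                    m += 1
            if m == 0:
                return last, False
            return float((rest_y - s / m) * mmpp), True

        dl, vl = paw(left_idx, self.cal.rest_y_left, self._last_left)
        dr, vr = paw(right_idx, self.cal.rest_y_right, self._last_right)
        self._last_left, self._last_right = dl, dr
        return KinematicSample(frame.timestamp, dl, dr, vl, vr)


def compute_displacement(
    frame: PoseFrame,
    calibration: Calibration,
    cfg: TrialConfig | None = None,
    last: KinematicSample | None = None,
) -> KinematicSample:
    """One-shot displacement for a single frame (hold-last from ``last``)."""
    comp = DisplacementComputer(calibration, cfg)
    if last is not None:
        comp._last_left = last.disp_left
        comp._last_right = last.disp_right
    return comp.step(frame)


class MovingAverage:
    """Causal moving average over the last ``window`` samples."""

    def __init__(self, window: int) -> None:
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self._buf: deque[float] = deque(maxlen=window)
        self._sum = 0.0

    def step(self, value: float) -> float:
        if len(self._buf) == self._buf.maxlen:
            self._sum -= self._buf[0]
        self._buf.append(value)
        self._sum += value
        return self._sum / len(self._buf)


def smooth(values: Iterable[float], window: int) -> np.ndarray:
    """Offline causal moving average; ``window=1`` is the identity.

    The leading edge uses partial windows (mean of the samples seen so far),
    so no frames of delay are added beyond the window itself.
    """
    ma = MovingAverage(window)
    return np.array([ma.step(float(v)) for v in values])


# ----------------------------------------------------------------------
# Trial state machine
# ----------------------------------------------------------------------

class TrialFSM:
    """Streaming three-state trial machine over left-paw displacement.

    Hysteresis: reaches start above ``start_tolerance`` but only succeed at
    ``target_offset``; after a success the machine stays REFRACTORY until the
    paw is back in the start band *and* the refractory interval has elapsed.
    Invalid samples cause no transition.
    """

    def __init__(self, cfg: TrialConfig | None = None) -> None:
        self.cfg = cfg or TrialConfig()
        self.state = TrialState.AT_REST
        self._success_t = -math.inf

    def step(self, sample: KinematicSample) -> list[TrialEvent]:
        if not sample.valid_left:
            return []
        cfg = self.cfg
        d = sample.disp_left
        t = sample.timestamp
        events: list[TrialEvent] = []
        if self.state is TrialState.REFRACTORY:
            if d <= cfg.start_tolerance and t >= self._success_t + cfg.refractory:
                events.append(TrialEvent("trial_reset", t))
                self.state = TrialState.AT_REST
            return events
        if self.state is TrialState.AT_REST and d > cfg.start_tolerance:
            events.append(TrialEvent("reach_start", t))
            self.state = TrialState.REACHING
        if self.state is TrialState.REACHING:
            # Target check falls through from reach_start so a frame that is
            # already in the target zone counts in the same frame.
            if d >= cfg.target_offset:
                events.append(TrialEvent("target_entry", t))
                events.append(TrialEvent("success", t))
                events.append(TrialEvent("reward", t, {"volume_ul": cfg.reward_volume_ul}))
                self._success_t = t
                self.state = TrialState.REFRACTORY
            elif d <= cfg.start_tolerance:
                events.append(TrialEvent("trial_reset", t))
                self.state = TrialState.AT_REST
        return events


def step_trial_fsm(
    state: TrialState,
    sample: KinematicSample,
    cfg: TrialConfig | None = None,
    success_time: float = -math.inf,
) -> tuple[TrialState, list[TrialEvent], float]:
    """Pure-function FSM step; returns (state, events, success_time)."""
    fsm = TrialFSM(cfg)
    fsm.state = state
    fsm._success_t = success_time
    events = fsm.step(sample)
    return fsm.state, events, fsm._success_t


# ----------------------------------------------------------------------
# Session loop
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class StageDelays:
    """Injected per-stage processing delays (ms) for latency bookkeeping."""

    acquire_ms: float = 0.0
    kinematics_ms: float = 0.0
    fsm_ms: float = 0.0
    tone_ms: float = 0.0

    @property
    def total_ms(self) -> float:
        return self.acquire_ms + self.kinematics_ms + self.fsm_ms + self.tone_ms


@dataclass(frozen=True)
class FrameTiming:
    t_frame: float
    t_delivered: float
    acquire_ms: float
    kinematics_ms: float
    fsm_ms: float
    tone_ms: float
    t_done: float


@dataclass
class SessionRecord:
    """Everything one session produced: events, kinematics, tones, timings."""

    mouse: str = "m0"
    day: int = 1
    group: str = "feedback"
    mode: str = "feedback"
    events: list[TrialEvent] = field(default_factory=list)
    kinematics: list[KinematicSample] = field(default_factory=list)
    tone_log: list[ToneCommand] = field(default_factory=list)
    timings: list[FrameTiming] = field(default_factory=list)
    trial_config: TrialConfig = field(default_factory=TrialConfig)
    sonification_config: SonificationConfig = field(default_factory=SonificationConfig)
    calibration: Calibration = field(default_factory=Calibration)

    @property
    def success_count(self) -> int:
        return sum(1 for e in self.events if e.kind == "success")

    @property
    def reach_start_count(self) -> int:
        return sum(1 for e in self.events if e.kind == "reach_start")

    # -------------------------------------------------- persistence
    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "events.jsonl", "w", encoding="utf-8") as fh:
            for e in self.events:
                fh.write(json.dumps({"t": e.timestamp, "kind": e.kind, "payload": e.payload},
                                    sort_keys=True) + "\n")
        with open(out / "kinematics.csv", "w", encoding="utf-8") as fh:
            fh.write("t,disp_left,disp_right,valid_left,valid_right\n")
            for s in self.kinematics:
                fh.write(f"{s.timestamp!r},{s.disp_left!r},{s.disp_right!r},"
                         f"{int(s.valid_left)},{int(s.valid_right)}\n")
        with open(out / "tones.jsonl", "w", encoding="utf-8") as fh:
            for c in self.tone_log:
                fh.write(json.dumps({"t": c.timestamp, "f_hz": c.frequency,
                                     "active": bool(c.active)}, sort_keys=True) + "\n")
        with open(out / "timings.csv", "w", encoding="utf-8") as fh:
            fh.write("t_frame,t_delivered,acquire_ms,kinematics_ms,fsm_ms,tone_ms,t_done\n")
            for ft in self.timings:
                fh.write(f"{ft.t_frame!r},{ft.t_delivered!r},{ft.acquire_ms!r},"
                         f"{ft.kinematics_ms!r},{ft.fsm_ms!r},{ft.tone_ms!r},{ft.t_done!r}\n")
        meta = {
            "mouse": self.mouse,
            "day": self.day,
            "group": self.group,
            "mode": self.mode,
            "trial_config": asdict(self.trial_config),
            "sonification_config": asdict(self.sonification_config),
            "calibration": asdict(self.calibration),
        }
        with open(out / "meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return out

    @classmethod
    def load(cls, session_dir: str | Path) -> "SessionRecord":
        d = Path(session_dir)
        with open(d / "meta.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        rec = cls(
            mouse=meta["mouse"],
            day=int(meta["day"]),
            group=meta["group"],
            mode=meta["mode"],
            trial_config=TrialConfig(**meta["trial_config"]),
            sonification_config=SonificationConfig(**meta["sonification_config"]),
            calibration=Calibration(**meta["calibration"]),
        )
        with open(d / "events.jsonl", encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    o = json.loads(line)
                    rec.events.append(TrialEvent(o["kind"], o["t"], o.get("payload", {})))
        with open(d / "kinematics.csv", encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                t, dl, dr, vl, vr = line.strip().split(",")
                rec.kinematics.append(
                    KinematicSample(float(t), float(dl), float(dr), bool(int(vl)), bool(int(vr)))
                )
        tones_path = d / "tones.jsonl"
        if tones_path.exists():
            with open(tones_path, encoding="utf-8") as fh:
                for line in fh:
                    if line.strip():
                        o = json.loads(line)
                        rec.tone_log.append(ToneCommand(o["t"], o["f_hz"], bool(o["active"])))
        timings_path = d / "timings.csv"
        if timings_path.exists():
            with open(timings_path, encoding="utf-8") as fh:
                next(fh)
                for line in fh:
                    vals = [float(v) for v in line.strip().split(",")]
                    rec.timings.append(FrameTiming(*vals))
        return rec


def run_session(
    source: Iterator[Tuple[float, PoseFrame]],
    calibration: Calibration,
    cfg: TrialConfig | None = None,
    soncfg: SonificationConfig | None = None,
    mode: str = "feedback",
    clock: Clock | None = None,
    stage_delays: StageDelays | None = None,
    mouse: str = "m0",
    day: int = 1,
    group: str | None = None,
) -> SessionRecord:
    """Drive the closed loop over a timed pose source.

    ``source`` yields ``(delivery_time, frame)`` (see
    :func:`sonoreach.clock.replay_source`); pass the *same* clock here and to
    the source so stage delays and latency share one timebase. In
    ``mode="control"`` the tone stage is skipped entirely - the event log and
    kinematics are identical to feedback mode on the same stream. Source
    exhaustion ends the session cleanly with ``session_end``.
    """
    if mode not in ("feedback", "control"):
        raise ValueError(f"mode must be 'feedback' or 'control', got {mode!r}")
    cfg = cfg or TrialConfig()
    soncfg = soncfg or SonificationConfig()
    delays = stage_delays or StageDelays()
    if clock is None:
        clock = SimulatedClock()
    rec = SessionRecord(
        mouse=mouse,
        day=day,
        group=group if group is not None else mode,
        mode=mode,
        trial_config=cfg,
        sonification_config=soncfg,
        calibration=calibration,
    )
    disp = DisplacementComputer(calibration, cfg)
    sm_left = MovingAverage(cfg.smooth_window)
    sm_right = MovingAverage(cfg.smooth_window)
    fsm = TrialFSM(cfg)
    advance = getattr(clock, "advance", None)
    first = True
    last_t = 0.0
    for t_delivered, frame in source:
        if first:
            rec.events.append(TrialEvent("session_start", frame.timestamp))
            rec.events.append(TrialEvent("led_on", frame.timestamp, {"on": True}))
            first = False
        if advance is not None and delays.acquire_ms:
            advance(delays.acquire_ms / 1e3)
        raw = disp.step(frame)
        sample = KinematicSample(
            raw.timestamp,
            sm_left.step(raw.disp_left),
            sm_right.step(raw.disp_right),
            raw.valid_left,
            raw.valid_right,
        )
        if advance is not None and delays.kinematics_ms:
            advance(delays.kinematics_ms / 1e3)
        rec.events.extend(fsm.step(sample))
        if advance is not None and delays.fsm_ms:
            advance(delays.fsm_ms / 1e3)
        tone_ms = 0.0
        if mode == "feedback":
            if advance is not None and delays.tone_ms:
                advance(delays.tone_ms / 1e3)
            tone_ms = delays.tone_ms
            freq = map_frequency(sample.disp_left, soncfg)
            active = sample.valid_left and sample.disp_left > 0
            rec.tone_log.append(ToneCommand(clock.now(), freq, active))
        t_done = clock.now()
        rec.timings.append(
            FrameTiming(
                frame.timestamp,
                t_delivered,
                delays.acquire_ms,
                delays.kinematics_ms,
                delays.fsm_ms,
                tone_ms,
                t_done,
            )
        )
        rec.kinematics.append(sample)
        last_t = frame.timestamp
    if not first:
        rec.events.append(TrialEvent("led_off", last_t, {"on": False}))
        rec.events.append(TrialEvent("session_end", last_t))
    return rec


def run_stream(
    stream: PoseStream,
    calibration: Calibration,
    cfg: TrialConfig | None = None,
    soncfg: SonificationConfig | None = None,
    mode: str = "feedback",
    speed: float = 1.0,
    stage_delays: StageDelays | None = None,
    **kwargs,
) -> SessionRecord:
    """Convenience wrapper: replay ``stream`` under a fresh simulated clock."""
    clock = SimulatedClock()
    source = replay_source(stream, clock, speed=speed)
    return run_session(
        source, calibration, cfg, soncfg, mode=mode, clock=clock,
        stage_delays=stage_delays, **kwargs,
    )


# ----------------------------------------------------------------------
# Latency instrumentation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EngineMetrics:
    n_frames: int
    duration_s: float
    loop_rate_hz: float
    mean_latency_ms: float
    max_latency_ms: float
    stage_means_ms: dict

    def to_dict(self) -> dict:
        return asdict(self)


def measure_latency(record: SessionRecord) -> EngineMetrics:
    """Per-frame end-to-end latency: pipeline-done time minus delivery time.

    Under a simulated clock with injected stage delays the reported latency
    equals the injected sum exactly.
    """
    if not record.timings:
        raise ValueError("record contains no frame timings")
    ft = record.timings
    lat = np.array([(f.t_done - f.t_delivered) * 1e3 for f in ft])
    t_frames = np.array([f.t_frame for f in ft])
    duration = float(t_frames[-1] - t_frames[0]) if len(ft) > 1 else 0.0
    rate = (len(ft) - 1) / duration if duration > 0 else math.inf
    stage_means = {
        "acquire_ms": float(np.mean([f.acquire_ms for f in ft])),
        "kinematics_ms": float(np.mean([f.kinematics_ms for f in ft])),
        "fsm_ms": float(np.mean([f.fsm_ms for f in ft])),
        "tone_ms": float(np.mean([f.tone_ms for f in ft])),
    }
    return EngineMetrics(
        n_frames=len(ft),
        duration_s=duration,
        loop_rate_hz=float(rate),
        mean_latency_ms=float(lat.mean()),
        max_latency_ms=float(lat.max()),
        stage_means_ms=stage_means,
    )
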