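"""Clocks and timed frame replay.

The real hardware loop is paced by a camera; here a :func:`replay_source`
paces frames from a stored stream by a clock. Under :class:`SimulatedClock`
delivery times are exactly reproducible, which makes the whole closed loop
deterministic and testable; :class:`WallClock` gives soft real-time replay.
"""

from __future__ import annotations

import time
from typing import Iterator, Protocol, Tuple

from .pose import PoseFrame, PoseStream

__all__ = ["Clock", "SimulatedClock", "WallClock", "replay_source"]


class Clock(Protocol):
    def now(self) -> float: ...

    def sleep_until(self, t: float) -> None: ...


class SimulatedClock:
    """A virtual clock: ``sleep_until`` jumps time forward instantly."""

    def __init__(self, start: float = 0.0) -> None:
        self._t = float(start)

    def now(self) -> float:
        return self._t

    def sleep_until(self, t: float) -> None:
        if t > self._t:
            self._t = t

    def advance(self, dt: float) -> None:
        if dt < 0:
            raise ValueError("cannot advance a clock backwards")
        self._t += dt


class WallClock:
    """Monotonic wall clock for soft real-time replay."""

    def __init__(self) -> None:
        self._origin = time.monotonic()

    def now(self) -> float:
        return time.monotonic() - self._origin

    def sleep_until(self, t: float) -> None:
        dt = t - self.now()
        if dt > 0:
            time.sleep(dt)

    def advance(self, dt: float) -> None:
        # Real time cannot be advanced; busy-wait instead.
        self.sleep_until(self.now() + dt)


def replay_source(
    stream: PoseStream, clock: Clock | None = None, speed: float = 1.0
) -> Iterator[Tuple[float, PoseFrame]]:
    """Yield ``(delivery_time, frame)`` pairs paced by ``clock``.

    Frames are delivered at inter-frame intervals of ``dt / speed`` where
    ``dt`` is the stored timestamp difference. With the default
    :class:`SimulatedClock` a stream recorded at 70 fps is delivered exactly
    at ``k / 70`` seconds.
    """
    if speed <= 0:
        raise ValueError("speed must be > 0")
    if clock is None:
        clock = SimulatedClock()
    t0 = clock.now()
    ts0: float | None = None
    for frame in stream:
        if ts0 is None:
            ts0 = frame.timestamp
        clock.sleep_until(t0 + (frame.timestamp - ts0) / speed)
        yield clock.now(), frame
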