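"""Independent brute-force oracles used across the test suite.

These deliberately re-derive expected behavior by different means than the
implementation (excursion scans instead of streaming state machines, cell
scans instead of vectorized validation) so agreement is informative.
"""

from __future__ import annotations

import numpy as np

from sonoreach.engine import TrialConfig


def count_successes_oracle(t, d, cfg: TrialConfig) -> int:
    """Count successful reaches by scanning maximal excursions.

    An excursion is a maximal run of samples above ``start_tolerance``. An
    excursion scores a success if the system is armed (previous trial fully
    reset) and its maximum crosses ``target_offset``. After a success the
    system rearms at the first below-tolerance sample at least ``refractory``
    seconds after the target crossing.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    above = d > cfg.start_tolerance
    n = d.size
    successes = 0
    armed = True
    success_t = -np.inf
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            seg = d[i : j + 1]
            if armed and seg.max() >= cfg.target_offset:
                successes += 1
                armed = False
                cross = i + int(np.argmax(seg >= cfg.target_offset))
                success_t = t[cross]
            i = j + 1
        else:
            if not armed and t[i] >= success_t + cfg.refractory:
                armed = True
            i += 1
    return successes


def random_displacement_sequence(rng: np.random.Generator, max_len: int = 200) -> np.ndarray:
    """A random displacement trace that wanders across all FSM thresholds."""
    n = rng.integers(5, max_len + 1)
    kind = rng.integers(3)
    if kind == 0:  # random walk
        d = np.clip(np.cumsum(rng.normal(0.0, 3.0, n)), 0.0, 30.0)
    elif kind == 1:  # independent spikes (stress single-sample transitions)
        d = rng.uniform(0.0, 22.0, n) * (rng.random(n) < 0.5)
    else:  # smooth bumps
        x = np.linspace(0, rng.uniform(2, 8) * np.pi, n)
        d = np.clip(18.0 * np.abs(np.sin(x)) + rng.normal(0, 1.0, n), 0.0, 30.0)
    return d


def scan_invalid_likelihood_cells(stream) -> set[tuple[int, str]]:
    """Brute-force cell scan: every (frame, bodypart) with likelihood outside [0, 1]."""
    bad = set()
    for frame in stream:
        for kp in frame.keypoints:
            if np.isfinite(kp.likelihood) and not (0.0 <= kp.likelihood <= 1.0):
                bad.add((frame.frame_index, kp.name))
    return bad
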