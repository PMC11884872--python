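"""Displacement-to-tone mapping, offline synthesis and audio validation.

The feedback tone encodes the left forepaw's vertical displacement as a pure
tone whose frequency is mapped linearly from the 2-20 kHz band: rest maps to
2 kHz, the target height (15 mm by default) to 20 kHz, and displacement is
clipped to that range. Synthesis is phase-continuous (a phase accumulator
carries across frequency changes) with raised-cosine on/off ramps so the
feedback contains no clicks.

Validation closes the loop offline: a short-time spectral peak track of the
rendered audio is compared against the commanded frequencies, and commanded
frequency is regressed on concurrent displacement (on a noise-free session
the two are exactly linearly related).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import signal, stats

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SessionRecord

__all__ = [
    "SonificationConfig",
    "ToneCommand",
    "CorrelationResult",
    "PeakTrack",
    "map_frequency",
    "synthesize",
    "write_wav",
    "spectrogram_peak_track",
    "track_command_match",
    "frequency_displacement_correlation",
]


@dataclass(frozen=True)
class SonificationConfig:
    """Parameters of the displacement -> frequency map and synthesis.

    f_min_khz / f_max_khz
        Tone band endpoints; defaults 2 and 20 kHz (speaker-rated band).
    d_max_mm
        Displacement mapped to ``f_max``; defaults to the 15 mm target height
        so reaching the target sounds the top of the band.
    amplitude
        Linear peak amplitude in (0, 1].
    sample_rate
        Output rate in Hz; must satisfy the Nyquist bound for ``f_max``.
    ramp_ms
        Raised-cosine on/off ramp length, milliseconds.
    """

    f_min_khz: float = 2.0
    f_max_khz: float = 20.0
    d_max_mm: float = 15.0
    amplitude: float = 0.5
    sample_rate: int = 44100
    ramp_ms: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.f_min_khz < self.f_max_khz):
            raise ValueError("need 0 < f_min < f_max")
        if self.d_max_mm <= 0:
            raise ValueError("d_max_mm must be > 0")
        if not (0 < self.amplitude <= 1):
            raise ValueError("amplitude must be in (0, 1]")
        if self.ramp_ms < 0:
            raise ValueError("ramp_ms must be >= 0")

    @property
    def f_min_hz(self) -> float:
        return self.f_min_khz * 1000.0

    @property
    def f_max_hz(self) -> float:
        return self.f_max_khz * 1000.0


@dataclass(frozen=True)
class ToneCommand:
    """One per-frame tone instruction from the real-time loop."""

    timestamp: float
    frequency: float
    active: bool


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r and OLS slope (with 95% CI) of frequency vs displacement.

    Both variables are normalized to their configured ranges (displacement by
    ``d_max``, frequency by the band width) so the slope is unitless and
    equals 1 for the exact linear map.
    """

    pearson_r: float
    slope: float
    slope_ci: tuple[float, float]
    n: int


def map_frequency(disp_mm: float, cfg: SonificationConfig | None = None) -> float:
    """Linear displacement -> frequency map, clipped to the band.

    ``disp <= 0`` maps to ``f_min``; ``disp >= d_max`` maps to ``f_max``.
    Returns Hz.
    """
    if cfg is None:
        cfg = SonificationConfig()
    u = min(max(disp_mm / cfg.d_max_mm, 0.0), 1.0)
    return cfg.f_min_hz + (cfg.f_max_hz - cfg.f_min_hz) * u


# ----------------------------------------------------------------------
# Synthesis
# ----------------------------------------------------------------------

def _envelope(active: np.ndarray, n_ramp: int) -> np.ndarray:
    """Smooth 0/1 gate with raised-cosine ramps of ``n_ramp`` samples."""
    env = active.astype(float)
    if n_ramp <= 1:
        return env
    kernel = np.hanning(n_ramp + 2)[1:-1]
    kernel /= kernel.sum()
    return signal.fftconvolve(env, kernel, mode="same")


def synthesize(
    commands: Sequence[ToneCommand],
    cfg: SonificationConfig | None = None,
    end_time: float | None = None,
) -> np.ndarray:
    """Render a command stream to a waveform (float64 in [-1, 1]).

    Each command's frequency holds until the next command; the waveform spans
    ``[0, end_time]`` (silence before the first command and over inactive
    spans). Phase is accumulated continuously so frequency steps cause no
    discontinuity; activity transitions are ramped.
    """
    if cfg is None:
        cfg = SonificationConfig()
    sr = cfg.sample_rate
    if sr < 2 * cfg.f_max_hz:
        raise ValueError(
            f"sample_rate {sr} Hz violates the Nyquist bound for f_max {cfg.f_max_hz:g} Hz"
        )
    if len(commands) == 0:
        n = int(round((end_time or 0.0) * sr))
        return np.zeros(n)
    times = np.array([c.timestamp for c in commands], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("tone commands must be time-ordered")
    freqs = np.array([c.frequency for c in commands], dtype=float)
    act = np.array([c.active for c in commands], dtype=bool)
    if end_time is None:
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0 / 70.0
        end_time = float(times[-1]) + dt
    n = int(round(end_time * sr))
    t = np.arange(n) / sr
    idx = np.searchsorted(times, t, side="right") - 1
    covered = idx >= 0
    idx = np.clip(idx, 0, len(commands) - 1)
    freq = freqs[idx]
    active = covered & act[idx]
    phase = np.cumsum(2.0 * np.pi * freq / sr)
    env = _envelope(active, int(round(cfg.ramp_ms / 1000.0 * sr)))
    return cfg.amplitude * np.sin(phase) * env


def write_wav(path, waveform: np.ndarray, cfg: SonificationConfig | None = None) -> None:
    """Write a waveform as 16-bit PCM mono WAV."""
    from scipy.io import wavfile

    if cfg is None:
        cfg = SonificationConfig()
    clipped = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, cfg.sample_rate, (clipped * 32767).astype(np.int16))


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PeakTrack:
    """Short-time spectral peak track: window centres, peak Hz, activity."""

    times: np.ndarray
    frequency: np.ndarray
    active: np.ndarray
    bin_hz: float


def spectrogram_peak_track(
    waveform: np.ndarray,
    cfg: SonificationConfig | None = None,
    nperseg: int = 512,
    activity_rel: float = 0.05,
) -> PeakTrack:
    """Track the dominant frequency per short-time window.

    Uses a Hann-window magnitude spectrogram (hop = ``nperseg / 2``) with
    parabolic interpolation around the peak bin. Windows whose peak magnitude
    falls below ``activity_rel`` times the loudest window are marked inactive
    (their frequency estimate is unreliable silence).
    """
    if cfg is None:
        cfg = SonificationConfig()
    w = np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise ValueError("waveform is empty")
    nperseg = min(nperseg, w.size)
    f, t, S = signal.spectrogram(
        w,
        fs=cfg.sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        mode="magnitude",
    )
    peak_idx = np.argmax(S, axis=0)
    cols = np.arange(S.shape[1])
    peak_mag = S[peak_idx, cols]
    active = peak_mag > activity_rel * max(peak_mag.max(), 1e-300)
    df = float(f[1] - f[0]) if len(f) > 1 else cfg.sample_rate / nperseg
    # Parabolic refinement on log-magnitude around the peak bin.
    freq = f[peak_idx].astype(float)
    interior = (peak_idx > 0) & (peak_idx < S.shape[0] - 1)
    ii = np.nonzero(interior)[0]
    if ii.size:
        eps = 1e-300
        a = np.log(S[peak_idx[ii] - 1, ii] + eps)
        b = np.log(S[peak_idx[ii], ii] + eps)
        c = np.log(S[peak_idx[ii] + 1, ii] + eps)
        denom = a - 2 * b + c
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (a - c) / np.where(denom == 0, 1, denom), 0.0)
        freq[ii] = freq[ii] + np.clip(shift, -0.5, 0.5) * df
    return PeakTrack(times=t, frequency=freq, active=active, bin_hz=df)


def track_command_match(
    track: PeakTrack, commands: Sequence[ToneCommand], window_s: float
) -> tuple[float, int]:
    """Fraction of active windows whose peak matches a commanded frequency.

    The command stream is piecewise constant (one command per camera frame),
    so a short-time window contains one or two commanded tones; the window's
    spectral peak should coincide - within one frequency bin - with one of
    the frequencies commanded during that window. Only windows lying fully
    inside active command spans are scored (on/off ramps and silence carry no
    commanded frequency). Returns ``(fraction_within_one_bin, n_windows)``.
    """
    tt = np.array([c.timestamp for c in commands], dtype=float)
    tf = np.array([c.frequency for c in commands], dtype=float)
    ta = np.array([c.active for c in commands], dtype=bool)
    if tt.size == 0:
        return 0.0, 0
    half = window_s / 2.0
    i0 = np.clip(np.searchsorted(tt, track.times - half, side="right") - 1, 0, tt.size - 1)
    i1 = np.clip(np.searchsorted(tt, track.times + half, side="right") - 1, 0, tt.size - 1)
    errs = []
    for w in range(len(track.times)):
        a, b = int(i0[w]), int(i1[w])
        if a > 0 and ta[a : b + 1].all():
            errs.append(float(np.min(np.abs(tf[a : b + 1] - track.frequency[w]))))
    if not errs:
        return 0.0, 0
    errs_arr = np.array(errs)
    return float(np.mean(errs_arr <= track.bin_hz)), int(errs_arr.size)


def frequency_displacement_correlation(
    record: "SessionRecord", cfg: SonificationConfig | None = None
) -> CorrelationResult:
    """Correlate commanded tone frequency with concurrent displacement.

    Pairs every active tone command with the kinematic sample nearest in time
    (within one frame period) and keeps only within-range pairs
    (``0 < disp < d_max``, where the map is strictly linear). Returns Pearson
    r and the normalized OLS slope with its 95% confidence interval.
    """
    if cfg is None:
        cfg = getattr(record, "sonification_config", None) or SonificationConfig()
    tones = [c for c in record.tone_log if c.active]
    if not tones:
        raise ValueError("no tone commands in record (control session?)")
    kt = np.array([s.timestamp for s in record.kinematics], dtype=float)
    kd = np.array([s.disp_left for s in record.kinematics], dtype=float)
    if kt.size < 2:
        raise ValueError("record has too few kinematic samples")
    period = float(np.median(np.diff(kt)))
    tt = np.array([c.timestamp for c in tones], dtype=float)
    tf = np.array([c.frequency for c in tones], dtype=float)
    j = np.clip(np.searchsorted(kt, tt), 0, kt.size - 1)
    j_prev = np.clip(j - 1, 0, kt.size - 1)
    use_prev = np.abs(kt[j_prev] - tt) <= np.abs(kt[j] - tt)
    j = np.where(use_prev, j_prev, j)
    close = np.abs(kt[j] - tt) <= period + 1e-12
    d = kd[j[close]]
    fhz = tf[close]
    unclipped = (d > 0) & (d < cfg.d_max_mm)
    d, fhz = d[unclipped], fhz[unclipped]
    if d.size < 3:
        raise ValueError(f"fewer than 3 within-range tone/displacement pairs (got {d.size})")
    x = d / cfg.d_max_mm
    y = (fhz - cfg.f_min_hz) / (cfg.f_max_hz - cfg.f_min_hz)
    lr = stats.linregress(x, y)
    half = stats.t.ppf(0.975, d.size - 2) * lr.stderr
    return CorrelationResult(
        pearson_r=float(lr.rvalue),
        slope=float(lr.slope),
        slope_ci=(float(lr.slope - half), float(lr.slope + half)),
        n=int(d.size),
    )
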