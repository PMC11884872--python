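"""Pose time-series containers and CSV I/O for markerless forepaw tracking.

The on-disk format is the three-header-row CSV dialect emitted by common
markerless pose-estimation toolchains: a ``scorer`` row, a ``bodyparts`` row
and a ``coords`` row (cycling ``x``, ``y``, ``likelihood`` per bodypart),
followed by one numeric row per video frame with the frame index in column 0.

Conventions
-----------
* Image coordinates: ``y`` increases downward. Downstream displacement is
  computed as ``rest_y - y`` so upward paw motion is positive.
* Missing or non-finite cells become keypoints with ``likelihood = 0`` rather
  than dropped frames, preserving the frame cadence the real-time loop needs.
* The dialect carries no time column; timestamps are synthesized as
  ``frame_index / fps``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DEFAULT_BODYPARTS",
    "Keypoint",
    "PoseFrame",
    "PoseStream",
    "Calibration",
    "PoseFormatError",
    "PoseValidationError",
    "read_pose_csv",
    "write_pose_csv",
]

#: Eight tracked digits: four per forepaw.
DEFAULT_BODYPARTS: tuple[str, ...] = tuple(
    f"{side}_digit{i}" for side in ("left", "right") for i in range(1, 5)
)


class PoseFormatError(ValueError):
    """Structural problem in a pose CSV (bad header, ragged row, ...)."""


class PoseValidationError(ValueError):
    """Cell-level validation failure (e.g. likelihood outside [0, 1])."""


@dataclass(frozen=True)
class Keypoint:
    """One tracked bodypart in one frame (pixel coordinates)."""

    name: str
    x: float
    y: float
    likelihood: float

    @property
    def missing(self) -> bool:
        return (
            self.likelihood == 0.0
            or not math.isfinite(self.x)
            or not math.isfinite(self.y)
        )


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-world calibration plus per-paw resting baselines.

    ``mm_per_pixel`` converts vertical pixel excursions to millimetres;
    ``rest_y_*`` are the resting-position y-coordinates (pixels) of each paw.
    """

    mm_per_pixel: float = 0.1
    rest_y_left: float = 400.0
    rest_y_right: float = 400.0

    def __post_init__(self) -> None:
        if not (self.mm_per_pixel > 0 and math.isfinite(self.mm_per_pixel)):
            raise ValueError("mm_per_pixel must be finite and > 0")
        if not (math.isfinite(self.rest_y_left) and math.isfinite(self.rest_y_right)):
            raise ValueError("rest positions must be finite")


class PoseFrame:
    """One timestamped frame; a lightweight view onto the stream arrays."""

    __slots__ = ("frame_index", "timestamp", "names", "x", "y", "likelihood")

    def __init__(
        self,
        frame_index: int,
        timestamp: float,
        names: Sequence[str],
        x: np.ndarray,
        y: np.ndarray,
        likelihood: np.ndarray,
    ) -> None:
        self.frame_index = int(frame_index)
        self.timestamp = float(timestamp)
        self.names = tuple(names)
        self.x = x
        self.y = y
        self.likelihood = likelihood

    @property
    def keypoints(self) -> tuple[Keypoint, ...]:
        return tuple(
            Keypoint(n, float(xi), float(yi), float(li))
            for n, xi, yi, li in zip(self.names, self.x, self.y, self.likelihood)
        )

    def keypoint(self, name: str) -> Keypoint:
        i = self.names.index(name)
        return Keypoint(name, float(self.x[i]), float(self.y[i]), float(self.likelihood[i]))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PoseFrame(frame_index={self.frame_index}, t={self.timestamp:.4f}, k={len(self.names)})"


class PoseStream:
    """A pose time series: identical keypoint set across frames.

    Stored as ``(n_frames, n_keypoints)`` arrays for x, y and likelihood;
    iteration yields :class:`PoseFrame` views.
    """

    def __init__(
        self,
        bodyparts: Sequence[str],
        x: np.ndarray,
        y: np.ndarray,
        likelihood: np.ndarray,
        frame_index: np.ndarray | None = None,
        fps: float = 70.0,
    ) -> None:
        self.bodyparts = tuple(bodyparts)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.likelihood = np.asarray(likelihood, dtype=float)
        k = len(self.bodyparts)
        n = self.x.shape[0] if self.x.ndim == 2 else 0
        for arr, nm in ((self.x, "x"), (self.y, "y"), (self.likelihood, "likelihood")):
            if arr.shape != (n, k):
                raise ValueError(f"{nm} must have shape (n_frames, {k}), got {arr.shape}")
        if fps <= 0:
            raise ValueError("fps must be > 0")
        self.fps = float(fps)
        if frame_index is None:
            frame_index = np.arange(n)
        self.frame_index = np.asarray(frame_index, dtype=int)
        if self.frame_index.shape != (n,):
            raise ValueError("frame_index must have one entry per frame")
        if n > 1 and not np.all(np.diff(self.frame_index) > 0):
            raise ValueError("frame_index must be strictly increasing")
        # Missing cells (non-finite coordinates) are flagged, never dropped.
        bad = ~(np.isfinite(self.x) & np.isfinite(self.y) & np.isfinite(self.likelihood))
        if bad.any():
            self.likelihood = self.likelihood.copy()
            self.likelihood[bad] = 0.0
        self._validate_likelihood()

    # ------------------------------------------------------------------
    @property
    def timestamps(self) -> np.ndarray:
        return self.frame_index / self.fps

    @property
    def n_keypoints(self) -> int:
        return len(self.bodyparts)

    def __len__(self) -> int:
        return self.x.shape[0]

    def frame(self, i: int) -> PoseFrame:
        return PoseFrame(
            self.frame_index[i],
            self.frame_index[i] / self.fps,
            self.bodyparts,
            self.x[i],
            self.y[i],
            self.likelihood[i],
        )

    def __iter__(self) -> Iterator[PoseFrame]:
        ts = self.timestamps
        for i in range(len(self)):
            yield PoseFrame(
                self.frame_index[i], ts[i], self.bodyparts, self.x[i], self.y[i], self.likelihood[i]
            )

    # ------------------------------------------------------------------
    def _validate_likelihood(self) -> None:
        finite = np.isfinite(self.likelihood)
        bad = finite & ((self.likelihood < 0) | (self.likelihood > 1))
        if bad.any():
            rows, cols = np.nonzero(bad)
            items = [
                f"frame {int(self.frame_index[r])} bodypart {self.bodyparts[c]} "
                f"likelihood {self.likelihood[r, c]:g}"
                for r, c in zip(rows[:20], cols[:20])
            ]
            more = "" if len(rows) <= 20 else f" (+{len(rows) - 20} more)"
            raise PoseValidationError(
                "likelihood outside [0, 1]: " + "; ".join(items) + more
            )


# ----------------------------------------------------------------------
# CSV I/O
# ----------------------------------------------------------------------

def _header_tag(row: list[str]) -> str:
    return row[0].strip().lower() if row else ""


def read_pose_csv(path: str | Path, fps: float = 70.0) -> PoseStream:
    """Read the 3-header-row pose CSV dialect.

    Raises :class:`PoseFormatError` on structural problems (naming the
    offending header row or data line) and :class:`PoseValidationError` when a
    likelihood cell falls outside [0, 1] (listing frame and bodypart).
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh)]
    if len(rows) < 3:
        raise PoseFormatError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    h_scorer, h_body, h_coords = rows[0], rows[1], rows[2]
    if _header_tag(h_body) == "individuals" or _header_tag(h_coords) == "individuals":
        raise PoseFormatError(
            f"{path}: multi-animal dialect ('individuals' header row) is not supported; "
            "expected the single-animal scorer/bodyparts/coords layout"
        )
    if _header_tag(h_scorer) != "scorer":
        raise PoseFormatError(f"{path}: header row 1 must start with 'scorer', got {h_scorer[:1]!r}")
    if _header_tag(h_body) != "bodyparts":
        raise PoseFormatError(f"{path}: header row 2 must start with 'bodyparts', got {h_body[:1]!r}")
    if _header_tag(h_coords) != "coords":
        raise PoseFormatError(f"{path}: header row 3 must start with 'coords', got {h_coords[:1]!r}")
    ncol = len(h_body)
    if len(h_scorer) != ncol or len(h_coords) != ncol:
        raise PoseFormatError(f"{path}: header rows have inconsistent column counts")
    if (ncol - 1) % 3 != 0 or ncol < 4:
        raise PoseFormatError(
            f"{path}: coords header must cycle x,y,likelihood per bodypart (got {ncol - 1} value columns)"
        )
    k = (ncol - 1) // 3
    bodyparts: list[str] = []
    for j in range(k):
        names = {h_body[1 + 3 * j + c] for c in range(3)}
        if len(names) != 1:
            raise PoseFormatError(
                f"{path}: bodyparts header row does not repeat each name three times near column {1 + 3 * j}"
            )
        coords = [h_coords[1 + 3 * j + c].strip().lower() for c in range(3)]
        if coords != ["x", "y", "likelihood"]:
            raise PoseFormatError(
                f"{path}: coords header row must cycle x,y,likelihood; got {coords} for bodypart {names.pop()!r}"
            )
        bodyparts.append(h_body[1 + 3 * j].strip())

    data = [(lineno, row) for lineno, row in enumerate(rows[3:], start=4) if any(c.strip() for c in row)]
    n = len(data)
    x = np.full((n, k), np.nan)
    y = np.full((n, k), np.nan)
    lik = np.zeros((n, k))
    frame_index = np.zeros(n, dtype=int)

    def parse(cell: str, lineno: int) -> float:
        cell = cell.strip()
        if cell == "" or cell.lower() in ("nan", "na"):
            return math.nan
        try:
            return float(cell)
        except ValueError:
            raise PoseFormatError(f"{path}: line {lineno}: non-numeric value {cell!r}") from None

    for i, (lineno, row) in enumerate(data):
        if len(row) != ncol:
            raise PoseFormatError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(row)}"
            )
        try:
            frame_index[i] = int(float(row[0]))
        except ValueError:
            raise PoseFormatError(f"{path}: line {lineno}: bad frame index {row[0]!r}") from None
        for j in range(k):
            x[i, j] = parse(row[1 + 3 * j], lineno)
            y[i, j] = parse(row[2 + 3 * j], lineno)
            lik[i, j] = parse(row[3 + 3 * j], lineno)
    lik[np.isnan(lik)] = 0.0
    return PoseStream(bodyparts, x, y, lik, frame_index=frame_index, fps=fps)


def write_pose_csv(stream: PoseStream, path: str | Path, scorer: str = "sonoreach") -> Path:
    """Write a stream in the 3-header-row dialect.

    ``read_pose_csv(write_pose_csv(s))`` reproduces every numeric field
    (floats are written with shortest round-trip representation). Refuses to
    write an empty stream, leaving no file behind.
    """
    if len(stream) == 0:
        raise ValueError("refusing to write an empty pose stream")
    path = Path(path)

    def fmt(v: float) -> str:
        return repr(float(v)) if math.isfinite(v) else ""

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["scorer"] + [scorer] * (3 * stream.n_keypoints))
        w.writerow(["bodyparts"] + [bp for bp in stream.bodyparts for _ in range(3)])
        w.writerow(["coords"] + ["x", "y", "likelihood"] * stream.n_keypoints)
        for i in range(len(stream)):
            row: list[str] = [str(int(stream.frame_index[i]))]
            for j in range(stream.n_keypoints):
                row += [fmt(stream.x[i, j]), fmt(stream.y[i, j]), fmt(stream.likelihood[i, j])]
            w.writerow(row)
    return path
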