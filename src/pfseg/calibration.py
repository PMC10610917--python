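"""Radiometric calibration and temperature windowing.

A radiometric thermal camera reports integer sensor counts, not temperatures.
Two black-body references at known set points (28 °C and 36 °C here) placed in
the field of view anchor an affine count-to-temperature map, fitted per frame
from the mean counts over each reference region.  Temperatures are then
rendered to grayscale through a fixed temperature window: a band of
``width_c`` degrees centred on ``center_c`` is mapped linearly onto [0, 1] and
everything outside is clipped.  Finally the calibration targets themselves are
cropped away so they cannot bias downstream image statistics.

Conventions: all pixel regions are 0-based, half-open ``[row0, row1) x
[col0, col1)`` rectangles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gamma import GrayscaleImage

__all__ = [
    "Rect",
    "RadiometricFrame",
    "BlackbodyReference",
    "TemperatureMap",
    "WindowSpec",
    "DegenerateCalibrationError",
    "CropFailureError",
    "calibrate_two_point",
    "temperature_to_grayscale",
    "grayscale_to_temperature",
    "crop_calibration_targets",
    "read_frame",
    "write_frame",
    "read_mask",
    "write_mask",
    "load_blackbody_sidecar",
    "save_blackbody_sidecar",
]

DEFAULT_BIT_DEPTH = 16
#: Black-body set points used throughout: a cool and a warm anchor in °C.
DEFAULT_SETPOINTS_C = (28.0, 36.0)
#: Default window: 10 °C wide, centred midway between the two set points.
DEFAULT_WINDOW_WIDTH_C = 10.0
DEFAULT_WINDOW_CENTER_C = 32.0


class DegenerateCalibrationError(ValueError):
    """The two reference regions have (numerically) identical mean counts."""


class CropFailureError(ValueError):
    """No non-empty rectangle avoids all calibration-target regions."""


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [row0, row1) x [col0, col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"empty or inverted rectangle: {self}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"negative rectangle origin: {self}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    def inside(self, height: int, width: int) -> bool:
        return self.row1 <= height and self.col1 <= width

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def intersects(self, other: "Rect") -> bool:
        return not (
            self.row1 <= other.row0
            or other.row1 <= self.row0
            or self.col1 <= other.col0
            or other.col1 <= self.col0
        )


@dataclass(frozen=True)
class RadiometricFrame:
    """Raw sensor counts from a single thermal exposure."""

    counts: np.ndarray
    bit_depth: int = DEFAULT_BIT_DEPTH

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.size == 0:
            raise ValueError("counts must be a non-empty 2-D array")
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be integer-typed")
        if c.min() < 0 or c.max() >= 2 ** self.bit_depth:
            raise ValueError(f"counts out of range for {self.bit_depth}-bit ADC")
        object.__setattr__(self, "counts", c)

    @property
    def height(self) -> int:
        return self.counts.shape[0]

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class BlackbodyReference:
    """A controlled-temperature patch in the field of view."""

    region: Rect
    setpoint_c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.setpoint_c <= 60.0):
            raise ValueError("setpoint outside the plausible 0-60 °C band")


@dataclass(frozen=True)
class TemperatureMap:
    """Per-pixel temperatures in °C."""

    temp_c: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temp_c, dtype=np.float64)
        if t.ndim != 2 or t.size == 0:
            raise ValueError("temp_c must be a non-empty 2-D array")
        if not np.all(np.isfinite(t)):
            raise ValueError("temperatures must be finite")
        object.__setattr__(self, "temp_c", t)


@dataclass(frozen=True)
class WindowSpec:
    """Fixed temperature window mapped linearly onto [0, 1]."""

    center_c: float = DEFAULT_WINDOW_CENTER_C
    width_c: float = DEFAULT_WINDOW_WIDTH_C

    def __post_init__(self) -> None:
        if self.width_c <= 0:
            raise ValueError("window width must be positive")

    @property
    def low_c(self) -> float:
        return self.center_c - self.width_c / 2.0

    @property
    def high_c(self) -> float:
        return self.center_c + self.width_c / 2.0


def _region_statistic(frame: RadiometricFrame, ref: BlackbodyReference, statistic: str) -> float:
    if not ref.region.inside(frame.height, frame.width):
        raise IndexError(f"black-body region {ref.region} outside {frame.height}x{frame.width} frame")
    patch = frame.counts[ref.region.slices()].astype(np.float64)
    if statistic == "mean":
        return float(patch.mean())
    if statistic == "median":
        return float(np.median(patch))
    raise ValueError(f"unknown statistic {statistic!r}")


def calibrate_two_point(
    frame: RadiometricFrame,
    bb_low: BlackbodyReference,
    bb_high: BlackbodyReference,
    statistic: str = "mean",
) -> TemperatureMap:
    """Affine count-to-temperature conversion anchored on two references.

    The affine map is the unique line through (mean counts of the low region,
    low set point) and (mean counts of the high region, high set point),
    applied pixelwise.  ``statistic`` may be ``"median"`` for robustness to
    outlier pixels inside a reference patch.
    """
    if not bb_low.setpoint_c < bb_high.setpoint_c:
        raise ValueError("bb_low must have the lower set point")
    c_low = _region_statistic(frame, bb_low, statistic)
    c_high = _region_statistic(frame, bb_high, statistic)
    if np.isclose(c_low, c_high):
        raise DegenerateCalibrationError(
            f"reference regions have identical {statistic} counts ({c_low:.3f})"
        )
    slope = (bb_high.setpoint_c - bb_low.setpoint_c) / (c_high - c_low)
    temp = bb_low.setpoint_c + slope * (frame.counts.astype(np.float64) - c_low)
    return TemperatureMap(temp)


def temperature_to_grayscale(tmap: TemperatureMap, window: WindowSpec = WindowSpec()) -> GrayscaleImage:
    """Linear window map ``v = (T - low) / width`` clipped to [0, 1]."""
    v = (tmap.temp_c - window.low_c) / window.width_c
    return GrayscaleImage(np.clip(v, 0.0, 1.0), provenance="raw-windowed")


def grayscale_to_temperature(img: GrayscaleImage, window: WindowSpec = WindowSpec()) -> TemperatureMap:
    """Inverse of the window map; exact for temperatures inside the window."""
    return TemperatureMap(img.values * window.width_c + window.low_c)


def _largest_empty_rect(height: int, width: int, obstacles: list[Rect]) -> Rect | None:
    """Exhaustive maximal empty rectangle over obstacle-edge candidates.

    The optimum is bounded by obstacle edges or the frame border on every
    side, so scanning all candidate edge 4-tuples is exact.  Obstacle counts
    here are tiny (a handful of calibration patches), keeping this cheap.
    """
    rows = sorted({0, height} | {r.row0 for r in obstacles} | {r.row1 for r in obstacles})
    cols = sorted({0, width} | {c.col0 for c in obstacles} | {c.col1 for c in obstacles})
    rows = [r for r in rows if 0 <= r <= height]
    cols = [c for c in cols if 0 <= c <= width]
    best: Rect | None = None
    best_area = 0
    for i, r0 in enumerate(rows):
        for r1 in rows[i + 1:]:
            for j, c0 in enumerate(cols):
                for c1 in cols[j + 1:]:
                    cand = Rect(r0, r1, c0, c1)
                    if any(cand.intersects(o) for o in obstacles):
                        continue
                    area = cand.height * cand.width
                    # deterministic tie-break: larger area, then upper, then left
                    if area > best_area or (
                        area == best_area
                        and best is not None
                        and (cand.row0, cand.col0) < (best.row0, best.col0)
                    ):
                        best, best_area = cand, area
    return best


def crop_calibration_targets(img: GrayscaleImage, regions: list[Rect]) -> GrayscaleImage:
    """Largest axis-aligned sub-image containing no calibration region.

    With references mounted at the frame margins this returns the central
    strip between them.  An empty region list returns the image unchanged.
    """
    if not regions:
        return img
    h, w = img.shape
    clipped = []
    for r in regions:
        rr = Rect(max(r.row0, 0), min(r.row1, h), max(r.col0, 0), min(r.col1, w))
        clipped.append(rr)
    best = _largest_empty_rect(h, w, clipped)
    if best is None:
        raise CropFailureError("calibration regions cover the whole frame")
    return GrayscaleImage(img.values[best.slices()], provenance=img.provenance)


# --------------------------------------------------------------------------
# File I/O: 16-bit TIFF/PNG frames, 8-bit PNG masks, JSON sidecars
# --------------------------------------------------------------------------

def read_frame(path: str | Path, bit_depth: int = DEFAULT_BIT_DEPTH) -> RadiometricFrame:
    """Read a 16-bit grayscale TIFF or PNG as a radiometric frame."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        counts = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        counts = iio.imread(path)
    counts = np.asarray(counts)
    if counts.ndim == 3:  # tolerate single-channel images stored with a channel axis
        counts = counts[..., 0]
    return RadiometricFrame(counts.astype(np.uint16), bit_depth=bit_depth)


def write_frame(path: str | Path, frame: RadiometricFrame) -> None:
    path = Path(path)
    data = frame.counts.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG mask as a boolean array (nonzero = foreground)."""
    import imageio.v3 as iio

    m = np.asarray(iio.imread(Path(path)))
    if m.ndim == 3:
        m = m[..., 0]
    return m > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def save_blackbody_sidecar(path: str | Path, refs: list[BlackbodyReference]) -> None:
    payload = [
        {
            "row0": r.region.row0,
            "row1": r.region.row1,
            "col0": r.region.col0,
            "col1": r.region.col1,
            "setpoint_c": r.setpoint_c,
        }
        for r in refs
    ]
    Path(path).write_text(json.dumps({"blackbodies": payload}, indent=2))


def load_blackbody_sidecar(path: str | Path) -> list[BlackbodyReference]:
    payload = json.loads(Path(path).read_text())
    return [
        BlackbodyReference(
            region=Rect(d["row0"], d["row1"], d["col0"], d["col1"]),
            setpoint_c=float(d["setpoint_c"]),
        )
        for d in payload["blackbodies"]
    ]
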