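"""Image-derived biofilm statistics.

Two assay read-outs are computed from photographs:

* the *settling ratio* — the fraction of a culture tube cleared of cells,
  measured from an intensity plot-profile along a line drawn from the
  meniscus to the bottom of the tube; and
* the *background-corrected invasion intensity* — the mean gray level of a
  washed agar-invasion spot minus the mean background level of the plate,
  clamped at zero.

Images are held as 2-D float grids on the 8-bit gray scale [0, 255] with
pixel (0, 0) at the top-left, x increasing rightward and y downward.
Annotations (profile lines, spot ROIs) are inputs; no automatic detection
is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import map_coordinates

from .exceptions import FormatError, GeometryError, ValidationError

#: ITU-R BT.709 luminance weights used for color-to-gray conversion.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class GrayImage:
    """Single-channel image with intensities on [0, 255].

    ``pixels`` is indexed ``[y, x]`` (row-major, origin top-left).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise FormatError("GrayImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite values")
        if px.min() < 0 or px.max() > 255:
            raise ValidationError("image intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def inverted(self) -> "GrayImage":
        """Contrast-flipped copy (255 - value), for opposite-polarity photos."""
        return GrayImage(255.0 - self.pixels)


def to_grayscale(image: np.ndarray) -> GrayImage:
    """Convert a 1- or 3-channel image to a :class:`GrayImage`.

    Color images are collapsed with fixed luminance weights
    (0.2126 R + 0.7152 G + 0.0722 B); already-grayscale input is passed
    through unchanged (values clipped to [0, 255]).
    """
    arr = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("image contains non-finite values")
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr @ LUMA_WEIGHTS
    elif arr.ndim == 3 and arr.shape[2] == 1:
        gray = arr[:, :, 0]
    else:
        raise FormatError(
            f"unsupported channel layout {arr.shape}; expected 2-D or HxWx3"
        )
    return GrayImage(np.clip(gray, 0.0, 255.0))


def load_image(path: str | Path, invert: bool = False) -> GrayImage:
    """Read a PNG/TIFF/JPEG photograph as a gray image.

    16-bit images are rescaled onto [0, 255]; RGB(A) images are converted
    with the fixed luminance weights. ``invert`` flips contrast for
    photographs in which the dense region is dark rather than bright.
    """
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    arr = arr.astype(float)
    if arr.max() > 255:  # 16-bit source
        arr = arr * (255.0 / 65535.0)
    img = to_grayscale(arr)
    return img.inverted() if invert else img


def save_image(image: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF (values rounded to integers)."""
    iio.imwrite(Path(path), np.round(image.pixels).astype(np.uint8))


# ---------------------------------------------------------------------------
# Settling (flocculation) quantification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileLine:
    """Line annotation from the meniscus end (start) to the tube bottom (end)."""

    start: tuple[float, float]
    end: tuple[float, float]
    sampling_step_px: float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_step_px <= 0:
            raise ValidationError("sampling_step_px must be positive")
        if self.length == 0:
            raise ValidationError("profile line must have nonzero length")

    @property
    def length(self) -> float:
        (x0, y0), (x1, y1) = self.start, self.end
        return float(np.hypot(x1 - x0, y1 - y0))


@dataclass(frozen=True)
class IntensityProfile:
    """Intensities sampled along a line, with distances from the start point."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.size == 0:
            raise ValidationError("empty profile")
        if pos.size != val.size:
            raise ValidationError("positions and values differ in length")
        if pos[0] != 0 or np.any(np.diff(pos) <= 0):
            raise ValidationError("positions must ascend strictly from 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    @property
    def max_gray(self) -> float:
        return float(self.values.max())

    @property
    def length(self) -> float:
        return float(self.positions[-1])


@dataclass(frozen=True)
class TubeMeasurement:
    """Settling measurement: per-line cleared fractions and their mean."""

    per_line_ratios: tuple[float, ...]

    @property
    def ratio(self) -> float:
        return float(np.mean(self.per_line_ratios))


def extract_profile(image: GrayImage, line: ProfileLine) -> IntensityProfile:
    """Sample the image along a line with bilinear interpolation.

    Samples are evenly spaced from the start to the end point; spacing is
    as close to ``sampling_step_px`` as divides the line length evenly, so
    both endpoints are always included.
    """
    for name, (x, y) in (("start", line.start), ("end", line.end)):
        if not (0 <= x <= image.width - 1 and 0 <= y <= image.height - 1):
            raise GeometryError(f"line {name} point {(x, y)} outside image")
    n_steps = max(1, int(round(line.length / line.sampling_step_px)))
    t = np.linspace(0.0, 1.0, n_steps + 1)
    (x0, y0), (x1, y1) = line.start, line.end
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    values = map_coordinates(image.pixels, [ys, xs], order=1, mode="nearest")
    return IntensityProfile(positions=t * line.length, values=values)


def settling_ratio(profile: IntensityProfile) -> float:
    """Cleared fraction of a tube from one intensity plot-profile.

    Scanning from the meniscus end, the first sampled position whose gray
    value reaches half of the profile maximum marks the boundary between
    cleared supernatant (low gray) and the settled, dense region (high
    gray). The returned ratio is that distance divided by the line length.
    A profile that is zero everywhere carries no signal; it yields 0 with
    a warning.
    """
    if profile.max_gray == 0:
        warnings.warn("all-zero profile: no cells visible, ratio set to 0")
        return 0.0
    half = profile.max_gray / 2.0
    idx = int(np.argmax(profile.values >= half))
    return float(profile.positions[idx] / profile.length)


def settling_score(
    image: GrayImage, lines: Sequence[ProfileLine], invert: bool = False
) -> TubeMeasurement:
    """Average settling ratio across plot-profile lines (typically three)."""
    if len(lines) == 0:
        raise ValidationError("at least one profile line is required")
    img = image.inverted() if invert else image
    ratios = tuple(settling_ratio(extract_profile(img, ln)) for ln in lines)
    return TubeMeasurement(per_line_ratios=ratios)


# ---------------------------------------------------------------------------
# Agar-invasion quantification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpotROI:
    """Region of interest covering one invaded spot.

    Either a circle (center + radius; a pixel belongs if its center is
    within the radius) or an explicit boolean mask.
    """

    center: tuple[float, float] | None = None
    radius: float | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        circle = self.center is not None and self.radius is not None
        if circle == (self.mask is not None):
            raise ValidationError("specify either center+radius or a mask")
        if circle and self.radius <= 0:
            raise ValidationError("radius must be positive")

    def mask_for(self, image: GrayImage) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != image.pixels.shape:
                raise GeometryError("mask shape does not match image")
            return m
        cx, cy = self.center
        if not (
            cx - self.radius >= 0
            and cx + self.radius <= image.width - 1
            and cy - self.radius >= 0
            and cy + self.radius <= image.height - 1
        ):
            raise GeometryError("circular ROI extends outside the image")
        yy, xx = np.mgrid[0 : image.height, 0 : image.width]
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius**2


@dataclass(frozen=True)
class InvasionMeasurement:
    """One spot's background-corrected intensity and its components.

    ``background = (A_t * I_t - A_s * I_s) / (A_t - A_s)`` where ``A_t`` /
    ``I_t`` are the area and mean gray of the whole image and ``A_s`` /
    ``I_s`` those of the spot ROI; algebraically this is the mean gray of
    the pixels outside the ROI. ``corrected`` clamps negative values to 0.
    """

    area_total: int
    mean_total: float
    area_spot: int
    mean_spot: float

    @property
    def background(self) -> float:
        return (
            self.area_total * self.mean_total - self.area_spot * self.mean_spot
        ) / (self.area_total - self.area_spot)

    @property
    def raw_corrected(self) -> float:
        return self.mean_spot - self.background

    @property
    def corrected(self) -> float:
        return max(0.0, self.raw_corrected)


def measure_spot(image: GrayImage, roi: SpotROI) -> InvasionMeasurement:
    """Measure one invaded spot against the whole-image background."""
    mask = roi.mask_for(image)
    area_spot = int(mask.sum())
    if area_spot < 1:
        raise ValidationError("ROI contains no pixels")
    area_total = image.pixels.size
    if area_spot >= area_total:
        raise ValidationError("ROI must be strictly smaller than the image")
    return InvasionMeasurement(
        area_total=area_total,
        mean_total=float(image.pixels.mean()),
        area_spot=area_spot,
        mean_spot=float(image.pixels[mask].mean()),
    )


def invasion_score(measurements: Iterable[InvasionMeasurement]) -> float:
    """Mean corrected intensity across replicate spot images (typically 3)."""
    vals = [m.corrected for m in measurements]
    if not vals:
        raise ValidationError("at least one measurement is required")
    return float(np.mean(vals))
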