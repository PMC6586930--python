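"""Calibrated image containers, TIFF I/O, ROI handling and unit conversion.

All geometry in the package is expressed through :class:`CalibratedImage`,
a plain 2-D intensity grid tagged with the physical edge length of one
pixel in micrometres.  Coordinates are 0-based ``(row, col)`` with
half-open extents throughout.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "CalibratedImage",
    "TwoChannelImage",
    "ROI",
    "load_two_channel_tiff",
    "write_two_channel_tiff",
    "crop_roi",
    "um2_to_px_area",
    "um_to_px",
]


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D fluorescence intensity grid with physical pixel calibration.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities (arbitrary fluorescence units).  Loaded
        images are non-negative; background-subtracted derivatives may
        carry negative values and are handled explicitly downstream.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres; must be > 0.
    bit_depth : int
        Nominal acquisition depth (8 or 16).  Informational only once
        pixels are in memory.
    """

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={px.ndim}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"image extents must be positive, got {px.shape}")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, pixel_size_um: float | None = None) -> "CalibratedImage":
        """Return a copy carrying new pixel data (same calibration unless given)."""
        return CalibratedImage(
            pixels=pixels,
            pixel_size_um=self.pixel_size_um if pixel_size_um is None else pixel_size_um,
            bit_depth=self.bit_depth,
        )


@dataclass(frozen=True)
class TwoChannelImage:
    """Marker channel (compartment identity) + protein channel (quantified)."""

    marker: CalibratedImage
    protein: CalibratedImage

    def __post_init__(self) -> None:
        if self.marker.shape != self.protein.shape:
            raise ValueError(
                f"channel shapes differ: marker {self.marker.shape} vs protein {self.protein.shape}"
            )
        if self.marker.pixel_size_um != self.protein.pixel_size_um:
            raise ValueError("channels must share pixel_size_um")

    @property
    def shape(self) -> tuple[int, int]:
        return self.marker.shape

    @property
    def pixel_size_um(self) -> float:
        return self.marker.pixel_size_um


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangular region of interest (default 300 x 300 px).

    0-based origin, half-open extents: rows ``origin_row .. origin_row +
    height_px - 1`` inclusive.
    """

    origin_row: int = 0
    origin_col: int = 0
    height_px: int = 300
    width_px: int = 300

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("ROI extents must be positive")
        if self.origin_row < 0 or self.origin_col < 0:
            raise ValueError("ROI origin must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def validate_within(self, image_shape: tuple[int, int]) -> None:
        if (
            self.origin_row + self.height_px > image_shape[0]
            or self.origin_col + self.width_px > image_shape[1]
        ):
            raise ValueError(
                f"ROI {self} exceeds image bounds {image_shape}; refusing to clip silently"
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ROI":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            origin_row=int(d["origin_row"]),
            origin_col=int(d["origin_col"]),
            height_px=int(d["height_px"]),
            width_px=int(d["width_px"]),
        )


def _bit_depth_of(arr: np.ndarray) -> int:
    return 8 if arr.dtype == np.uint8 else 16


def _extract_plane(stack: np.ndarray, index: int, what: str) -> np.ndarray:
    """Pull one channel plane out of a TIFF array.

    Accepts plane-first stacks ``(N, H, W)`` (multi-page TIFF) and
    channel-last ``(H, W, C)`` arrays with a small trailing channel axis.
    """
    if stack.ndim == 2:
        raise ValueError(
            f"single-plane TIFF has no channel {index} for the {what} channel; "
            "a two-channel image is required"
        )
    if stack.ndim != 3:
        raise ValueError(f"unsupported TIFF dimensionality {stack.shape}")
    # Heuristic: a genuine channel axis is short; image axes are not.
    if stack.shape[-1] <= 4 < stack.shape[0]:
        stack = np.moveaxis(stack, -1, 0)
    n = stack.shape[0]
    if not (0 <= index < n):
        raise ValueError(f"{what} channel index {index} out of range for {n}-plane TIFF")
    return stack[index]


def load_two_channel_tiff(
    path: str | os.PathLike,
    marker_index: int,
    protein_index: int,
    pixel_size_um: float,
) -> TwoChannelImage:
    """Read a dual-channel TIFF, selecting marker and protein planes by index.

    Calibration comes from the caller (the plugin dialog asks the user for
    pixel size); TIFF resolution metadata, when present and conflicting,
    only triggers a logged warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    if not (pixel_size_um > 0):
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    if marker_index == protein_index:
        raise ValueError("marker and protein channel indices must be distinct")
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        res = tf.pages[0].tags.get("XResolution")
    if res is not None:
        num, den = res.value
        # num == den (resolution 1) is the writer default, not a calibration
        if num > 0 and den > 0 and num != den:
            # TIFF XResolution is pixels per unit; only sanity-check, never override.
            meta_px = den / num
            if abs(meta_px - pixel_size_um) / pixel_size_um > 1e-3:
                logger.warning(
                    "TIFF metadata pixel size %.4g differs from supplied %.4g um/px; "
                    "using the supplied value",
                    meta_px,
                    pixel_size_um,
                )
    marker = _extract_plane(stack, marker_index, "marker")
    protein = _extract_plane(stack, protein_index, "protein")
    if np.min(marker) < 0 or np.min(protein) < 0:
        raise ValueError("loaded intensities must be non-negative")
    depth = _bit_depth_of(marker)
    return TwoChannelImage(
        marker=CalibratedImage(marker, pixel_size_um, depth),
        protein=CalibratedImage(protein, pixel_size_um, _bit_depth_of(protein)),
    )


def write_two_channel_tiff(path: str | os.PathLike, image: TwoChannelImage) -> None:
    """Write marker + protein as a two-page TIFF (marker first), bit-exact."""
    tifffile.imwrite(path, np.stack([image.marker.pixels, image.protein.pixels]))


def crop_roi(image: CalibratedImage, roi: ROI) -> CalibratedImage:
    """Extract the ROI sub-image; calibration unchanged, no silent clipping."""
    roi.validate_within(image.shape)
    sub = image.pixels[
        roi.origin_row : roi.origin_row + roi.height_px,
        roi.origin_col : roi.origin_col + roi.width_px,
    ].copy()
    return image.with_pixels(sub)


def um2_to_px_area(area_um2: float, pixel_size_um: float) -> float:
    """Convert a physical area in um^2 to a (real-valued) pixel count."""
    if not (area_um2 > 0):
        raise ValueError(f"area_um2 must be > 0, got {area_um2}")
    if not (pixel_size_um > 0):
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return area_um2 / (pixel_size_um * pixel_size_um)


def um_to_px(length_um: float, pixel_size_um: float) -> float:
    """Convert a physical length in um to pixels."""
    if not (pixel_size_um > 0):
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return length_um / pixel_size_um
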