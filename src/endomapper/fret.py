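"""Ratiometric FRET-biosensor quantification (YFP-FRET emission / CFP emission).

The biosensor reports GTPase activation as the per-pixel ratio of
sensitized (YFP, 530 nm) to donor (CFP, 480 nm) emission after
subtracting, per channel, the mean of a user-drawn background region
outside the cell.  Summaries are reported over the whole cell, over a
narrow band at the cell periphery (default 1.67 um, approximating the
plasma membrane) and over marker-segmented endomembrane compartments.
Optional block binning (2x2, 3x3) trades resolution for signal on dim
compartments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .image_io import CalibratedImage
from .segmentation import LabeledCompartments

__all__ = [
    "FretInput",
    "RatioMap",
    "subtract_background",
    "bin_image",
    "bin_mask",
    "fret_ratio_map",
    "edge_band_mask",
    "region_mean_ratio",
]

DEFAULT_EDGE_BAND_UM = 1.67


@dataclass(frozen=True)
class FretInput:
    """Donor/acceptor channels plus the masks needed to quantify them.

    cfp, yfp : CFP-emission and FRET(YFP)-emission channels, same geometry.
    cell_mask : boolean grid, True inside the manually segmented cell.
    background_region : boolean grid, True over a region outside the cell
        used for per-channel background estimation; must be disjoint from
        the cell mask and non-empty.
    bin_factor : integer >= 1 block-binning factor applied before ratioing.
    edge_band_um : width of the cell-periphery band (default 1.67 um).
    """

    cfp: CalibratedImage
    yfp: CalibratedImage
    cell_mask: np.ndarray
    background_region: np.ndarray
    bin_factor: int = 1
    edge_band_um: float = DEFAULT_EDGE_BAND_UM

    def __post_init__(self) -> None:
        cm = np.asarray(self.cell_mask, dtype=bool)
        bg = np.asarray(self.background_region, dtype=bool)
        if self.cfp.shape != self.yfp.shape:
            raise ValueError("cfp and yfp must share geometry")
        if self.cfp.pixel_size_um != self.yfp.pixel_size_um:
            raise ValueError("cfp and yfp must share pixel_size_um")
        if cm.shape != self.cfp.shape or bg.shape != self.cfp.shape:
            raise ValueError("masks must share the channel geometry")
        if np.any(cm & bg):
            raise ValueError("background region must be disjoint from the cell mask")
        if not bg.any():
            raise ValueError("background region is empty")
        if int(self.bin_factor) < 1:
            raise ValueError("bin_factor must be >= 1")
        if not (self.edge_band_um > 0):
            raise ValueError("edge_band_um must be > 0")
        object.__setattr__(self, "cell_mask", cm)
        object.__setattr__(self, "background_region", bg)


@dataclass(frozen=True)
class RatioMap:
    """Per-pixel YFP/CFP ratio with a validity mask.

    ratio holds NaN where invalid; valid pixels have a strictly positive
    background-subtracted CFP denominator and lie inside the cell mask.
    """

    ratio: np.ndarray
    valid_mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.ratio.shape != self.valid_mask.shape:
            raise ValueError("ratio and valid_mask must share geometry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ratio.shape  # type: ignore[return-value]


def subtract_background(
    channel: CalibratedImage, background_region: np.ndarray
) -> CalibratedImage:
    """Subtract the background region's mean intensity from every pixel.

    Results may go negative; they are flagged downstream (a non-positive
    CFP denominator invalidates the pixel), never clamped.
    """
    bg = np.asarray(background_region, dtype=bool)
    if bg.shape != channel.shape:
        raise ValueError("background region must share the channel geometry")
    if not bg.any():
        raise ValueError("background region is empty")
    level = float(np.asarray(channel.pixels, dtype=float)[bg].mean())
    return channel.with_pixels(np.asarray(channel.pixels, dtype=float) - level)


def _block_reduce_mean(px: np.ndarray, factor: int) -> np.ndarray:
    h = (px.shape[0] // factor) * factor
    w = (px.shape[1] // factor) * factor
    if h == 0 or w == 0:
        raise ValueError(f"image {px.shape} too small for bin factor {factor}")
    trimmed = px[:h, :w]
    return trimmed.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def bin_image(channel: CalibratedImage, factor: int) -> CalibratedImage:
    """Reduce non-overlapping factor x factor blocks to their mean.

    Trailing rows/cols that do not fill a block are dropped; the pixel
    size is multiplied by the factor.  Factor 1 is the identity.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return channel
    out = _block_reduce_mean(np.asarray(channel.pixels, dtype=float), factor)
    return channel.with_pixels(out, pixel_size_um=channel.pixel_size_um * factor)


def bin_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Bin a boolean mask: a block belongs to the mask if the majority of
    its pixels do (block mean > 0.5)."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return np.asarray(mask, dtype=bool)
    return _block_reduce_mean(np.asarray(mask, dtype=float), factor) > 0.5


def fret_ratio_map(inp: FretInput) -> RatioMap:
    """Background-subtract both channels, bin, and ratio YFP/CFP per pixel.

    Pixels outside the (binned) cell mask or with CFP <= eps are invalid,
    where eps defaults to 1e-6 of the background-subtracted CFP maximum.
    """
    cfp = subtract_background(inp.cfp, inp.background_region)
    yfp = subtract_background(inp.yfp, inp.background_region)
    cfp = bin_image(cfp, inp.bin_factor)
    yfp = bin_image(yfp, inp.bin_factor)
    cell = bin_mask(inp.cell_mask, inp.bin_factor)
    cfp_px = np.asarray(cfp.pixels, dtype=float)
    yfp_px = np.asarray(yfp.pixels, dtype=float)
    cmax = float(cfp_px.max())
    if cmax <= 0:
        raise ValueError(
            "no positive CFP signal after background subtraction; ratio undefined everywhere"
        )
    eps = 1e-6 * cmax
    valid = cell & (cfp_px > eps)
    if not valid.any():
        raise ValueError(
            "every pixel is invalid (outside the cell mask or CFP below floor); "
            "check masks and background region"
        )
    ratio = np.full(cfp_px.shape, np.nan)
    ratio[valid] = yfp_px[valid] / cfp_px[valid]
    return RatioMap(ratio=ratio, valid_mask=valid, pixel_size_um=cfp.pixel_size_um)


def edge_band_mask(
    cell_mask: np.ndarray, band_um: float, pixel_size_um: float
) -> np.ndarray:
    """Band of given physical width at the cell periphery.

    The band is the cell mask minus its erosion by a disk of radius
    ``round(band_um / pixel_size_um)`` pixels, so band and eroded interior
    partition the cell exactly.  A width rounding to zero pixels is
    rejected (the band would be empty at this sampling).
    """
    cm = np.asarray(cell_mask, dtype=bool)
    if not cm.any():
        raise ValueError("cell mask is empty")
    if not (band_um > 0):
        raise ValueError("band_um must be > 0")
    width = int(round(band_um / pixel_size_um))
    if width < 1:
        raise ValueError(
            f"band width {band_um} um rounds to 0 px at {pixel_size_um} um/px; "
            "use a smaller pixel size (less binning) to resolve the band"
        )
    interior = morphology.erosion(cm, morphology.disk(width))
    return cm & ~interior


def region_mean_ratio(
    ratio_map: RatioMap,
    region: np.ndarray | LabeledCompartments,
) -> float | None | list[float | None]:
    """Mean ratio over the valid pixels of a region.

    A boolean mask yields one value (None when the region holds no valid
    pixel); a labeled-compartment map yields one value per label.
    """
    if isinstance(region, LabeledCompartments):
        if region.label_map.shape != ratio_map.shape:
            raise ValueError("compartment labels must share the ratio-map geometry")
        out: list[float | None] = []
        for lab in region.labels:
            sel = (region.label_map == lab) & ratio_map.valid_mask
            out.append(float(ratio_map.ratio[sel].mean()) if sel.any() else None)
        return out
    mask = np.asarray(region, dtype=bool)
    if mask.shape != ratio_map.shape:
        raise ValueError("region mask must share the ratio-map geometry")
    sel = mask & ratio_map.valid_mask
    if not sel.any():
        return None
    return float(ratio_map.ratio[sel].mean())
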