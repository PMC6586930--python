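"""Ground-truthed synthetic fixtures for the colocalization and FRET pipelines.

The colocalization generator emulates a confocal cross-section of a cell
interior: disk-like compartments (endosome scale, ~1.2 um^2 by default)
at high marker intensity over a dim background, convolved with a Gaussian
point-spread proxy, plus additive Gaussian (or Poisson) noise.  The
protein channel is flat background except inside a controllable fraction
``f`` of compartments, where it is multiplied by an enrichment factor
``e``.  With ``e = 1`` the protein channel is independent of the marker —
the null-calibration regime.

Every fixture is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .fret import FretInput
from .image_io import CalibratedImage, TwoChannelImage

__all__ = [
    "SyntheticParams",
    "CompartmentTruth",
    "GroundTruth",
    "generate_colocalization_fixture",
    "generate_self_colocalization_fixture",
    "generate_fret_fixture",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Generative parameters of the two-channel fixture.

    Defaults emulate the endosome operating regime: a 300x300 px ROI at
    0.1 um/px with 50 non-overlapping compartments of ~1.2 um^2
    (radius drawn uniformly in ``radius_um_range``), marker contrast
    200 over background 10, protein background 50, confocal-blur proxy
    sigma 1 px, additive Gaussian noise sd 2.
    """

    image_size_px: int = 300
    pixel_size_um: float = 0.1
    n_compartments: int = 50
    radius_um_range: tuple[float, float] = (0.55, 0.70)
    marker_background: float = 10.0
    marker_foreground: float = 200.0
    protein_background: float = 50.0
    enrichment_factor: float = 1.0
    fraction_enriched: float = 0.0
    noise_model: str = "gaussian"
    noise_sd: float = 2.0
    psf_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px < 8:
            raise ValueError("image_size_px too small")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if self.n_compartments < 0:
            raise ValueError("n_compartments must be >= 0")
        lo, hi = self.radius_um_range
        if not (0 < lo <= hi):
            raise ValueError("radius_um_range must satisfy 0 < lo <= hi")
        for name in ("marker_background", "marker_foreground", "protein_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if not (0 <= self.fraction_enriched <= 1):
            raise ValueError("fraction_enriched must be in [0, 1]")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.psf_sigma_px < 0:
            raise ValueError("psf_sigma_px must be >= 0")


@dataclass(frozen=True)
class CompartmentTruth:
    center_row: int
    center_col: int
    radius_px: float
    enriched: bool


@dataclass(frozen=True)
class GroundTruth:
    """True compartment geometry and enrichment flags of a fixture."""

    compartments: tuple[CompartmentTruth, ...]
    fraction_enriched: float

    @property
    def count(self) -> int:
        return len(self.compartments)

    @property
    def n_enriched(self) -> int:
        return sum(c.enriched for c in self.compartments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "center_row": c.center_row,
                    "center_col": c.center_col,
                    "radius_px": c.radius_px,
                    "enriched": c.enriched,
                }
                for c in self.compartments
            ],
            columns=["center_row", "center_col", "radius_px", "enriched"],
        )


def _place_disks(
    rng: np.random.Generator, size: int, radii_px: np.ndarray, margin_px: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping disk centres inside the image."""
    n = len(radii_px)
    rows = np.zeros(n, dtype=np.int64)
    cols = np.zeros(n, dtype=np.int64)
    max_attempts = 500 * max(n, 1)
    attempts = 0
    placed = 0
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping compartments of radii "
                f"~{radii_px.mean():.1f} px in a {size}x{size} image"
            )
        attempts += 1
        r_px = radii_px[placed]
        lo = int(np.ceil(r_px)) + 1
        hi = size - lo
        if hi <= lo:
            raise RuntimeError("image too small for the requested compartment radius")
        r = int(rng.integers(lo, hi))
        c = int(rng.integers(lo, hi))
        ok = True
        for j in range(placed):
            min_d = radii_px[placed] + radii_px[j] + margin_px
            if (r - rows[j]) ** 2 + (c - cols[j]) ** 2 < min_d * min_d:
                ok = False
                break
        if ok:
            rows[placed] = r
            cols[placed] = c
            placed += 1
    return rows, cols


def _disk_mask(size: int, rows: np.ndarray, cols: np.ndarray, radii_px: np.ndarray,
               select: np.ndarray | None = None) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    idx = range(len(rows)) if select is None else np.flatnonzero(select)
    yy, xx = np.ogrid[:size, :size]
    for i in idx:
        rr = int(np.ceil(radii_px[i])) + 1
        r0, r1 = max(rows[i] - rr, 0), min(rows[i] + rr + 1, size)
        c0, c1 = max(cols[i] - rr, 0), min(cols[i] + rr + 1, size)
        dy = np.arange(r0, r1)[:, None] - rows[i]
        dx = np.arange(c0, c1)[None, :] - cols[i]
        mask[r0:r1, c0:c1] |= dy * dy + dx * dx <= radii_px[i] ** 2
    return mask


def _add_noise(rng: np.random.Generator, ideal: np.ndarray, params: SyntheticParams) -> np.ndarray:
    if params.noise_model == "poisson":
        noisy = rng.poisson(np.clip(ideal, 0, None)).astype(float)
    else:
        noisy = ideal + rng.normal(0.0, params.noise_sd, size=ideal.shape)
    return np.clip(noisy, 0.0, None)


def _build_fixture(
    params: SyntheticParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Common geometry: placed disks, enrichment flags, ideal marker image."""
    rng = np.random.default_rng(params.seed)
    size = params.image_size_px
    n = params.n_compartments
    radii_px = (
        rng.uniform(*params.radius_um_range, size=n) / params.pixel_size_um
        if n
        else np.zeros(0)
    )
    rows, cols = _place_disks(rng, size, radii_px) if n else (np.zeros(0, int), np.zeros(0, int))
    n_enriched = int(round(params.fraction_enriched * n))
    enriched = np.zeros(n, dtype=bool)
    if n_enriched:
        enriched[rng.choice(n, size=n_enriched, replace=False)] = True
    marker_ideal = np.full((size, size), params.marker_background, dtype=float)
    all_mask = _disk_mask(size, rows, cols, radii_px)
    marker_ideal[all_mask] = params.marker_foreground
    truth = GroundTruth(
        compartments=tuple(
            CompartmentTruth(int(r), int(c), float(rp), bool(e))
            for r, c, rp, e in zip(rows, cols, radii_px, enriched)
        ),
        fraction_enriched=params.fraction_enriched,
    )
    return rows, cols, radii_px, enriched, marker_ideal, truth


def _blur(img: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma) if sigma > 0 else img


def generate_colocalization_fixture(
    params: SyntheticParams,
) -> tuple[TwoChannelImage, GroundTruth]:
    """Marker channel of bright disks + protein channel enriched in a
    fraction ``f`` of them; deterministic given the seed."""
    rows, cols, radii_px, enriched, marker_ideal, truth = _build_fixture(params)
    size = params.image_size_px
    protein_ideal = np.full((size, size), params.protein_background, dtype=float)
    if enriched.any():
        enr_mask = _disk_mask(size, rows, cols, radii_px, select=enriched)
        protein_ideal[enr_mask] = params.protein_background * params.enrichment_factor
    marker_ideal = _blur(marker_ideal, params.psf_sigma_px)
    protein_ideal = _blur(protein_ideal, params.psf_sigma_px)
    # independent noise draws per channel, but all from the one seeded stream
    noise_rng = np.random.default_rng(np.random.default_rng(params.seed).integers(2**31))
    marker = _add_noise(noise_rng, marker_ideal, params)
    protein = _add_noise(noise_rng, protein_ideal, params)
    image = TwoChannelImage(
        marker=CalibratedImage(marker, params.pixel_size_um),
        protein=CalibratedImage(protein, params.pixel_size_um),
    )
    return image, truth


def generate_self_colocalization_fixture(
    params: SyntheticParams, noise_fraction: float = 0.05
) -> tuple[TwoChannelImage, GroundTruth]:
    """Benchmark fixture where the protein channel *is* the marker channel
    plus Gaussian noise of sd = ``noise_fraction`` x marker foreground —
    the two-markers-of-one-compartment self-validation regime, in which
    essentially every real compartment should score positive."""
    rows, cols, radii_px, _, marker_ideal, truth = _build_fixture(params)
    marker_ideal = _blur(marker_ideal, params.psf_sigma_px)
    noise_rng = np.random.default_rng(np.random.default_rng(params.seed).integers(2**31))
    marker = _add_noise(noise_rng, marker_ideal, params)
    sd = noise_fraction * params.marker_foreground
    protein = np.clip(marker_ideal + noise_rng.normal(0.0, sd, marker_ideal.shape), 0, None)
    image = TwoChannelImage(
        marker=CalibratedImage(marker, params.pixel_size_um),
        protein=CalibratedImage(protein, params.pixel_size_um),
    )
    return image, truth


def generate_fret_fixture(
    true_ratio: float | np.ndarray = 2.0,
    cfp_level: float = 100.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (120, 120),
    pixel_size_um: float = 0.334,
    bin_factor: int = 1,
    cell_margin_px: int = 20,
    edge_band_um: float = 1.67,
) -> FretInput:
    """Build a FRET input with a known ratio field.

    The cell is a centred rectangle (margin ``cell_margin_px``); the
    background region is a strip along the top edge, outside the cell.
    Inside the cell: cfp = background + cfp_level, yfp = background +
    true_ratio * cfp_level (plus optional Gaussian noise), so after exact
    background subtraction the per-pixel ratio equals ``true_ratio``.
    """
    ratio = np.asarray(true_ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("true ratio must be positive everywhere")
    h, w = shape
    m = cell_margin_px
    if h <= 2 * m or w <= 2 * m:
        raise ValueError("shape too small for the cell margin")
    cell = np.zeros((h, w), dtype=bool)
    cell[m : h - m, m : w - m] = True
    if ratio.ndim == 2 and ratio.shape != (h, w):
        raise ValueError("a 2-D true_ratio must match the image shape")
    ratio_field = np.broadcast_to(ratio, (h, w)).astype(float)
    bg_region = np.zeros((h, w), dtype=bool)
    bg_region[: max(m // 2, 2), :] = True
    rng = np.random.default_rng(seed)
    cfp = np.full((h, w), background, dtype=float)
    yfp = np.full((h, w), background, dtype=float)
    cfp[cell] += cfp_level
    yfp[cell] += ratio_field[cell] * cfp_level
    if noise_sd > 0:
        cfp = np.clip(cfp + rng.normal(0, noise_sd, (h, w)), 0, None)
        yfp = np.clip(yfp + rng.normal(0, noise_sd, (h, w)), 0, None)
    return FretInput(
        cfp=CalibratedImage(cfp, pixel_size_um),
        yfp=CalibratedImage(yfp, pixel_size_um),
        cell_mask=cell,
        background_region=bg_region,
        bin_factor=bin_factor,
        edge_band_um=edge_band_um,
    )
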