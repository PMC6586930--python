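"""Randomized pseudo-compartments: the chance-colocalization null model.

Pseudo-compartments are rasterized disks of compartment-like area placed
uniformly at random inside the ROI.  Because their placement carries no
information about the marker channel, their protein-channel intensities
estimate the colocalization expected by chance; a protein is considered
genuinely present at a compartment class only if real compartments measure
significantly brighter than this null.

Field defaults follow the endosome/autophagosome operating point
(n = 1000 disks of 1.2 um^2); the trans-Golgi point is n = 10 disks of
9.2 um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import um2_to_px_area

__all__ = [
    "PseudoCompartmentParams",
    "PseudoRegion",
    "PseudoCompartmentSet",
    "generate_pseudo_compartments",
    "disk_offsets",
]

RNG_NAME = "numpy PCG64 (default_rng)"


@dataclass(frozen=True)
class PseudoCompartmentParams:
    n: int = 1000
    area_um2: float = 1.2
    seed: int = 0
    allow_overlap: bool = True

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not (self.area_um2 > 0):
            raise ValueError("area_um2 must be > 0")


@dataclass(frozen=True)
class PseudoRegion:
    """One rasterized pseudo-compartment disk."""

    center_row: int
    center_col: int
    radius_px: int
    rows: np.ndarray  # absolute pixel rows of the rasterized disk
    cols: np.ndarray

    @property
    def area_px(self) -> int:
        return len(self.rows)

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


def disk_offsets(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col offsets of all integer pixels whose centre lies within
    ``radius_px`` of the disk centre (Euclidean, inclusive)."""
    r = int(radius_px)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dr * dr + dc * dc <= r * r
    return dr[inside], dc[inside]


@dataclass(frozen=True)
class PseudoCompartmentSet:
    """n randomized disks, all strictly inside the ROI.

    Centres and a shared radius are stored; per-region pixel sets are
    materialized on demand.  ``rng_name``/``seed`` make the draw fully
    reproducible and are echoed into reports.
    """

    center_rows: np.ndarray
    center_cols: np.ndarray
    radius_px: int
    roi_shape: tuple[int, int]
    seed: int
    requested_area_px: float

    @property
    def n(self) -> int:
        return len(self.center_rows)

    @property
    def rng_name(self) -> str:
        return RNG_NAME

    @property
    def realized_area_px(self) -> int:
        """Pixel count of one rasterized disk (identical for all regions)."""
        return len(disk_offsets(self.radius_px)[0])

    @property
    def regions(self) -> list[PseudoRegion]:
        dr, dc = disk_offsets(self.radius_px)
        return [
            PseudoRegion(int(r), int(c), self.radius_px, r + dr, c + dc)
            for r, c in zip(self.center_rows, self.center_cols)
        ]

    def region_pixels(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        dr, dc = disk_offsets(self.radius_px)
        return self.center_rows[i] + dr, self.center_cols[i] + dc

    def label_map(self) -> np.ndarray:
        """Rasterize regions into an integer map (later disks overwrite)."""
        lm = np.zeros(self.roi_shape, dtype=np.int32)
        dr, dc = disk_offsets(self.radius_px)
        for i, (r, c) in enumerate(zip(self.center_rows, self.center_cols), start=1):
            lm[r + dr, c + dc] = i
        return lm


def generate_pseudo_compartments(
    roi_shape: tuple[int, int],
    pixel_size_um: float,
    params: PseudoCompartmentParams,
) -> PseudoCompartmentSet:
    """Draw ``params.n`` random disks of ``params.area_um2`` inside the ROI.

    The disk radius is ``round(sqrt(area_px / pi))`` with ``area_px =
    area_um2 / pixel_size_um**2``; centres are uniform over all positions
    keeping the disk fully inside the ROI.  With ``allow_overlap=False``
    disks are rejection-sampled to be pairwise disjoint (sensitivity-
    analysis mode; the default, unconstrained placement is the proper
    "by chance" null).
    """
    area_px = um2_to_px_area(params.area_um2, pixel_size_um)
    radius = int(round(float(np.sqrt(area_px / np.pi))))
    h, w = int(roi_shape[0]), int(roi_shape[1])
    if 2 * radius + 1 > h or 2 * radius + 1 > w:
        raise ValueError(
            f"pseudo-compartment disk (radius {radius} px for {params.area_um2} um^2 "
            f"at {pixel_size_um} um/px) does not fit inside ROI {roi_shape}"
        )
    rng = np.random.default_rng(params.seed)
    if params.n == 0:
        empty = np.zeros(0, dtype=np.int64)
        return PseudoCompartmentSet(empty, empty, radius, (h, w), params.seed, area_px)
    if params.allow_overlap:
        rows = rng.integers(radius, h - radius, size=params.n)
        cols = rng.integers(radius, w - radius, size=params.n)
    else:
        rows_l: list[int] = []
        cols_l: list[int] = []
        min_d2 = (2 * radius + 1) ** 2
        attempts = 0
        max_attempts = 10000 * max(params.n, 1)
        while len(rows_l) < params.n:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"could not place {params.n} non-overlapping pseudo-compartments "
                    f"in ROI {roi_shape} after {max_attempts} attempts"
                )
            attempts += 1
            r = int(rng.integers(radius, h - radius))
            c = int(rng.integers(radius, w - radius))
            if all((r - rr) ** 2 + (c - cc) ** 2 >= min_d2 for rr, cc in zip(rows_l, cols_l)):
                rows_l.append(r)
                cols_l.append(c)
        rows = np.array(rows_l, dtype=np.int64)
        cols = np.array(cols_l, dtype=np.int64)
    return PseudoCompartmentSet(
        np.asarray(rows, dtype=np.int64),
        np.asarray(cols, dtype=np.int64),
        radius,
        (h, w),
        params.seed,
        area_px,
    )
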