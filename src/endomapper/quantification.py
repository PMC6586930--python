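"""Intensity quantification, the mean + k*SD positivity rule, and the
real-vs-null comparison.

The decision rule: a compartment is *positive* for the protein of interest
iff its mean protein intensity strictly exceeds ``mean + k * SD`` of the
protein intensity over the entire ROI (default k = 1).  Percent positive
is reported for the real compartments and for the randomized pseudo-
compartments; the two distributions of per-region means are compared with
a two-sided Mann-Whitney rank-sum test.

All standard deviations are population SDs (divide by N), matching ImageJ
measurement semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

from .image_io import ROI, CalibratedImage, TwoChannelImage, crop_roi
from .null_model import (
    PseudoCompartmentParams,
    PseudoCompartmentSet,
    disk_offsets,
    generate_pseudo_compartments,
)
from .segmentation import LabeledCompartments, SegmentationParams, segment_compartments

__all__ = [
    "RegionMeasurement",
    "RoiStats",
    "PositivityResult",
    "TestResult",
    "EndomapperReport",
    "roi_statistics",
    "measure_regions",
    "classify_positive",
    "rank_sum_test",
    "run_endomapper",
]


@dataclass(frozen=True)
class RegionMeasurement:
    """Area, mean and population SD of the protein channel over one region."""

    region_id: int
    area_px: int
    mean_intensity: float
    sd_intensity: float


@dataclass(frozen=True)
class RoiStats:
    """Whole-ROI protein statistics defining the positivity threshold."""

    mean: float
    sd: float
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.k < 0:
            raise ValueError("k must be >= 0")

    @property
    def threshold(self) -> float:
        return self.mean + self.k * self.sd


@dataclass(frozen=True)
class PositivityResult:
    """Per-region calls against the mean + k*SD threshold."""

    calls: tuple[bool, ...]
    threshold_value: float
    n_positive: int
    n_total: int

    @property
    def percent_positive(self) -> float | None:
        """Percentage of positive regions; None (missing) when no regions."""
        if self.n_total == 0:
            return None
        return 100.0 * self.n_positive / self.n_total


@dataclass(frozen=True)
class TestResult:
    """Two-sided Mann-Whitney rank-sum test result."""

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str


def roi_statistics(protein: CalibratedImage, k: float = 1.0) -> RoiStats:
    """Mean and population SD of protein intensity over the whole ROI crop."""
    px = np.asarray(protein.pixels, dtype=float)
    if px.size == 0:
        raise ValueError("empty ROI")
    return RoiStats(mean=float(px.mean()), sd=float(px.std()), k=float(k))


def _measure_labeled(labels: LabeledCompartments, px: np.ndarray) -> list[RegionMeasurement]:
    k = labels.n_compartments
    if k == 0:
        return []
    idx = np.arange(1, k + 1)
    means = ndimage.mean(px, labels.label_map, idx)
    sds = ndimage.standard_deviation(px, labels.label_map, idx)
    areas = labels.areas_px
    return [
        RegionMeasurement(int(i), int(a), float(m), float(s))
        for i, a, m, s in zip(idx, areas, means, sds)
    ]


def _measure_pseudo(pset: PseudoCompartmentSet, px: np.ndarray) -> list[RegionMeasurement]:
    if pset.n == 0:
        return []
    dr, dc = disk_offsets(pset.radius_px)
    # (n, m) gather of every disk's pixels at once
    rows = pset.center_rows[:, None] + dr[None, :]
    cols = pset.center_cols[:, None] + dc[None, :]
    vals = px[rows, cols]
    means = vals.mean(axis=1)
    sds = vals.std(axis=1)
    area = len(dr)
    return [
        RegionMeasurement(i + 1, area, float(m), float(s))
        for i, (m, s) in enumerate(zip(means, sds))
    ]


def measure_regions(
    regions: LabeledCompartments | PseudoCompartmentSet,
    protein: CalibratedImage,
) -> list[RegionMeasurement]:
    """One (area, mean, SD) measurement per region over the protein channel."""
    px = np.asarray(protein.pixels, dtype=float)
    if isinstance(regions, LabeledCompartments):
        if regions.label_map.shape != px.shape:
            raise ValueError(
                f"geometry mismatch: labels {regions.label_map.shape} vs protein {px.shape}"
            )
        return _measure_labeled(regions, px)
    if isinstance(regions, PseudoCompartmentSet):
        if regions.roi_shape != px.shape:
            raise ValueError(
                f"geometry mismatch: pseudo-set ROI {regions.roi_shape} vs protein {px.shape}"
            )
        return _measure_pseudo(regions, px)
    raise TypeError(f"unsupported region container {type(regions).__name__}")


def classify_positive(
    measurements: Sequence[RegionMeasurement], stats: RoiStats
) -> PositivityResult:
    """Call each region positive iff mean_intensity > mean + k*SD (strict)."""
    thr = stats.threshold
    calls = tuple(m.mean_intensity > thr for m in measurements)
    return PositivityResult(
        calls=calls,
        threshold_value=thr,
        n_positive=int(sum(calls)),
        n_total=len(calls),
    )


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    U is reported for sample ``a`` (count of pairs a > b, ties counted
    half).  The exact null distribution is used for small tie-free
    samples (n1 + n2 <= 12); otherwise the normal approximation with tie
    correction.  Degenerate all-tied samples return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and a.size + b.size <= 12) else "asymptotic"
    if np.ptp(pooled) == 0:
        # all observations identical: U is forced to the midpoint, no evidence
        return TestResult(a.size * b.size / 2.0, 1.0, a.size, b.size, "degenerate")
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return TestResult(float(res.statistic), min(p, 1.0), int(a.size), int(b.size), method)


@dataclass(frozen=True)
class EndomapperReport:
    """Everything one run of the workflow produced, with full provenance."""

    n_compartments: int
    real_measurements: list[RegionMeasurement]
    pseudo_measurements: list[RegionMeasurement]
    roi_stats: RoiStats
    real_positivity: PositivityResult
    pseudo_positivity: PositivityResult
    test: TestResult | None
    labels: LabeledCompartments
    pseudo_set: PseudoCompartmentSet
    parameters: dict

    @property
    def percent_positive_real(self) -> float | None:
        return self.real_positivity.percent_positive

    @property
    def percent_positive_pseudo(self) -> float | None:
        return self.pseudo_positivity.percent_positive

    def to_dict(self) -> dict:
        """JSON-serializable summary (counts, percentages, threshold, U, p, params)."""
        return {
            "n_compartments": self.n_compartments,
            "n_pseudo": self.pseudo_set.n,
            "threshold_value": self.roi_stats.threshold,
            "roi_mean": self.roi_stats.mean,
            "roi_sd": self.roi_stats.sd,
            "k": self.roi_stats.k,
            "percent_positive_real": self.percent_positive_real,
            "percent_positive_pseudo": self.percent_positive_pseudo,
            "mann_whitney_u": None if self.test is None else self.test.u_statistic,
            "mann_whitney_p": None if self.test is None else self.test.p_value,
            "parameters": self.parameters,
        }

    def summary(self) -> str:
        lines = [
            "Endomapper report",
            "-----------------",
            f"compartments segmented : {self.n_compartments}",
            f"pseudo-compartments    : {self.pseudo_set.n} "
            f"(radius {self.pseudo_set.radius_px} px, seed {self.pseudo_set.seed})",
            f"positivity threshold   : {self.roi_stats.threshold:.6g} "
            f"(ROI mean {self.roi_stats.mean:.6g} + {self.roi_stats.k:g} x SD {self.roi_stats.sd:.6g})",
        ]
        pr = self.percent_positive_real
        pp = self.percent_positive_pseudo
        lines.append(
            "percent positive (real)  : "
            + ("missing (no compartments)" if pr is None else f"{pr:.1f}%")
        )
        lines.append(
            "percent positive (pseudo): "
            + ("missing" if pp is None else f"{pp:.1f}%")
        )
        if self.test is not None:
            lines.append(
                f"Mann-Whitney real vs pseudo: U = {self.test.u_statistic:.6g}, "
                f"p = {self.test.p_value:.3g} ({self.test.method})"
            )
        else:
            lines.append("Mann-Whitney real vs pseudo: not computed (no compartments)")
        return "\n".join(lines)


def _compartment_baseline(measurements: Sequence[RegionMeasurement], k: float) -> RoiStats:
    """Alternative threshold baseline: mean/SD over per-compartment means."""
    means = np.array([m.mean_intensity for m in measurements], dtype=float)
    if means.size == 0:
        raise ValueError("compartment baseline requires at least one compartment")
    return RoiStats(mean=float(means.mean()), sd=float(means.std()), k=float(k))


def run_endomapper(
    image: TwoChannelImage,
    roi: ROI,
    seg: SegmentationParams = SegmentationParams(),
    null: PseudoCompartmentParams = PseudoCompartmentParams(),
    k: float = 1.0,
    baseline: str = "roi",
) -> EndomapperReport:
    """Run the full workflow: crop -> segment -> measure real & null ->
    threshold -> classify -> rank-sum comparison.

    baseline : ``"roi"`` (default; threshold from whole-ROI protein
        statistics) or ``"compartments"`` (threshold from the distribution
        of per-compartment mean intensities).
    """
    if baseline not in ("roi", "compartments"):
        raise ValueError(f"unknown baseline {baseline!r}")
    marker_roi = crop_roi(image.marker, roi)
    protein_roi = crop_roi(image.protein, roi)
    labels = segment_compartments(marker_roi, seg)
    real = measure_regions(labels, protein_roi)
    pseudo_set = generate_pseudo_compartments(
        protein_roi.shape, image.pixel_size_um, null
    )
    pseudo = measure_regions(pseudo_set, protein_roi)
    stats = roi_statistics(protein_roi, k)
    if baseline == "compartments" and real:
        stats = _compartment_baseline(real, k)
    real_pos = classify_positive(real, stats)
    pseudo_pos = classify_positive(pseudo, stats)
    test = None
    if real and pseudo:
        test = rank_sum_test(
            [m.mean_intensity for m in real], [m.mean_intensity for m in pseudo]
        )
    parameters = {
        "roi": {
            "origin_row": roi.origin_row,
            "origin_col": roi.origin_col,
            "height_px": roi.height_px,
            "width_px": roi.width_px,
        },
        "pixel_size_um": image.pixel_size_um,
        "segmentation": {
            "gaussian_sigma_px": seg.gaussian_sigma_px,
            "threshold_method": seg.threshold_method,
            "fixed_threshold": seg.fixed_threshold,
            "closing_radius_px": seg.closing_radius_px,
            "min_area_px": seg.min_area_px,
        },
        "null": {
            "n": null.n,
            "area_um2": null.area_um2,
            "seed": null.seed,
            "allow_overlap": null.allow_overlap,
            "rng": pseudo_set.rng_name,
        },
        "k": k,
        "baseline": baseline,
    }
    return EndomapperReport(
        n_compartments=labels.n_compartments,
        real_measurements=real,
        pseudo_measurements=pseudo,
        roi_stats=stats,
        real_positivity=real_pos,
        pseudo_positivity=pseudo_pos,
        test=test,
        labels=labels,
        pseudo_set=pseudo_set,
        parameters=parameters,
    )
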