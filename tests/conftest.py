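import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from endomapper import CalibratedImage, SegmentationParams


@pytest.fixture
def five_disk_marker() -> CalibratedImage:
    """Five disjoint radius-5 disks at intensity 200 on background 10."""
    img = np.full((120, 120), 10.0)
    centers = [(20, 20), (20, 90), (60, 55), (95, 20), (95, 95)]
    yy, xx = np.ogrid[:120, :120]
    for r, c in centers:
        img[(yy - r) ** 2 + (xx - c) ** 2 <= 25] = 200.0
    return CalibratedImage(img, 0.1)


@pytest.fixture
def hard_seg_params() -> SegmentationParams:
    """Segmentation with no smoothing/closing: threshold + label + size filter."""
    return SegmentationParams(
        gaussian_sigma_px=0.0,
        threshold_method="fixed",
        fixed_threshold=100.0,
        closing_radius_px=0,
        min_area_px=1,
    )
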