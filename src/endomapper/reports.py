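"""Report writing: the plugin's two measurement text files plus report.json.

Numeric cells are formatted to 6 significant digits so that re-writing an
identical report is byte-identical.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Sequence

from .quantification import EndomapperReport, RegionMeasurement

__all__ = ["write_reports", "write_measurements_csv"]

MEASUREMENT_COLUMNS = ("id", "area_px", "mean_intensity", "sd_intensity")


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def write_measurements_csv(path: str | os.PathLike, measurements: Sequence[RegionMeasurement]) -> None:
    lines = [",".join(MEASUREMENT_COLUMNS)]
    for m in measurements:
        lines.append(
            f"{m.region_id},{m.area_px},{_fmt(m.mean_intensity)},{_fmt(m.sd_intensity)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_reports(report: EndomapperReport, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write real/pseudo measurement CSVs and the JSON summary.

    Returns the paths written.  The directory must exist and be writable;
    it is created if absent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise PermissionError(f"output directory {out} is not writable")
    paths = {
        "real": out / "real_compartments.csv",
        "pseudo": out / "pseudo_compartments.csv",
        "report": out / "report.json",
    }
    write_measurements_csv(paths["real"], report.real_measurements)
    write_measurements_csv(paths["pseudo"], report.pseudo_measurements)
    paths["report"].write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    return paths
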