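"""Laminar density, co-labeling and fluorescence-ratio computations.

Operates on counted data — point patterns or per-ROI count tables — not on
raw micrographs.  Densities are cells/mm^2; per-animal values are the mean
over sections, and group values the mean over animals.  Fluorescence in the
intracortical input layer (L1B) is normalised by an equal-area patch of the
afferent layer (L1A) to control for illumination differences.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import PointPattern

__all__ = [
    "density",
    "average_density",
    "colabel_percent",
    "colabel_percent_pattern",
    "intensity_ratio",
    "count_table_from_patterns",
]


def density(count: float, area_mm2: float) -> float:
    """Cells per mm^2 for one ROI."""
    if area_mm2 <= 0:
        raise ValueError("ROI area must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / area_mm2


def average_density(section_densities: Sequence[float]) -> float:
    """Per-animal density: mean across that animal's sections."""
    d = np.asarray(section_densities, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one section")
    return float(d.mean())


def colabel_percent(
    colabel_count: float, denominator_count: float
) -> float:
    """100 x co-labeled cells / denominator-marker cells.

    Raises on a zero denominator (flagged upstream rather than divided).
    """
    if denominator_count <= 0:
        raise ZeroDivisionError("denominator marker count is zero")
    if colabel_count < 0 or colabel_count > denominator_count:
        raise ValueError("co-label count must be within [0, denominator]")
    return 100.0 * colabel_count / denominator_count


def colabel_percent_pattern(
    pattern: PointPattern, marker_a: str, marker_b: str, denominator: str
) -> float:
    """Co-labeling percentage on a point pattern.

    The numerator (cells positive for both markers) is symmetric; the
    denominator is the count of ``denominator`` (one of the two markers).
    """
    if denominator not in (marker_a, marker_b):
        raise ValueError("denominator must be one of the two markers")
    return colabel_percent(
        pattern.colabel_count(marker_a, marker_b), pattern.count(denominator)
    )


def intensity_ratio(patch_l1b: np.ndarray, patch_l1a: np.ndarray) -> float:
    """mean(L1B) / mean(L1A) for equal-area intensity patches."""
    a = np.asarray(patch_l1a, dtype=float)
    b = np.asarray(patch_l1b, dtype=float)
    if a.size != b.size:
        raise ValueError("patches must have equal areas")
    denom = a.mean()
    if denom == 0:
        raise ZeroDivisionError("L1A patch has zero mean intensity")
    return float(b.mean() / denom)


def count_table_from_patterns(
    patterns: Iterable[PointPattern],
    layer: str = "all",
    markers: Sequence[str] | None = None,
    reporter: str = "tdTom",
) -> pd.DataFrame:
    """Tabulate per-section counts and co-label counts from point patterns.

    One row per section with the ROI area, the reporter count, each marker
    count and each reporter-marker co-label count — the CSV-friendly
    count-table layout the rest of the module consumes.
    """
    rows = []
    for i, pat in enumerate(patterns):
        marker_names = (
            list(markers)
            if markers is not None
            else [m for m in pat.labels if m != reporter]
        )
        row: dict = {
            "roi": f"section-{i:02d}",
            "layer": layer,
            "area_mm2": pat.roi_area_mm2,
            reporter: pat.count(reporter),
        }
        for m in marker_names:
            row[m] = pat.count(m)
            row[f"{reporter}&{m}"] = pat.colabel_count(reporter, m)
        rows.append(row)
    return pd.DataFrame(rows)
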