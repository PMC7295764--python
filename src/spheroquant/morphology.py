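"""Cell-shape quantification and motility-mode classification.

Each segmented cell is reduced to its moment-equivalent ellipse (the
ellipse with the same area and second central moments as the mask) and
the aspect ratio AR = major / minor axis.  Cells with AR >= 2 are
classified mesenchymal (elongated), AR < 2 amoeboid (rounded); the
boundary value 2.0 is inclusive on the mesenchymal side.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "ShapeRecord",
    "segment_cells",
    "ellipse_aspect_ratio",
    "classify_population",
    "MESENCHYMAL_AR_THRESHOLD",
]

#: aspect-ratio threshold: AR >= 2 -> mesenchymal, else amoeboid
MESENCHYMAL_AR_THRESHOLD = 2.0


@dataclasses.dataclass
class ShapeRecord:
    cell_id: int
    major_axis: float     # µm, full axis length
    minor_axis: float     # µm
    aspect_ratio: float
    mode: str             # "mesenchymal" | "amoeboid"

    def __post_init__(self) -> None:
        if self.aspect_ratio < 1:
            raise ValueError("aspect ratio must be >= 1")


def _dark_background(img: np.ndarray, fraction: float = 0.05) -> float:
    flat = np.sort(img, axis=None)
    return float(np.median(flat[: max(1, int(fraction * flat.size))]))


def segment_cells(
    image: np.ndarray,
    pixel_size: float,
    min_area: float = 50.0,    # µm²
    max_area: float = 2000.0,  # µm²
) -> list:
    """Segment sparse single cells: background subtraction, Otsu
    threshold, connected components, area filter.

    Touching cells merge into one oversize component and are excluded by
    the area filter (documented behavior, not an error).  Returns the
    regionprops list of accepted components.
    """
    img = np.asarray(image, dtype=float)
    img = np.clip(img - _dark_background(img), 0, None)
    if img.max() <= 0:
        return []
    try:
        thr = threshold_otsu(img)
    except ValueError:
        return []
    mask = img > thr
    if not mask.any():
        return []
    props = regionprops(label(mask))
    out = []
    for rp in props:
        area_um2 = rp.area * pixel_size**2
        if min_area <= area_um2 <= max_area:
            out.append(rp)
    return out


def ellipse_aspect_ratio(region, pixel_size: float, cell_id: int = 0) -> ShapeRecord:
    """Aspect ratio of the moment-equivalent ellipse of one mask.

    Accepts a skimage regionprops object or a boolean mask.  Degenerate
    (zero-minor-axis) masks raise.
    """
    if isinstance(region, np.ndarray):
        props = regionprops(label(region.astype(int)))
        if not props:
            raise ValueError("empty mask")
        region = max(props, key=lambda rp: rp.area)
    major = float(region.axis_major_length) * pixel_size
    minor = float(region.axis_minor_length) * pixel_size
    if minor <= 0:
        raise ValueError("degenerate (collinear) mask: minor axis is zero")
    ar = major / minor
    mode = "mesenchymal" if ar >= MESENCHYMAL_AR_THRESHOLD else "amoeboid"
    return ShapeRecord(cell_id=cell_id, major_axis=major, minor_axis=minor,
                       aspect_ratio=ar, mode=mode)


def classify_population(
    records: list[ShapeRecord], bin_width: float = 0.25
) -> dict:
    """Mesenchymal fraction with binomial SE and the AR histogram."""
    if not records:
        raise ValueError("no shape records")
    ars = np.array([r.aspect_ratio for r in records])
    n = ars.size
    n_mes = int(np.sum(ars >= MESENCHYMAL_AR_THRESHOLD))
    frac = n_mes / n
    se = float(np.sqrt(frac * (1 - frac) / n))
    edges = np.arange(1.0, ars.max() + 2 * bin_width, bin_width)
    hist, _ = np.histogram(ars, bins=edges)
    return {
        "n_cells": n,
        "n_mesenchymal": n_mes,
        "fraction_mesenchymal": float(frac),
        "binomial_se": se,
        "histogram": pd.DataFrame({
            "ar_bin_left": edges[:-1], "ar_bin_right": edges[1:], "count": hist,
        }),
    }


def shape_table(records: list[ShapeRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
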