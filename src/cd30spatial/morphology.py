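"""Shape descriptors from labeled masks.

Computes the four descriptors the profile classification rests on — area,
centroid, eccentricity, solidity — plus the maximal Feret diameter, from an
integer label raster (0 = background). Area/centroid/eccentricity/solidity
follow the standard region-properties conventions (moment-equivalent
ellipse for eccentricity, pixelated convex hull for solidity) via
scikit-image; the maximal Feret diameter is computed here as the maximum
pairwise distance between convex-hull vertices of the region's pixel
centers, which equals the rotating-calipers caliper maximum.

Coordinates are returned in μm, image convention (origin top-left, x right,
y down); a pixel's center sits at (col + 0.5, row + 0.5) · resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import regionprops

from .datamodel import DEFAULT_RESOLUTION, ValidationError, validate_cells


@dataclass
class MaskImage:
    """Integer label raster with its physical resolution (μm/pixel)."""

    labels: np.ndarray
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label raster must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label raster must be integer-typed")
        if (self.labels < 0).any():
            raise ValidationError("labels must be non-negative")
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")


def _region_pixels(mask: MaskImage, label: int) -> np.ndarray:
    rows, cols = np.nonzero(mask.labels == label)
    if rows.size == 0:
        raise ValidationError(f"label {label} absent from mask")
    return np.column_stack([rows, cols])


def compute_area_centroid(mask: MaskImage, label: int) -> tuple[float, tuple[float, float]]:
    """Area (pixel count · res²) and centroid (mean pixel center, μm)."""
    px = _region_pixels(mask, label)
    res = mask.resolution
    area = px.shape[0] * res**2
    cy = (px[:, 0].mean() + 0.5) * res
    cx = (px[:, 1].mean() + 0.5) * res
    return float(area), (float(cx), float(cy))


def compute_eccentricity(mask: MaskImage, label: int) -> float:
    """Eccentricity of the moment-equivalent ellipse, in [0, 1].

    e = sqrt(1 − λ_minor/λ_major) with λ the eigenvalues of the region's
    normalized second central moments; a single pixel is defined as 0.
    """
    px = _region_pixels(mask, label)
    if px.shape[0] == 1:
        return 0.0
    region = _single_regionprops(mask, label)
    e = float(region.eccentricity)
    return min(max(e, 0.0), 1.0)


def compute_solidity(mask: MaskImage, label: int) -> float:
    """Region pixel count over filled-convex-hull pixel count, in (0, 1]."""
    px = _region_pixels(mask, label)
    if px.shape[0] <= 2:
        return 1.0
    region = _single_regionprops(mask, label)
    return float(min(region.solidity, 1.0))


def _single_regionprops(mask: MaskImage, label: int):
    sub = (mask.labels == label).astype(np.uint8)
    return regionprops(sub)[0]


def feret_brute_force(px: np.ndarray, resolution: float) -> float:
    """O(m²) max pairwise pixel-center distance — the testing oracle."""
    if px.shape[0] == 1:
        return resolution
    d2 = ((px[:, None, :].astype(float) - px[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max())) * resolution


def compute_feret_max(mask: MaskImage, label: int) -> float:
    """Maximal Feret diameter in μm.

    The caliper maximum over all orientations equals the largest pairwise
    distance between convex-hull vertices of the region's pixel centers;
    only hull vertices need be scanned. A single pixel reports one pixel
    width.
    """
    px = _region_pixels(mask, label)
    if px.shape[0] == 1:
        return mask.resolution
    pts = px.astype(float)
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:  # collinear pixels: hull is degenerate, scan all
        verts = pts
    d2 = ((verts[:, None, :] - verts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max())) * mask.resolution


def shape_descriptors(mask: MaskImage, label: int) -> dict[str, float]:
    area, (cx, cy) = compute_area_centroid(mask, label)
    return {
        "area_um2": area,
        "x_um": cx,
        "y_um": cy,
        "eccentricity": compute_eccentricity(mask, label),
        "solidity": compute_solidity(mask, label),
        "feret_um": compute_feret_max(mask, label),
    }


def extract_features(mask: MaskImage) -> pd.DataFrame:
    """One validated cell record per label in the mask; ``pc`` unassigned."""
    labels = np.unique(mask.labels)
    labels = labels[labels > 0]
    records = []
    for lab in labels:
        d = shape_descriptors(mask, int(lab))
        d["cell_id"] = int(lab)
        records.append(d)
    if not records:
        return validate_cells(
            pd.DataFrame(
                columns=[
                    "cell_id",
                    "x_um",
                    "y_um",
                    "area_um2",
                    "eccentricity",
                    "solidity",
                    "feret_um",
                ]
            )
        )
    return validate_cells(pd.DataFrame(records))
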