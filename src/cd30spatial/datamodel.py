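"""Canonical data types and validation.

All geometry is carried in micrometers; conversion from pixel units happens
once at ingest (default scan resolution 0.25 μm/pixel). Cell tables are held
as pandas DataFrames with a fixed column schema so every stage of the
pipeline reads and writes the same plain CSV interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Allowed diagnosis labels: the two classical Hodgkin lymphoma subtypes
#: (nodular sclerosis, mixed cellularity) and lymphadenitis.
DIAGNOSES = ("NScHL", "MCcHL", "LA")

#: Fixed column schema of the cell-table interchange CSV.
CELL_COLUMNS = (
    "cell_id",
    "x_um",
    "y_um",
    "area_um2",
    "eccentricity",
    "solidity",
    "feret_um",
)

#: Number of morphological profile classes (bit code: large, elongated, frayed).
N_CLASSES = 8

#: Default scan resolution in μm per pixel.
DEFAULT_RESOLUTION = 0.25


class ValidationError(ValueError):
    """A record or table violated a schema or domain invariant."""


def px_to_um(pixels: float, resolution: float = DEFAULT_RESOLUTION) -> float:
    """Convert a length in pixels to micrometers."""
    return pixels * resolution


def px2_to_um2(pixels_sq: float, resolution: float = DEFAULT_RESOLUTION) -> float:
    """Convert an area in pixels² to μm²."""
    return pixels_sq * resolution**2


@dataclass(frozen=True)
class ThresholdConfig:
    """Profile-class thresholds.

    ``min_area`` removes small objects (area ≤ min_area is discarded);
    ``area_large`` splits small/large (a 20 μm disk by default);
    ``ecc_elongated`` splits round/elongated; ``solidity_frayed`` splits
    frayed/not frayed (solidity below the threshold is frayed).
    """

    min_area: float = 109.0
    area_large: float = 314.16
    ecc_elongated: float = 0.75
    solidity_frayed: float = 0.90

    def __post_init__(self) -> None:
        if not self.min_area < self.area_large:
            raise ValidationError(
                f"min_area ({self.min_area}) must be below area_large "
                f"({self.area_large})"
            )
        if not 0.0 < self.ecc_elongated < 1.0:
            raise ValidationError("ecc_elongated must lie in (0, 1)")
        if not 0.0 < self.solidity_frayed <= 1.0:
            raise ValidationError("solidity_frayed must lie in (0, 1]")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    Defaults follow the study conditions: 175 μm neighbor cutoff
    (700 pixels at 0.25 μm/pixel), significance level α = 1%, 2.5 μm
    diameter bins anchored at zero with the [12.5, 15) μm bin as the
    lymphadenitis reference, and network edges drawn where the absolute
    cohort score exceeds 50% of its maximum.
    """

    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    max_neighbor_distance: float = 175.0
    alpha: float = 0.01
    diameter_bin_width: float = 2.5
    reference_bin: tuple[float, float] = (12.5, 15.0)
    network_edge_fraction: float = 0.5
    resolution: float = DEFAULT_RESOLUTION
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.diameter_bin_width <= 0:
            raise ValidationError("diameter_bin_width must be positive")
        if not 0.0 < self.network_edge_fraction <= 1.0:
            raise ValidationError("network_edge_fraction must lie in (0, 1]")
        if self.max_neighbor_distance <= 0:
            raise ValidationError("max_neighbor_distance must be positive")
        lo, hi = self.reference_bin
        if not lo < hi:
            raise ValidationError("reference_bin must be a nonempty interval")


def validate_cells(cells: pd.DataFrame, require_pc: bool = False) -> pd.DataFrame:
    """Validate a cell table against the schema and domain invariants.

    Returns the validated frame (with ``pc`` as nullable integer). Raises
    :class:`ValidationError` naming offending rows; validation is total —
    no malformed row passes silently.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table missing required columns: {missing}")
    cells = cells.copy()
    if "pc" not in cells.columns:
        cells["pc"] = pd.array([pd.NA] * len(cells), dtype="Int64")
    else:
        try:
            cells["pc"] = cells["pc"].astype("Int64")
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"pc column is not integer-valued: {exc}") from exc

    for col in CELL_COLUMNS:
        vals = pd.to_numeric(cells[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            rows = cells.index[bad].tolist()[:10]
            raise ValidationError(f"non-numeric or missing {col!r} in rows {rows}")
        cells[col] = vals
    cells["cell_id"] = cells["cell_id"].astype(np.int64)

    def _reject(mask: pd.Series, what: str) -> None:
        if mask.any():
            rows = cells.index[mask].tolist()[:10]
            raise ValidationError(f"{what} in rows {rows}")

    _reject(cells["cell_id"] <= 0, "non-positive cell_id")
    _reject(cells["cell_id"].duplicated(), "duplicate cell_id")
    _reject(cells["area_um2"] <= 0, "non-positive area_um2")
    _reject(
        (cells["eccentricity"] < 0) | (cells["eccentricity"] > 1),
        "eccentricity outside [0, 1]",
    )
    _reject(
        (cells["solidity"] <= 0) | (cells["solidity"] > 1),
        "solidity outside (0, 1]",
    )
    _reject(cells["feret_um"] <= 0, "non-positive feret_um")
    # Feret diameter can never undercut the equivalent-circle diameter;
    # pixel-center measurements undershoot by ~1 px, so allow 2% relative
    # plus 0.5 μm absolute raster slack.
    equiv = 2.0 * np.sqrt(cells["area_um2"] / np.pi)
    _reject(
        cells["feret_um"] < 0.98 * equiv - 0.5,
        "feret_um below equivalent diameter",
    )
    assigned = cells["pc"].notna()
    if assigned.any():
        pcvals = cells.loc[assigned, "pc"].astype(int)
        _reject(
            pd.Series((pcvals < 0) | (pcvals >= N_CLASSES), index=cells.index).fillna(
                False
            ),
            f"pc outside 0..{N_CLASSES - 1}",
        )
    if require_pc and not assigned.all():
        rows = cells.index[~assigned].tolist()[:10]
        raise ValidationError(f"unassigned pc in rows {rows}")
    return cells


@dataclass
class ImageDataset:
    """All CD30-positive cells of one whole-slide image.

    ``window`` is the axis-aligned bounding rectangle ``(xmin, ymin, xmax,
    ymax)`` in μm (image convention: origin top-left, y downward); if not
    given it is taken from the data extent.
    """

    image_id: str
    diagnosis: str
    cells: pd.DataFrame
    resolution: float = DEFAULT_RESOLUTION
    window: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(
                f"diagnosis {self.diagnosis!r} not in {DIAGNOSES}"
            )
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")
        self.cells = validate_cells(self.cells)
        if self.window is None:
            if len(self.cells):
                self.window = (
                    float(self.cells["x_um"].min()),
                    float(self.cells["y_um"].min()),
                    float(self.cells["x_um"].max()),
                    float(self.cells["y_um"].max()),
                )
            else:
                self.window = (0.0, 0.0, 0.0, 0.0)
        xmin, ymin, xmax, ymax = self.window
        inside = (
            (self.cells["x_um"] >= xmin)
            & (self.cells["x_um"] <= xmax)
            & (self.cells["y_um"] >= ymin)
            & (self.cells["y_um"] <= ymax)
        )
        if not inside.all():
            rows = self.cells.index[~inside].tolist()[:10]
            raise ValidationError(f"cell centroids outside window in rows {rows}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def classified(self) -> bool:
        return bool(len(self.cells)) and bool(self.cells["pc"].notna().all())

    def with_cells(self, cells: pd.DataFrame) -> "ImageDataset":
        return ImageDataset(
            image_id=self.image_id,
            diagnosis=self.diagnosis,
            cells=cells,
            resolution=self.resolution,
            window=self.window,
        )

    def equals(self, other: "ImageDataset", rtol: float = 1e-9) -> bool:
        """Value equality up to floating-point round-trip tolerance."""
        if (
            self.image_id != other.image_id
            or self.diagnosis != other.diagnosis
            or len(self.cells) != len(other.cells)
        ):
            return False
        a = self.cells.sort_values("cell_id").reset_index(drop=True)
        b = other.cells.sort_values("cell_id").reset_index(drop=True)
        if not (a["cell_id"].values == b["cell_id"].values).all():
            return False
        for col in CELL_COLUMNS[1:]:
            if not np.allclose(a[col].values, b[col].values, rtol=rtol):
                return False
        return a["pc"].fillna(-1).equals(b["pc"].fillna(-1))


@dataclass(frozen=True)
class ManifestEntry:
    image_id: str
    diagnosis: str
    path: str


@dataclass
class CohortManifest:
    """Index of a cohort: one row per image (id, diagnosis, cell-table path)."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.diagnosis not in DIAGNOSES:
                raise ValidationError(
                    f"diagnosis {e.diagnosis!r} for image {e.image_id} "
                    f"not in {DIAGNOSES}"
                )
        ids = [e.image_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate image_id in manifest")

    def counts(self) -> dict[str, int]:
        out = {d: 0 for d in DIAGNOSES}
        for e in self.entries:
            out[e.diagnosis] += 1
        return out

    def for_diagnosis(self, diagnosis: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.diagnosis == diagnosis]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def cells_from_records(records: Iterable[dict]) -> pd.DataFrame:
    """Build a validated cell table from an iterable of dict records."""
    df = pd.DataFrame(list(records))
    return validate_cells(df)
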