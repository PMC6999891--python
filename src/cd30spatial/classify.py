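"""Profile-class assignment from shape descriptors.

Each cell is mapped to one of eight morphological profile classes (PC) by a
three-bit code over its shape descriptors:

    pc = large + 2 * elongated + 4 * frayed

with ``large ⇔ area ≥ area_large``, ``elongated ⇔ eccentricity ≥
ecc_elongated`` and ``frayed ⇔ solidity < solidity_frayed``. PC 0 is a
small round cell, PC 7 a large, elongated, frayed cell — the morphology
typical of Hodgkin/Reed-Sternberg cells. Objects of 109 μm² or less are
discarded before classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import N_CLASSES, ImageDataset, ThresholdConfig, ValidationError

#: Human-readable names of the eight profile classes, in bit-code order.
CLASS_NAMES = (
    "small round",
    "large round",
    "small elongated",
    "large elongated",
    "small frayed",
    "large frayed",
    "small elongated frayed",
    "large elongated frayed",
)


def filter_small_objects(cells: pd.DataFrame, min_area: float = 109.0) -> pd.DataFrame:
    """Drop objects with area ≤ ``min_area`` μm² (strictly larger survive)."""
    return cells[cells["area_um2"] > min_area].reset_index(drop=True)


def classify_cell(
    area: float, eccentricity: float, solidity: float, thresholds: ThresholdConfig
) -> int:
    """Assign the profile class of a single descriptor triple."""
    large = int(area >= thresholds.area_large)
    elongated = int(eccentricity >= thresholds.ecc_elongated)
    frayed = int(solidity < thresholds.solidity_frayed)
    return large + 2 * elongated + 4 * frayed


def classify_cells(
    cells: pd.DataFrame, thresholds: ThresholdConfig
) -> pd.DataFrame:
    """Vectorized classification; fills the ``pc`` column."""
    large = (cells["area_um2"].values >= thresholds.area_large).astype(int)
    elongated = (cells["eccentricity"].values >= thresholds.ecc_elongated).astype(int)
    frayed = (cells["solidity"].values < thresholds.solidity_frayed).astype(int)
    out = cells.copy()
    out["pc"] = pd.array(large + 2 * elongated + 4 * frayed, dtype="Int64")
    return out


def classify_dataset(
    dataset: ImageDataset, thresholds: ThresholdConfig | None = None
) -> ImageDataset:
    """Filter small objects, then classify every remaining cell."""
    thresholds = thresholds or ThresholdConfig()
    cells = filter_small_objects(dataset.cells, thresholds.min_area)
    return dataset.with_cells(classify_cells(cells, thresholds))


def class_frequencies(dataset: ImageDataset) -> np.ndarray:
    """Relative frequency f(i) of each profile class over all classified cells.

    Isolated cells (no neighbor within the cutoff) still count here: the
    class marginals are a property of the whole image.
    """
    if dataset.n_cells == 0:
        raise ValidationError("cannot compute class frequencies of an empty dataset")
    if not dataset.classified:
        raise ValidationError("dataset has unclassified cells (pc column incomplete)")
    counts = np.bincount(dataset.cells["pc"].astype(int).values, minlength=N_CLASSES)
    return counts / counts.sum()


def small_large_split(freqs: np.ndarray) -> tuple[float, float]:
    """Aggregate frequencies into (small, large): PC 0/2/4/6 vs PC 1/3/5/7."""
    freqs = np.asarray(freqs, dtype=float)
    small = float(freqs[[0, 2, 4, 6]].sum())
    large = float(freqs[[1, 3, 5, 7]].sum())
    return small, large
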