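"""Nearest-neighbor tables and distance statistics.

For every classified cell the single nearest other cell (Euclidean distance
between centroids) is recorded together with both profile classes, provided
it lies within the communication cutoff (default 175 μm, roughly ten cell
diameters). The relation is directional and deliberately not symmetrized.

The null reference is complete spatial randomness (CSR): for a homogeneous
Poisson process of intensity λ the nearest-neighbor distance is Rayleigh
with pdf 2πλr·exp(−πλr²) and mean 1/(2√λ).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datamodel import ImageDataset, ValidationError

#: Relative tolerance treating two neighbor distances as tied.
_TIE_RTOL = 1e-9


@dataclass
class NeighborhoodTable:
    """Per-cell (PC, NPC, distance) rows under the cutoff.

    ``rows`` columns: ``cell_id, pc, neighbor_id, npc, nn_distance_um``.
    ``excluded_isolated`` counts cells whose nearest other cell lies beyond
    the cutoff; those cells appear in no row but remain part of the image's
    class marginals.
    """

    rows: pd.DataFrame
    excluded_isolated: int
    cutoff: float

    def __len__(self) -> int:
        return len(self.rows)


def _nearest_brute(xy: np.ndarray, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs scan; ties broken by lowest neighbor cell_id. O(n²) oracle."""
    n = len(xy)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.empty(n, dtype=int)
    nn_d = np.empty(n)
    for i in range(n):
        dmin = d2[i].min()
        tied = np.flatnonzero(d2[i] <= dmin * (1 + 2 * _TIE_RTOL))
        nn_idx[i] = tied[np.argmin(ids[tied])]
        nn_d[i] = np.sqrt(dmin)
    return nn_idx, nn_d


def _nearest_kdtree(xy: np.ndarray, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """KD-tree nearest neighbors with the same deterministic tie-break.

    Contract: identical output to :func:`_nearest_brute` on any input.
    """
    tree = cKDTree(xy)
    dist, idx = tree.query(xy, k=2)
    nn_d = dist[:, 1]
    nn_idx = idx[:, 1]
    # resolve ties (equidistant neighbors) toward the lowest cell_id
    for i in np.flatnonzero(nn_d > 0):
        cand = tree.query_ball_point(xy[i], nn_d[i] * (1 + _TIE_RTOL))
        cand = [c for c in cand if c != i]
        if len(cand) > 1:
            d = np.sqrt(((xy[cand] - xy[i]) ** 2).sum(axis=1))
            tied = [c for c, dd in zip(cand, d) if dd <= nn_d[i] * (1 + 2 * _TIE_RTOL)]
            nn_idx[i] = min(tied, key=lambda c: ids[c])
    # coincident points: query may return the point itself at distance 0
    zero = nn_d == 0
    if zero.any():
        for i in np.flatnonzero(zero):
            cand = [c for c in tree.query_ball_point(xy[i], 0.0) if c != i]
            if cand:
                nn_idx[i] = min(cand, key=lambda c: ids[c])
            else:  # numerically distinct after all; fall back to k=2 result
                pass
    return nn_idx, nn_d


def nearest_neighbors(
    dataset: ImageDataset, cutoff: float = 175.0, method: str = "kdtree"
) -> NeighborhoodTable:
    """Build the neighborhood table of a classified image.

    Every cell contributes at most one row: its nearest other cell and the
    distance, if within ``cutoff`` μm. Cells with no neighbor inside the
    cutoff are excluded and counted in ``excluded_isolated``. Distance ties
    are broken toward the lowest neighbor ``cell_id``.
    """
    if not dataset.classified:
        raise ValidationError("nearest_neighbors requires a classified dataset")
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    cells = dataset.cells
    n = len(cells)
    cols = ["cell_id", "pc", "neighbor_id", "npc", "nn_distance_um"]
    if n < 2:
        return NeighborhoodTable(pd.DataFrame(columns=cols), excluded_isolated=n,
                                 cutoff=cutoff)
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    ids = cells["cell_id"].to_numpy(dtype=np.int64)
    pcs = cells["pc"].to_numpy(dtype=int)
    if not np.isfinite(xy).all():
        raise ValidationError("non-finite centroid coordinates")
    if method == "brute":
        nn_idx, nn_d = _nearest_brute(xy, ids)
    elif method == "kdtree":
        nn_idx, nn_d = _nearest_kdtree(xy, ids)
    else:
        raise ValueError(f"unknown method {method!r}")
    keep = nn_d <= cutoff
    rows = pd.DataFrame(
        {
            "cell_id": ids[keep],
            "pc": pcs[keep],
            "neighbor_id": ids[nn_idx[keep]],
            "npc": pcs[nn_idx[keep]],
            "nn_distance_um": nn_d[keep],
        }
    )
    return NeighborhoodTable(rows, excluded_isolated=int((~keep).sum()), cutoff=cutoff)


def csr_nn_distribution(lam: float) -> tuple[Callable[[np.ndarray], np.ndarray], float]:
    """CSR nearest-neighbor distance law for intensity ``lam`` (μm⁻²).

    Returns ``(pdf, mean)`` with pdf(r) = 2πλr·exp(−πλr²) and mean
    1/(2√λ) μm.
    """
    if lam <= 0:
        raise ValidationError("intensity must be positive")

    def pdf(r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return 2.0 * np.pi * lam * r * np.exp(-np.pi * lam * r**2)

    return pdf, 1.0 / (2.0 * np.sqrt(lam))


def mean_nn_distance(table: NeighborhoodTable) -> tuple[float, float]:
    """Mean and SD of nearest-neighbor distances over the table's rows."""
    if len(table) == 0:
        raise ValidationError("empty neighborhood table")
    d = table.rows["nn_distance_um"].to_numpy()
    return float(d.mean()), float(d.std(ddof=0))


def pair_mean_distance(table: NeighborhoodTable, pc: int, npc: int) -> float | None:
    """Mean NN distance over rows with the given (PC, NPC); None if absent."""
    sel = table.rows[(table.rows["pc"] == pc) & (table.rows["npc"] == npc)]
    if len(sel) == 0:
        return None
    return float(sel["nn_distance_um"].mean())


def pc0_pair_distance_ratio(table: NeighborhoodTable) -> float | None:
    """Ratio of the mean distance of small-round (PC=NPC=0) pairs to the
    overall mean NN distance; > 1 means such pairs sit farther apart than
    typical neighbors. ``None`` when no qualifying pair exists."""
    if len(table) == 0:
        return None
    num = pair_mean_distance(table, 0, 0)
    if num is None:
        return None
    den = float(table.rows["nn_distance_um"].mean())
    return num / den
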