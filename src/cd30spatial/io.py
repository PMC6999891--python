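"""Readers and writers for the plain-text interchange formats.

Cell tables and matrices travel as CSV, configuration as YAML. Matrices are
written in the conventional orientation of the significance tables: one row
per neighbor profile class (NPC), one column per profile class (PC), i.e.
the transpose of the internal ``M[pc, npc]`` layout.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    CELL_COLUMNS,
    N_CLASSES,
    AnalysisConfig,
    CohortManifest,
    ImageDataset,
    ManifestEntry,
    ThresholdConfig,
    ValidationError,
    validate_cells,
)

logger = logging.getLogger("cd30spatial")

_PC_COLS = [f"PC{i}" for i in range(N_CLASSES)]
_NPC_ROWS = [f"NPC{j}" for j in range(N_CLASSES)]


def read_cell_table(
    path: str | Path,
    image_id: str,
    diagnosis: str,
    resolution: float = 0.25,
    window: tuple[float, float, float, float] | None = None,
) -> ImageDataset:
    """Read a cell-table CSV into a validated :class:`ImageDataset`.

    The file must carry the seven-column header
    ``cell_id,x_um,y_um,area_um2,eccentricity,solidity,feret_um`` with an
    optional trailing ``pc`` column. Malformed rows raise
    :class:`ValidationError` naming the rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    ds = ImageDataset(
        image_id=image_id,
        diagnosis=diagnosis,
        cells=df,
        resolution=resolution,
        window=window,
    )
    logger.info("read %d cells from %s (image %s)", ds.n_cells, path, image_id)
    return ds


def write_cell_table(dataset: ImageDataset, path: str | Path) -> Path:
    """Write the dataset's cell table to CSV (``pc`` blank where unassigned)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = list(CELL_COLUMNS) + ["pc"]
    dataset.cells[cols].to_csv(path, index=False)
    logger.info("wrote %d cells to %s", dataset.n_cells, path)
    return path


def write_matrix(matrix: np.ndarray | pd.DataFrame, path: str | Path) -> Path:
    """Serialize an 8×8 per-class matrix to CSV.

    The in-memory convention is ``matrix[pc, npc]``; the file is written
    with NPC rows and PC columns (the orientation of printed significance
    matrices), so the array is transposed on output.
    """
    arr = np.asarray(matrix, dtype=object)
    if arr.shape != (N_CLASSES, N_CLASSES):
        raise ValidationError(f"matrix must be 8x8, got shape {arr.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame(arr.T, index=_NPC_ROWS, columns=_PC_COLS)
    out.to_csv(path, index=True, index_label="")
    return path


def read_matrix(path: str | Path, dtype: type = float) -> np.ndarray:
    """Read a matrix CSV written by :func:`write_matrix` back to ``M[pc, npc]``.

    ``dtype=str`` reads call matrices (blank entries become ``"ns"``).
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape != (N_CLASSES, N_CLASSES):
        raise ValidationError(f"matrix file {path} has shape {df.shape}, not 8x8")
    arr = df.values.T  # back to [pc, npc]
    if dtype is str:
        out = np.empty((N_CLASSES, N_CLASSES), dtype=object)
        for i in range(N_CLASSES):
            for j in range(N_CLASSES):
                v = arr[i, j]
                out[i, j] = "ns" if (isinstance(v, float) and np.isnan(v)) or v in (
                    "",
                    None,
                ) else str(v)
        return out
    return arr.astype(dtype)


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV (``image_id,diagnosis,path``)."""
    df = pd.read_csv(path, dtype=str)
    required = ["image_id", "diagnosis", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    entries = [
        ManifestEntry(r.image_id, r.diagnosis, r.path) for r in df.itertuples()
    ]
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(e.image_id, e.diagnosis, e.path) for e in manifest],
        columns=["image_id", "diagnosis", "path"],
    ).to_csv(path, index=False)
    return path


_THRESHOLD_KEYS = {"min_area", "area_large", "ecc_elongated", "solidity_frayed"}


def config_from_dict(data: dict[str, Any]) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a (possibly partial) mapping."""
    data = dict(data or {})
    thr = data.pop("thresholds", {}) or {}
    unknown = set(thr) - _THRESHOLD_KEYS
    if unknown:
        raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {"thresholds": ThresholdConfig(**thr)}
    allowed = {
        "max_neighbor_distance",
        "alpha",
        "diameter_bin_width",
        "reference_bin",
        "network_edge_fraction",
        "resolution",
        "seed",
    }
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for k, v in data.items():
        kwargs[k] = tuple(v) if k == "reference_bin" else v
    return AnalysisConfig(**kwargs)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load a YAML config file; absent keys fall back to the defaults.

    ``None`` or an empty file yields the all-defaults configuration
    (175 μm cutoff, α = 0.01, 2.5 μm bins).
    """
    if path is None:
        return AnalysisConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def dump_config(config: AnalysisConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = asdict(config)
    data["reference_bin"] = list(config.reference_bin)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
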