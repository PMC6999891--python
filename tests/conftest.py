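import numpy as np
import pandas as pd
import pytest

from cd30spatial.datamodel import ImageDataset, ThresholdConfig, validate_cells
from cd30spatial.synthetic import (
    DEFAULT_CLASS_FREQS,
    SyntheticSpec,
    default_clustering,
    sample_morphology,
    sample_null_image,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_cells(xy: np.ndarray, pcs=None, rng=None, thresholds=None) -> pd.DataFrame:
    """Cell table at given positions with valid (classifier-consistent)
    morphology; pcs=None leaves pc unassigned with class-0 features."""
    rng = rng if rng is not None else np.random.default_rng(0)
    thresholds = thresholds or ThresholdConfig()
    n = len(xy)
    labels = np.zeros(n, dtype=int) if pcs is None else np.asarray(pcs, dtype=int)
    frames = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        m = sample_morphology(int(c), idx.size, thresholds, rng)
        m.insert(0, "y_um", xy[idx, 1])
        m.insert(0, "x_um", xy[idx, 0])
        m["cell_id"] = idx + 1
        if pcs is not None:
            m["pc"] = int(c)
        frames.append(m)
    cells = pd.concat(frames, ignore_index=True).sort_values("cell_id")
    cols = ["cell_id", "x_um", "y_um", "area_um2", "eccentricity", "solidity",
            "feret_um"] + (["pc"] if pcs is not None else [])
    return validate_cells(cells[cols].reset_index(drop=True))


def make_dataset(xy, pcs=None, image_id="img", diagnosis="LA", rng=None,
                 window=None) -> ImageDataset:
    xy = np.asarray(xy, dtype=float)
    return ImageDataset(
        image_id=image_id,
        diagnosis=diagnosis,
        cells=make_cells(xy, pcs, rng),
        window=window,
    )


@pytest.fixture
def null_image(rng):
    return sample_null_image(
        (0.0, 0.0, 1000.0, 1000.0), 1200, DEFAULT_CLASS_FREQS["MCcHL"], rng
    )


@pytest.fixture
def clustered_spec():
    intensity = DEFAULT_CLASS_FREQS["MCcHL"] * 2.5e-3
    return SyntheticSpec(
        window=(0.0, 0.0, 2000.0, 2000.0),
        intensity=intensity,
        clustering=default_clustering(intensity),
        seed=11,
    )
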