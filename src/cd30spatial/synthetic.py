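"""Synthetic cohorts: marked point patterns with controllable structure.

Stands in for the study's whole-slide images. Cells of each profile class
are laid down either as complete spatial randomness (CSR, the null model)
or as a Thomas cluster process (Poisson parents, Poisson offspring counts,
isotropic Gaussian displacement), since CD30-positive cells cluster in real
tissue regardless of diagnosis. Two planted interactions are available:

* attraction (a, b, fraction): the stated fraction of class-b cluster
  parents is co-located with randomly chosen class-a parents, so their
  offspring mingle and class-b cells preferentially find class-a nearest
  neighbors;
* repulsion (a, b, radius): class-b points within the hard-core radius of
  any class-a point are deleted (the later-sampled class of the pair loses),
  emptying class-a neighborhoods of class b.

Morphology features are drawn uniformly inside the threshold cell of the
intended class with a 5% safety margin on every threshold, so the
classifier recovers the planted class exactly. The Feret diameter is
derived from an ellipse of the drawn area and eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    DIAGNOSES,
    N_CLASSES,
    CohortManifest,
    ImageDataset,
    ManifestEntry,
    ThresholdConfig,
    ValidationError,
    validate_cells,
)
from .morphology import MaskImage

#: Default per-class frequency mix per diagnosis. Small classes dominate
#: everywhere; the large-cell total falls from NScHL (17.4%) over MCcHL
#: (11.1%) to lymphadenitis (8.1%).
DEFAULT_CLASS_FREQS = {
    "NScHL": np.array([0.345, 0.060, 0.110, 0.010, 0.240, 0.070, 0.131, 0.034]),
    "MCcHL": np.array([0.390, 0.037, 0.122, 0.007, 0.258, 0.042, 0.119, 0.025]),
    "LA": np.array([0.420, 0.028, 0.130, 0.005, 0.270, 0.030, 0.099, 0.018]),
}

#: Largest area the morphology sampler will draw (a 60 μm disk).
AREA_MAX = 2827.4

#: Default image counts per diagnosis.
DEFAULT_IMAGE_COUNTS = {"NScHL": 12, "MCcHL": 12, "LA": 11}


@dataclass(frozen=True)
class ClusterParams:
    """Thomas process parameters: parents/μm², offspring per parent, σ μm."""

    parent_intensity: float
    offspring_mean: float
    sigma: float

    def __post_init__(self) -> None:
        if self.parent_intensity < 0 or self.offspring_mean < 0:
            raise ValidationError("cluster intensities must be non-negative")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic image (or a cohort of such images).

    ``intensity[c]`` is the expected number of class-c cells per μm²;
    classes with an entry in ``clustering`` are laid down as Thomas
    clusters, the rest as CSR.
    """

    window: tuple[float, float, float, float] = (0.0, 0.0, 2000.0, 2000.0)
    intensity: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_FREQS["MCcHL"] * 2.5e-3
    )
    clustering: dict[int, ClusterParams] = field(default_factory=dict)
    attraction_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    repulsion_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    morphology_margin: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (N_CLASSES,):
            raise ValidationError(f"intensity must have {N_CLASSES} entries")
        if (self.intensity < 0).any():
            raise ValidationError("intensities must be non-negative")
        for a, b, frac in self.attraction_pairs:
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("shared-parent fraction must lie in [0, 1]")
            if a not in self.clustering or b not in self.clustering:
                raise ValidationError(
                    f"attraction pair ({a}, {b}) requires both classes clustered"
                )
        for _, _, radius in self.repulsion_pairs:
            if radius < 0:
                raise ValidationError("hard-core radius must be non-negative")
        xmin, ymin, xmax, ymax = self.window
        if not (xmin < xmax and ymin < ymax):
            raise ValidationError("window must have positive extent")

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)


def default_clustering(intensity: np.ndarray, offspring_mean: float = 25.0,
                       sigma: float = 30.0) -> dict[int, ClusterParams]:
    """Thomas parameters giving each class its requested intensity."""
    out = {}
    for c in range(N_CLASSES):
        if intensity[c] > 0:
            out[c] = ClusterParams(
                parent_intensity=intensity[c] / offspring_mean,
                offspring_mean=offspring_mean,
                sigma=sigma,
            )
    return out


def sample_csr(
    window: tuple[float, float, float, float],
    intensity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Homogeneous Poisson pattern: Poisson(λ·|W|) points uniform in W."""
    if intensity < 0:
        raise ValidationError("intensity must be non-negative")
    xmin, ymin, xmax, ymax = window
    area = (xmax - xmin) * (ymax - ymin)
    n = rng.poisson(intensity * area)
    pts = np.empty((n, 2))
    pts[:, 0] = rng.uniform(xmin, xmax, size=n)
    pts[:, 1] = rng.uniform(ymin, ymax, size=n)
    return pts


def _thomas_parents(
    window: tuple[float, float, float, float],
    parent_intensity: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    # parents live in the window dilated by 4σ so clusters straddling the
    # boundary contribute their share of offspring
    xmin, ymin, xmax, ymax = window
    pad = 4.0 * sigma
    return sample_csr((xmin - pad, ymin - pad, xmax + pad, ymax + pad),
                      parent_intensity, rng)


def _thomas_offspring(
    parents: np.ndarray,
    offspring_mean: float,
    sigma: float,
    window: tuple[float, float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    if len(parents) == 0 or offspring_mean == 0:
        return np.empty((0, 2))
    counts = rng.poisson(offspring_mean, size=len(parents))
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(0.0, sigma, size=centers.shape)
    xmin, ymin, xmax, ymax = window
    keep = (
        (pts[:, 0] >= xmin)
        & (pts[:, 0] <= xmax)
        & (pts[:, 1] >= ymin)
        & (pts[:, 1] <= ymax)
    )
    return pts[keep]


def sample_thomas(
    window: tuple[float, float, float, float],
    parent_intensity: float,
    offspring_mean: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thomas (Neyman-Scott) cluster process restricted to the window."""
    params = ClusterParams(parent_intensity, offspring_mean, sigma)
    parents = _thomas_parents(window, params.parent_intensity, params.sigma, rng)
    return _thomas_offspring(parents, params.offspring_mean, params.sigma, window, rng)


# ---------------------------------------------------------------------------
# morphology sampling

def _class_feature_box(
    pc: int, thresholds: ThresholdConfig, margin: float
) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float]]:
    """Uniform sampling box (area, ecc, solidity) for the target class."""
    t = thresholds
    large = bool(pc & 1)
    elongated = bool(pc & 2)
    frayed = bool(pc & 4)
    if large:
        area = (t.area_large * (1 + margin), AREA_MAX)
    else:
        area = (t.min_area + margin * t.min_area, t.area_large * (1 - margin))
    if elongated:
        ecc = (min(t.ecc_elongated * (1 + margin), 0.97), 0.98)
    else:
        ecc = (0.0, t.ecc_elongated * (1 - margin))
    if frayed:
        sol = (0.55, t.solidity_frayed * (1 - margin))
    else:
        sol = (min(t.solidity_frayed * (1 + margin), 1.0), 1.0)
    for name, (lo, hi) in (("area", area), ("eccentricity", ecc), ("solidity", sol)):
        if not lo < hi:
            raise ValidationError(
                f"infeasible morphology region for class {pc}: empty {name} range"
            )
    return area, ecc, sol


def sample_morphology(
    pc: int,
    n: int,
    thresholds: ThresholdConfig,
    rng: np.random.Generator,
    margin: float = 0.05,
) -> pd.DataFrame:
    """Draw n descriptor triples inside the class-pc threshold cell.

    The Feret diameter is the major axis of the ellipse with the drawn
    area and eccentricity, 2·sqrt(area / (π·sqrt(1 − e²))) — always at
    least the equivalent-circle diameter.
    """
    (a_lo, a_hi), (e_lo, e_hi), (s_lo, s_hi) = _class_feature_box(
        pc, thresholds, margin
    )
    area = rng.uniform(a_lo, a_hi, size=n)
    ecc = rng.uniform(e_lo, e_hi, size=n)
    sol = rng.uniform(s_lo, s_hi, size=n)
    feret = 2.0 * np.sqrt(area / (np.pi * np.sqrt(1.0 - ecc**2)))
    return pd.DataFrame(
        {
            "area_um2": area,
            "eccentricity": ecc,
            "solidity": sol,
            "feret_um": feret,
        }
    )


# ---------------------------------------------------------------------------
# whole images and cohorts

def _sample_class_points(
    spec: SyntheticSpec, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Positions per class, honoring clustering and attraction pairs."""
    shared_for: dict[int, tuple[int, float]] = {
        b: (a, frac) for a, b, frac in spec.attraction_pairs
    }
    parents: dict[int, np.ndarray] = {}
    points: dict[int, np.ndarray] = {}
    for c in range(N_CLASSES):
        if spec.intensity[c] == 0:
            points[c] = np.empty((0, 2))
            continue
        if c in spec.clustering:
            cp = spec.clustering[c]
            par = _thomas_parents(spec.window, cp.parent_intensity, cp.sigma, rng)
            if c in shared_for:
                a, frac = shared_for[c]
                donor = parents.get(a)
                if donor is not None and len(donor) and len(par):
                    share = rng.random(len(par)) < frac
                    idx = rng.integers(0, len(donor), size=int(share.sum()))
                    par[share] = donor[idx]
            parents[c] = par
            points[c] = _thomas_offspring(par, cp.offspring_mean, cp.sigma,
                                          spec.window, rng)
        else:
            points[c] = sample_csr(spec.window, spec.intensity[c], rng)
    # hard-core repulsion: the second class of the pair is thinned
    from scipy.spatial import cKDTree

    for a, b, radius in spec.repulsion_pairs:
        if radius <= 0 or len(points[a]) == 0 or len(points[b]) == 0:
            continue
        tree = cKDTree(points[a])
        d, _ = tree.query(points[b], k=1)
        points[b] = points[b][d > radius]
    return points


def sample_image(
    spec: SyntheticSpec,
    image_id: str,
    diagnosis: str = "MCcHL",
    rng: np.random.Generator | None = None,
) -> ImageDataset:
    """One synthetic image; ``pc`` left unassigned (classification fills it),
    but features are drawn so the classifier recovers the planted class."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    points = _sample_class_points(spec, rng)
    frames = []
    for c in range(N_CLASSES):
        pts = points[c]
        if len(pts) == 0:
            continue
        morph = sample_morphology(c, len(pts), spec.thresholds, rng,
                                  spec.morphology_margin)
        morph.insert(0, "y_um", pts[:, 1])
        morph.insert(0, "x_um", pts[:, 0])
        frames.append(morph)
    if frames:
        cells = pd.concat(frames, ignore_index=True)
        # shuffle so cell ids carry no class information
        order = rng.permutation(len(cells))
        cells = cells.iloc[order].reset_index(drop=True)
        cells.insert(0, "cell_id", np.arange(1, len(cells) + 1))
    else:
        cells = pd.DataFrame(
            columns=["cell_id", "x_um", "y_um", "area_um2", "eccentricity",
                     "solidity", "feret_um"]
        )
    cells = validate_cells(cells)
    return ImageDataset(
        image_id=image_id,
        diagnosis=diagnosis,
        cells=cells,
        window=spec.window,
    )


def sample_null_image(
    window: tuple[float, float, float, float],
    n_cells: int,
    class_probs: np.ndarray,
    rng: np.random.Generator,
    thresholds: ThresholdConfig | None = None,
    image_id: str = "null",
    diagnosis: str = "LA",
) -> ImageDataset:
    """CSR positions with independent multinomial class labels.

    The null model of the significance test: positions carry no class
    information at all. ``pc`` is assigned directly (the morphology draw is
    classifier-consistent, so classifying would reproduce it).
    """
    thresholds = thresholds or ThresholdConfig()
    class_probs = np.asarray(class_probs, dtype=float)
    if class_probs.shape != (N_CLASSES,) or not np.isclose(class_probs.sum(), 1.0):
        raise ValidationError("class_probs must be 8 probabilities summing to 1")
    xmin, ymin, xmax, ymax = window
    xy = np.empty((n_cells, 2))
    xy[:, 0] = rng.uniform(xmin, xmax, size=n_cells)
    xy[:, 1] = rng.uniform(ymin, ymax, size=n_cells)
    labels = rng.choice(N_CLASSES, size=n_cells, p=class_probs)
    frames = []
    for c in range(N_CLASSES):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        morph = sample_morphology(c, idx.size, thresholds, rng)
        morph.insert(0, "y_um", xy[idx, 1])
        morph.insert(0, "x_um", xy[idx, 0])
        morph["pc"] = c
        morph["cell_id"] = idx + 1
        frames.append(morph)
    cells = pd.concat(frames, ignore_index=True).sort_values("cell_id")
    cells = cells[["cell_id", "x_um", "y_um", "area_um2", "eccentricity",
                   "solidity", "feret_um", "pc"]].reset_index(drop=True)
    return ImageDataset(image_id=image_id, diagnosis=diagnosis,
                        cells=validate_cells(cells), window=window)


def sample_cohort(
    spec: SyntheticSpec,
    image_counts: dict[str, int] | None = None,
    class_freqs: dict[str, np.ndarray] | None = None,
) -> tuple[CohortManifest, list[ImageDataset]]:
    """A full multi-diagnosis cohort; per-image seeds derive from spec.seed.

    Per-diagnosis class mixes rescale ``spec.intensity``'s total; the
    spatial structure (clustering, planted pairs) is shared. Reproducible:
    a fixed ``spec.seed`` yields a bit-identical cohort.
    """
    image_counts = image_counts or dict(DEFAULT_IMAGE_COUNTS)
    class_freqs = class_freqs or DEFAULT_CLASS_FREQS
    total = float(spec.intensity.sum())
    seeds = np.random.SeedSequence(spec.seed).spawn(sum(image_counts.values()))
    datasets = []
    entries = []
    i = 0
    for diagnosis in DIAGNOSES:
        for k in range(image_counts.get(diagnosis, 0)):
            intensity = class_freqs[diagnosis] * total
            img_spec = SyntheticSpec(
                window=spec.window,
                intensity=intensity,
                clustering=_rescaled_clustering(spec, intensity),
                attraction_pairs=list(spec.attraction_pairs),
                repulsion_pairs=list(spec.repulsion_pairs),
                thresholds=spec.thresholds,
                morphology_margin=spec.morphology_margin,
                seed=spec.seed,
            )
            image_id = f"{diagnosis}-{k + 1:02d}"
            rng = np.random.default_rng(seeds[i])
            datasets.append(sample_image(img_spec, image_id, diagnosis, rng))
            entries.append(ManifestEntry(image_id, diagnosis, f"{image_id}.csv"))
            i += 1
    return CohortManifest(entries), datasets


def _rescaled_clustering(
    spec: SyntheticSpec, intensity: np.ndarray
) -> dict[int, ClusterParams]:
    out = {}
    for c, cp in spec.clustering.items():
        scale = intensity[c] / spec.intensity[c] if spec.intensity[c] > 0 else 0.0
        out[c] = ClusterParams(cp.parent_intensity * scale, cp.offspring_mean,
                               cp.sigma)
    return out


# ---------------------------------------------------------------------------
# diameter mixture components (for the background-subtraction analysis)

def sample_diameters(component: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw maximal Feret diameters (μm) from a named population.

    ``"lymphocyte"``: activated lymphocytes, 10-30 μm, mode near 13.5 μm
    (truncated normal). ``"hrs"``: Hodgkin/Reed-Sternberg-like cells,
    normal(30, 10) truncated to [16, 65] μm — zero mass below 15 μm, the
    identifying assumption of the background subtraction.
    """
    if component == "lymphocyte":
        lo, hi, mu, sd = 10.0, 30.0, 13.5, 2.0
    elif component == "hrs":
        lo, hi, mu, sd = 16.0, 65.0, 30.0, 10.0
    else:
        raise ValidationError(f"unknown diameter component {component!r}")
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mu, sd, size=2 * n)
        draw = draw[(draw >= lo) & (draw <= hi)]
        out = np.concatenate([out, draw])
    return out[:n]


# ---------------------------------------------------------------------------
# mask fixtures

def rasterize_shapes(
    shapes: list[tuple[str, dict]],
    resolution: float = 0.25,
    shape_px: tuple[int, int] | None = None,
) -> MaskImage:
    """Rasterize disks/ellipses/crosses (parameters in μm) to a label mask.

    Shape k (1-based) labels every pixel whose center falls inside it.
    Supported kinds: ``disk`` (center, radius), ``ellipse`` (center, a, b,
    angle_deg), ``cross`` (center, length, width — two centered orthogonal
    rectangles). Overlapping shapes are an error.
    """
    if not shapes:
        raise ValidationError("no shapes to rasterize")
    # autosize the canvas to cover all shapes plus a margin
    if shape_px is None:
        extent = 0.0
        for kind, p in shapes:
            cx, cy = p["center"]
            r = {
                "disk": lambda p: p["radius"],
                "ellipse": lambda p: max(p["a"], p["b"]),
                "cross": lambda p: p["length"] / 2.0,
            }[kind](p)
            extent = max(extent, cx + r, cy + r)
        side = int(np.ceil((extent + 2.0) / resolution))
        shape_px = (side, side)
    labels = np.zeros(shape_px, dtype=np.int32)
    rows, cols = np.mgrid[0 : shape_px[0], 0 : shape_px[1]]
    px_x = (cols + 0.5) * resolution
    px_y = (rows + 0.5) * resolution
    for k, (kind, p) in enumerate(shapes, start=1):
        cx, cy = p["center"]
        dx = px_x - cx
        dy = px_y - cy
        if kind == "disk":
            inside = dx**2 + dy**2 <= p["radius"] ** 2
        elif kind == "ellipse":
            theta = np.deg2rad(p.get("angle_deg", 0.0))
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            inside = (u / p["a"]) ** 2 + (v / p["b"]) ** 2 <= 1.0
        elif kind == "cross":
            half_l = p["length"] / 2.0
            half_w = p["width"] / 2.0
            horiz = (np.abs(dx) <= half_l) & (np.abs(dy) <= half_w)
            vert = (np.abs(dx) <= half_w) & (np.abs(dy) <= half_l)
            inside = horiz | vert
        else:
            raise ValidationError(f"unknown shape kind {kind!r}")
        if (labels[inside] != 0).any():
            raise ValidationError(f"shape {k} ({kind}) overlaps an earlier shape")
        labels[inside] = k
    return MaskImage(labels=labels, resolution=resolution)
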