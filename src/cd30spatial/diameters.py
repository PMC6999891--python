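"""Cell-diameter distributions and lymphadenitis background subtraction.

"Diameter" means the maximal Feret diameter throughout. Diameters are
binned into uniform half-open bins [lo, hi) of width 2.5 μm anchored at
zero. CD30-positive cells in lymphadenitis (LA) are activated lymphocytes,
not tumor cells; assuming cells in the reference bin (default [12.5, 15)
μm) of a lymphoma image are background of the same kind, the LA
distribution scaled by the reference-bin ratio c is subtracted from the
disease distribution. The leftover mass 1 − c estimates the proportion of
genuine Hodgkin/Reed-Sternberg cells; the identifying assumption is that
true tumor cells contribute no mass to the reference bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ImageDataset, ValidationError


@dataclass
class DiameterHistogram:
    """Normalized histogram of maximal Feret diameters (half-open bins)."""

    edges: np.ndarray  # len nbins+1, uniform, starting at 0
    freqs: np.ndarray  # len nbins, sums to 1
    n_cells: int

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def bin_index(self, interval: tuple[float, float]) -> int:
        """Index of the bin equal to ``interval``; error if bins mismatch."""
        lo, hi = interval
        idx = int(round(lo / self.bin_width))
        if (
            idx < 0
            or idx >= len(self.freqs)
            or abs(self.edges[idx] - lo) > 1e-9
            or abs(self.edges[idx + 1] - hi) > 1e-9
        ):
            raise ValidationError(
                f"interval {interval} is not a bin of this histogram"
            )
        return idx


def diameter_histogram(
    dataset_or_values: ImageDataset | np.ndarray, bin_width: float = 2.5
) -> DiameterHistogram:
    """Histogram the maximal Feret diameters of a dataset (or raw values)."""
    if isinstance(dataset_or_values, ImageDataset):
        values = dataset_or_values.cells["feret_um"].to_numpy(dtype=float)
    else:
        values = np.asarray(dataset_or_values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot histogram an empty dataset")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if (values < 0).any():
        raise ValidationError("negative diameters")
    # floor-index binning gives exactly half-open [lo, hi) bins anchored at 0
    idx = np.floor(values / bin_width).astype(int)
    nbins = int(idx.max()) + 1
    edges = np.arange(nbins + 1) * bin_width
    counts = np.bincount(idx, minlength=nbins)
    freqs = counts / counts.sum()
    return DiameterHistogram(edges=edges, freqs=freqs, n_cells=int(values.size))


def _aligned(a: DiameterHistogram, b: DiameterHistogram) -> tuple[np.ndarray, np.ndarray]:
    """Pad two same-width, zero-anchored histograms to a common length."""
    if abs(a.bin_width - b.bin_width) > 1e-9:
        raise ValidationError("histograms have different bin widths")
    n = max(len(a.freqs), len(b.freqs))
    fa = np.zeros(n)
    fb = np.zeros(n)
    fa[: len(a.freqs)] = a.freqs
    fb[: len(b.freqs)] = b.freqs
    return fa, fb


@dataclass
class CorrectedDistribution:
    """Disease diameter distribution after LA-background subtraction."""

    group: str
    edges: np.ndarray
    freqs: np.ndarray  # corrected, clipped at 0, renormalized
    scaling_c: float
    hrs_proportion: float  # 1 - c, clamped to [0, 1]
    clipped_mass: float  # total negative mass removed before renormalization

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def background_correction(
    disease: DiameterHistogram,
    la: DiameterHistogram,
    reference_bin: tuple[float, float] = (12.5, 15.0),
    group: str = "",
) -> CorrectedDistribution:
    """Subtract the scaled LA background from a disease histogram.

    c = disease(ref)/la(ref); corrected(b) = max(0, disease(b) − c·la(b)),
    renormalized; the estimated tumor-cell proportion is 1 − c.
    """
    fd, fl = _aligned(disease, la)
    ref = disease.bin_index(reference_bin)
    la_ref = fl[ref]
    if la_ref <= 0:
        raise ValidationError("LA histogram has zero mass in the reference bin")
    c = float(fd[ref] / la_ref)
    corrected = fd - c * fl
    clipped = float(-corrected[corrected < 0].sum())
    corrected = np.clip(corrected, 0.0, None)
    total = corrected.sum()
    if total > 0:
        corrected = corrected / total
    n = len(corrected)
    edges = np.arange(n + 1) * disease.bin_width
    return CorrectedDistribution(
        group=group,
        edges=edges,
        freqs=corrected,
        scaling_c=c,
        hrs_proportion=float(np.clip(1.0 - c, 0.0, 1.0)),
        clipped_mass=clipped,
    )


def corrected_moments(
    corrected: CorrectedDistribution, tail_threshold: float = 50.0
) -> tuple[float, float, float]:
    """(mean, SD, tail fraction) of a corrected distribution.

    Moments are taken over bin centers weighted by corrected frequencies;
    the tail fraction sums bins whose center exceeds ``tail_threshold`` μm.
    """
    w = corrected.freqs
    if w.sum() <= 0:
        raise ValidationError("all-zero corrected distribution: moments undefined")
    centers = corrected.centers
    mean = float((centers * w).sum())
    var = float(((centers - mean) ** 2 * w).sum())
    tail = float(w[centers > tail_threshold].sum())
    return mean, float(np.sqrt(var)), tail
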