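"""End-to-end cohort pipeline.

Stages run in the analysis order — classify → neighborhood tables →
per-image significance matrices → per-diagnosis score matrices and
preference networks → diameter analysis — and every stage writes its
intermediate CSVs, so each stage is independently re-runnable and every
reported number is traceable to a file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .classify import class_frequencies, classify_dataset, small_large_split
from .datamodel import DIAGNOSES, AnalysisConfig, CohortManifest, ImageDataset
from .diameters import (
    CorrectedDistribution,
    background_correction,
    corrected_moments,
    diameter_histogram,
)
from .neighbors import NeighborhoodTable, mean_nn_distance, nearest_neighbors
from .scoring import NetworkSpec, ScoreMatrix, build_network, export_network, score_matrix
from .significance import SignificanceMatrix, significance_matrix

logger = logging.getLogger("cd30spatial")


@dataclass
class ImageResult:
    image_id: str
    diagnosis: str
    n_cells: int
    frequencies: np.ndarray
    mean_nn: float
    sd_nn: float
    excluded_isolated: int
    significance: SignificanceMatrix
    table: NeighborhoodTable
    feret_um: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class RunReport:
    config: AnalysisConfig
    images: list[ImageResult]
    scores: dict[str, ScoreMatrix]
    networks: dict[str, NetworkSpec]
    corrected: dict[str, CorrectedDistribution]
    moments: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def analyze_image(dataset: ImageDataset, config: AnalysisConfig) -> ImageResult:
    """Classify one image and compute its table and significance matrix."""
    ds = classify_dataset(dataset, config.thresholds)
    table = nearest_neighbors(ds, cutoff=config.max_neighbor_distance)
    freqs = class_frequencies(ds)
    if len(table):
        mean_nn, sd_nn = mean_nn_distance(table)
    else:
        mean_nn, sd_nn = float("nan"), float("nan")
    sig = significance_matrix(ds, table, alpha=config.alpha)
    return ImageResult(
        image_id=ds.image_id,
        diagnosis=ds.diagnosis,
        n_cells=ds.n_cells,
        frequencies=freqs,
        mean_nn=mean_nn,
        sd_nn=sd_nn,
        excluded_isolated=table.excluded_isolated,
        significance=sig,
        table=table,
        feret_um=ds.cells["feret_um"].to_numpy(dtype=float),
    )


def run_pipeline(
    config: AnalysisConfig,
    manifest: CohortManifest,
    out_dir: str | Path,
    datasets: list[ImageDataset] | None = None,
    base_dir: str | Path | None = None,
) -> RunReport:
    """Run the full analysis over a cohort and write all artifacts.

    ``datasets`` may carry pre-loaded images (matched to the manifest by
    image_id); otherwise cell tables are read from the manifest paths,
    resolved against ``base_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = {d.image_id: d for d in datasets} if datasets else {}
    results: list[ImageResult] = []
    summary_rows = []
    for entry in manifest:
        try:
            if entry.image_id in by_id:
                ds = by_id[entry.image_id]
            else:
                path = Path(entry.path)
                if base_dir is not None and not path.is_absolute():
                    path = Path(base_dir) / path
                ds = cio.read_cell_table(
                    path, entry.image_id, entry.diagnosis, config.resolution
                )
            res = analyze_image(ds, config)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed at image {entry.image_id!r}: {exc}"
            ) from exc
        results.append(res)
        img_dir = out / "images" / res.image_id
        cio.write_matrix(res.significance.calls, img_dir / "calls.csv")
        cio.write_matrix(res.significance.k, img_dir / "pair_counts.csv")
        cio.write_matrix(res.significance.k_low, img_dir / "k_low.csv")
        cio.write_matrix(res.significance.k_up, img_dir / "k_up.csv")
        res.table.rows.to_csv(img_dir / "neighborhood.csv", index=False)
        small, large = small_large_split(res.frequencies)
        summary_rows.append(
            {
                "image_id": res.image_id,
                "diagnosis": res.diagnosis,
                "n_cells": res.n_cells,
                "mean_nn_um": res.mean_nn,
                "sd_nn_um": res.sd_nn,
                "excluded_isolated": res.excluded_isolated,
                "frac_small": small,
                "frac_large": large,
                **{f"f{c}": res.frequencies[c] for c in range(8)},
            }
        )
    pd.DataFrame(summary_rows).to_csv(out / "image_summary.csv", index=False)

    groups = {d: [r.significance for r in results if r.diagnosis == d]
              for d in DIAGNOSES}
    groups["all"] = [r.significance for r in results]
    scores: dict[str, ScoreMatrix] = {}
    networks: dict[str, NetworkSpec] = {}
    for group, mats in groups.items():
        if not mats:
            continue
        sm = score_matrix(mats, group)
        scores[group] = sm
        cio.write_matrix(sm.score, out / f"score_{group}.csv")
        cio.write_matrix(sm.percent, out / f"score_percent_{group}.csv")
        net = build_network(sm, config.network_edge_fraction)
        networks[group] = net
        export_network(net, out / f"network_{group}.dot", "dot")
        export_network(net, out / f"network_{group}.graphml", "graphml")

    corrected, moments = diameter_stage(results, config, out)
    cio.dump_config(config, out / "config.yaml")
    logger.info("pipeline finished: %d images, %d groups", len(results),
                len(scores))
    return RunReport(
        config=config,
        images=results,
        scores=scores,
        networks=networks,
        corrected=corrected,
        moments=moments,
    )


def diameter_stage(
    results: list[ImageResult],
    config: AnalysisConfig,
    out: Path | None = None,
) -> tuple[dict[str, CorrectedDistribution], dict[str, tuple[float, float, float]]]:
    """Pooled diameter histograms per diagnosis; LA-background correction
    of the two lymphoma groups when an LA group is present."""
    corrected: dict[str, CorrectedDistribution] = {}
    moments: dict[str, tuple[float, float, float]] = {}
    hists = {}
    for d in DIAGNOSES:
        arrays = [r.feret_um for r in results if r.diagnosis == d and r.feret_um.size]
        feret = np.concatenate(arrays) if arrays else np.empty(0)
        if feret.size:
            hists[d] = diameter_histogram(feret, config.diameter_bin_width)
            if out is not None:
                pd.DataFrame(
                    {"bin_lo": hists[d].edges[:-1], "bin_hi": hists[d].edges[1:],
                     "freq": hists[d].freqs}
                ).to_csv(out / f"diameter_hist_{d}.csv", index=False)
    if "LA" in hists:
        for d in ("NScHL", "MCcHL"):
            if d not in hists:
                continue
            corr = background_correction(
                hists[d], hists["LA"], config.reference_bin, group=d
            )
            corrected[d] = corr
            moments[d] = corrected_moments(corr)
            if out is not None:
                pd.DataFrame(
                    {"bin_lo": corr.edges[:-1], "bin_hi": corr.edges[1:],
                     "freq": corr.freqs}
                ).to_csv(out / f"diameter_corrected_{d}.csv", index=False)
    return corrected, moments
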