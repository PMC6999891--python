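"""Data types, validation totality, and reader/writer round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cd30spatial import io as cio
from cd30spatial.datamodel import (
    AnalysisConfig,
    CohortManifest,
    ImageDataset,
    ManifestEntry,
    ThresholdConfig,
    ValidationError,
    validate_cells,
)

from conftest import make_dataset


def _table(**overrides):
    base = {
        "cell_id": [1, 2, 3],
        "x_um": [10.0, 20.0, 30.0],
        "y_um": [10.0, 15.0, 5.0],
        "area_um2": [150.0, 200.0, 400.0],
        "eccentricity": [0.2, 0.5, 0.9],
        "solidity": [0.95, 0.97, 0.8],
        "feret_um": [16.0, 18.0, 30.0],
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestValidation:
    def test_well_formed_passes(self):
        cells = validate_cells(_table())
        assert len(cells) == 3
        assert cells["pc"].isna().all()

    @pytest.mark.parametrize(
        "column,value,match",
        [
            ("eccentricity", 1.2, "eccentricity"),
            ("solidity", 0.0, "solidity"),
            ("area_um2", -5.0, "area"),
            ("cell_id", 1, "duplicate"),
            ("feret_um", 2.0, "equivalent diameter"),
        ],
    )
    def test_invariant_violations_name_rows(self, column, value, match):
        df = _table()
        df.loc[1, column] = value
        with pytest.raises(ValidationError, match=match):
            validate_cells(df)

    def test_missing_column_is_schema_error(self):
        with pytest.raises(ValidationError, match="missing required"):
            validate_cells(_table().drop(columns=["solidity"]))

    def test_non_numeric_names_row(self):
        df = _table()
        df["x_um"] = df["x_um"].astype(object)
        df.loc[2, "x_um"] = "oops"
        with pytest.raises(ValidationError, match=r"x_um.*\[2\]"):
            validate_cells(df)

    def test_centroid_outside_window_rejected(self):
        with pytest.raises(ValidationError, match="outside window"):
            ImageDataset("i", "LA", _table(), window=(0, 0, 25, 25))

    def test_bad_diagnosis_rejected(self):
        with pytest.raises(ValidationError, match="diagnosis"):
            ImageDataset("i", "HL", _table())


class TestCellTableRoundTrip:
    def test_read_write_identity(self, tmp_path, rng):
        xy = rng.uniform(0, 500, size=(40, 2))
        ds = make_dataset(xy, pcs=rng.integers(0, 8, size=40), rng=rng)
        path = tmp_path / "cells.csv"
        cio.write_cell_table(ds, path)
        back = cio.read_cell_table(path, ds.image_id, ds.diagnosis)
        assert ds.equals(back)

    def test_read_rejects_malformed_row(self, tmp_path):
        df = _table()
        df.loc[0, "eccentricity"] = 1.2
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="eccentricity"):
            cio.read_cell_table(p, "x", "LA")


class TestMatrixRoundTrip:
    def test_wrong_shape_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="8x8"):
            cio.write_matrix(np.zeros((3, 3)), tmp_path / "m.csv")

    def test_orientation_matches_printed_layout(self, tmp_path):
        m = np.full((8, 8), "ns", dtype=object)
        m[0, 6] = "sl"  # PC0 -> NPC6
        p = cio.write_matrix(m, tmp_path / "calls.csv")
        df = pd.read_csv(p, index_col=0)
        # printed layout: NPC rows x PC columns
        assert df.loc["NPC6", "PC0"] == "sl"
        assert df.loc["NPC0", "PC6"] == "ns"

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_numeric_round_trip(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(-30, 30, size=(8, 8))
        p = tmp_path_factory.mktemp("m") / "m.csv"
        cio.write_matrix(m, p)
        assert (cio.read_matrix(p, dtype=int) == m).all()

    def test_call_matrix_round_trip(self, tmp_path, rng):
        m = rng.choice(["sh", "sl", "ns"], size=(8, 8)).astype(object)
        p = cio.write_matrix(m, tmp_path / "c.csv")
        assert (cio.read_matrix(p, dtype=str) == m).all()

    def test_reconstructed_significance_matrix_layout(self, tmp_path):
        # a published per-image matrix, reconstructed from its printed
        # calls (rows NPC0..7, columns PC0..7, blank = ns)
        printed_rows = [
            "sh . . . . sl sl .",
            ". sh sh sh . sh . sh",
            ". . sh sh sl . . .",
            ". sh . sh sl sh . sh",
            ". sl sl sl sh sl . sl",
            ". sh . sh sl sh . sh",
            "sl . . . . . . .",
            "sl sh . sh sl sh . sh",
        ]
        by_npc = np.array(
            [[c if c != "." else "ns" for c in row.split()] for row in printed_rows],
            dtype=object,
        )
        m = by_npc.T  # internal convention M[pc, npc]
        p = cio.write_matrix(m, tmp_path / "t2.csv")
        df = pd.read_csv(p, index_col=0).fillna("ns")
        # the written file reproduces the printed orientation exactly
        assert (df.values == by_npc).all()
        # column PC0 carries one sh (NPC0) and two sl (NPC6, NPC7)
        col0 = df["PC0"]
        assert col0["NPC0"] == "sh"
        assert list(col0[col0 == "sl"].index) == ["NPC6", "NPC7"]
        assert (cio.read_matrix(p, dtype=str) == m).all()


class TestConfig:
    def test_empty_file_gives_defaults(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("")
        cfg = cio.load_config(p)
        assert cfg.max_neighbor_distance == 175.0
        assert cfg.alpha == 0.01
        assert cfg.diameter_bin_width == 2.5
        assert cfg.thresholds.min_area == 109.0

    def test_override_applied(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("alpha: 0.05\nthresholds:\n  min_area: 90\n")
        cfg = cio.load_config(p)
        assert cfg.alpha == 0.05
        assert cfg.thresholds.min_area == 90

    @pytest.mark.parametrize("text", ["alpha: 1.5", "network_edge_fraction: 1.5"])
    def test_out_of_range_rejected(self, tmp_path, text):
        p = tmp_path / "c.yaml"
        p.write_text(text)
        with pytest.raises(ValidationError):
            cio.load_config(p)

    def test_config_round_trip(self, tmp_path):
        cfg = AnalysisConfig(alpha=0.02, thresholds=ThresholdConfig(min_area=100))
        p = cio.dump_config(cfg, tmp_path / "c.yaml")
        assert cio.load_config(p) == cfg


class TestManifest:
    def test_round_trip_and_counts(self, tmp_path):
        m = CohortManifest(
            [
                ManifestEntry("a", "NScHL", "a.csv"),
                ManifestEntry("b", "LA", "b.csv"),
            ]
        )
        p = cio.write_manifest(m, tmp_path / "m.csv")
        back = cio.read_manifest(p)
        assert back.counts() == {"NScHL": 1, "MCcHL": 0, "LA": 1}
        assert [e.image_id for e in back] == ["a", "b"]

    def test_duplicate_image_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            CohortManifest(
                [ManifestEntry("a", "LA", "x"), ManifestEntry("a", "LA", "y")]
            )
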