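"""Exact binomial machinery: oracles, calibration, planted-truth recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cd30spatial.datamodel import ValidationError
from cd30spatial.neighbors import nearest_neighbors
from cd30spatial.significance import (
    binom_cdf,
    conditional_probabilities,
    distance_significance_correlation,
    enrichment_log_odds,
    prediction_interval,
    significance_call,
    significance_matrix,
)
from cd30spatial.synthetic import DEFAULT_CLASS_FREQS, sample_null_image

from conftest import make_dataset


def interval_oracle(n, p, alpha):
    """Exhaustive term-by-term summation over all k in [0, n]."""
    ks = np.arange(n + 1)
    pmf = stats.binom.pmf(ks, n, p)
    cdf = np.cumsum(pmf)
    tail = np.cumsum(pmf[::-1])[::-1]  # tail[k] = P(X >= k)
    low_ok = ks[cdf <= alpha / 2]
    up_ok = ks[tail <= alpha / 2]
    k_low = int(low_ok.max()) if low_ok.size else -1
    k_up = int(up_ok.min()) if up_ok.size else n + 1
    return k_low, k_up


class TestBinomCdf:
    def test_closed_form_tenth(self):
        assert binom_cdf(0, 10, 0.5) == pytest.approx(1 / 1024)

    def test_full_support_is_one(self):
        assert binom_cdf(50, 50, 0.37) == pytest.approx(1.0)

    def test_matches_term_summation(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 201))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0, 1))
            direct = stats.binom.pmf(np.arange(k + 1), n, p).sum()
            assert binom_cdf(k, n, p) == pytest.approx(direct, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            binom_cdf(11, 10, 0.5)
        with pytest.raises(ValidationError):
            binom_cdf(1, 10, 1.5)


class TestPredictionInterval:
    def test_symmetric_ten_half(self):
        iv = prediction_interval(10, 0.5, 0.01)
        # CDF(0) = 1/1024 <= 0.005 < CDF(1); symmetric upper tail
        assert (iv.k_low, iv.k_up) == (0, 10)

    def test_degenerate_p_zero(self):
        iv = prediction_interval(20, 0.0, 0.01)
        assert iv.k_low == -1
        assert iv.k_up == 1  # P(X >= 1) = 0 <= alpha/2

    def test_alpha_monotone_never_narrows(self):
        wide = prediction_interval(500, 0.3, 0.001)
        narrow = prediction_interval(500, 0.3, 0.05)
        assert wide.k_low <= narrow.k_low
        assert wide.k_up >= narrow.k_up

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.integers(0, 200),
        st.floats(0.0, 1.0, allow_nan=False),
        st.floats(0.001, 0.5, exclude_min=False),
    )
    def test_oracle_equivalence(self, n, p, alpha):
        iv = prediction_interval(n, p, alpha)
        assert (iv.k_low, iv.k_up) == interval_oracle(n, p, alpha)

    def test_large_n_worked_example(self):
        iv = prediction_interval(3435, 0.316, 0.01)
        assert iv.k_low == interval_oracle(3435, 0.316, 0.01)[0]
        assert iv.k_up == interval_oracle(3435, 0.316, 0.01)[1]

    def test_coverage_at_study_scale(self, rng):
        # fraction of binomial draws outside the 1% interval stays near 1%
        n, p = 3435, 0.316
        iv = prediction_interval(n, p, 0.01)
        draws = rng.binomial(n, p, size=10000)
        outside = ((draws < iv.k_low) | (draws > iv.k_up)).mean()
        assert outside <= 0.012


class TestCalls:
    def test_worked_example_is_sh(self):
        iv = prediction_interval(3435, 0.316, 0.01)
        assert significance_call(1217, iv) == "sh"

    def test_interior_and_endpoints_are_ns(self):
        iv = prediction_interval(100, 0.4, 0.01)
        assert significance_call((iv.k_low + iv.k_up) // 2, iv) == "ns"
        assert significance_call(iv.k_low, iv) == "ns"
        assert significance_call(iv.k_up, iv) == "ns"
        assert significance_call(iv.k_low - 1, iv) == "sl"
        assert significance_call(iv.k_up + 1, iv) == "sh"


class TestSignificanceMatrix:
    def test_row_sums_match_neighbor_counts(self, null_image):
        t = nearest_neighbors(null_image)
        sig = significance_matrix(null_image, t)
        counts = t.rows.groupby("pc").size()
        for i in range(8):
            assert sig.k[i].sum() == counts.get(i, 0)

    def test_single_class_image_all_ns(self, rng):
        ds = make_dataset(rng.uniform(0, 200, size=(50, 2)), pcs=[0] * 50, rng=rng)
        sig = significance_matrix(ds, nearest_neighbors(ds))
        # p = f(0) = 1 so k = n is never outside the interval
        assert (sig.calls == "ns").all()

    def test_null_calibration_small_batch(self, rng):
        # pooled sh+sl rate over 60 null images stays near alpha
        flagged = total = 0
        probs = DEFAULT_CLASS_FREQS["LA"]
        for _ in range(60):
            ds = sample_null_image((0, 0, 1000, 1000), 800, probs, rng)
            sig = significance_matrix(ds, nearest_neighbors(ds))
            c = sig.call_counts()
            flagged += c["sh"] + c["sl"]
            total += 64
        assert flagged / total <= 0.02

    def test_label_shuffle_destroys_planted_calls(self, rng):
        from cd30spatial.classify import classify_dataset
        from cd30spatial.synthetic import (
            SyntheticSpec,
            default_clustering,
            sample_image,
        )

        intensity = DEFAULT_CLASS_FREQS["MCcHL"] * 2.5e-3
        spec = SyntheticSpec(
            window=(0, 0, 2000, 2000),
            intensity=intensity,
            clustering=default_clustering(intensity),
            attraction_pairs=[(5, 7, 0.8)],
            seed=42,
        )
        ds = classify_dataset(sample_image(spec, "planted"))
        sig = significance_matrix(ds, nearest_neighbors(ds))
        assert sig.calls[7, 5] == "sh"
        shuffled = ds.cells.copy()
        shuffled["pc"] = rng.permutation(shuffled["pc"].values)
        ds2 = ds.with_cells(shuffled)
        sig2 = significance_matrix(ds2, nearest_neighbors(ds2))
        assert sig2.calls[7, 5] == "ns"
        c = sig2.call_counts()
        assert (c["sh"] + c["sl"]) / 64 <= 0.05


class TestConditionalProbabilities:
    def test_worked_example_value(self, rng):
        # 1,217 of 3,435 class-0 cells with class-0 neighbors -> 0.354
        import pandas as pd

        from cd30spatial.neighbors import NeighborhoodTable

        rows = pd.DataFrame(
            {
                "cell_id": np.arange(1, 3436),
                "pc": 0,
                "neighbor_id": 1,
                "npc": np.repeat([0, 1], [1217, 2218]),
                "nn_distance_um": 10.0,
            }
        )
        cond = conditional_probabilities(
            NeighborhoodTable(rows, excluded_isolated=0, cutoff=175.0)
        )
        assert round(cond[0, 0], 3) == 0.354

    def test_hand_built_enumeration(self, rng):
        ds = make_dataset(
            [(0, 0), (10, 0), (108, 0), (100, 0)],
            pcs=[0, 0, 4, 0], rng=rng,
        )
        cond = conditional_probabilities(nearest_neighbors(ds))
        # pc0 cells: 1->2 (npc0), 2->1 (npc0), 4->3 (npc4); pc4: 3->4 (npc0)
        assert cond[0, 0] == pytest.approx(2 / 3)
        assert cond[0, 4] == pytest.approx(1 / 3)
        assert cond[4, 0] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, null_image):
        cond = conditional_probabilities(nearest_neighbors(null_image))
        sums = np.nansum(cond, axis=1)
        defined = ~np.isnan(cond).all(axis=1)
        assert np.allclose(sums[defined], 1.0)


class TestLogOdds:
    def test_median_near_zero(self):
        n, p = 100, 0.5
        assert abs(enrichment_log_odds(50, n, p)) < 0.2

    def test_strictly_increasing_in_k(self):
        vals = [enrichment_log_odds(k, 50, 0.3) for k in range(51)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_extreme_enrichment_large_positive(self):
        assert enrichment_log_odds(20, 20, 0.5) > 10.0


class TestDistanceCorrelation:
    def test_perfectly_linear(self):
        pairs = [(d, 2.0 * d + 1.0) for d in (10.0, 20.0, 30.0, 40.0)]
        assert distance_significance_correlation(pairs) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        d = rng.uniform(10, 50, size=30)
        lo = rng.normal(size=30)
        r1 = distance_significance_correlation(list(zip(d, lo)))
        r2 = distance_significance_correlation(list(zip(3 * d + 7, 0.5 * lo - 2)))
        assert r1 == pytest.approx(r2)

    def test_independent_pairs_near_zero(self, rng):
        d = rng.uniform(10, 50, size=1000)
        lo = rng.normal(size=1000)
        assert abs(distance_significance_correlation(list(zip(d, lo)))) < 0.1

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValidationError):
            distance_significance_correlation([(1.0, 2.0), (2.0, 3.0)])
        with pytest.raises(ValidationError):
            distance_significance_correlation([(1.0, 2.0)] * 5)
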