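"""Counting, Poisson thresholding, and co-expression summary statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crevalid as cv
from crevalid.coexpression_stats import (
    background_rate,
    call_positive,
    count_puncta_per_nucleus,
    pairwise_r2,
    poisson_threshold,
    specificity_consistency,
)
from crevalid.nucleus_segmentation import NucleusLabelMap
from crevalid.puncta_detection import PunctaSet

from conftest import label_map_from_truth, puncta_set_from_truth


def brute_force_poisson_k(lam, percentile):
    """Smallest k with sum_{i<=k} lam^i e^-lam / i! >= percentile (oracle)."""
    term = math.exp(-lam)
    cdf = term
    k = 0
    while cdf < percentile:
        k += 1
        term *= lam / k
        cdf += term
    return k


class TestPoissonThreshold:
    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 3.0, 10.0, 20.0])
    @pytest.mark.parametrize("percentile", [0.90, 0.95, 0.999])
    def test_matches_cdf_summation_oracle(self, lam, percentile):
        assert poisson_threshold(lam, 1.0, percentile) == brute_force_poisson_k(
            lam, percentile
        )

    def test_zero_rate_threshold_zero(self):
        assert poisson_threshold(0.0, 1000.0, 0.95) == 0

    def test_frozen_example_lambda3(self):
        # P(X<=5)=0.9161 < 0.95 <= P(X<=6)=0.9665 at lambda 3
        assert poisson_threshold(3.0, 1.0, 0.95) == 6
        assert poisson_threshold(3.0, 1.0, 0.999) == brute_force_poisson_k(
            3.0, 0.999
        )

    def test_rate_times_area_scaling(self):
        assert poisson_threshold(0.003, 1000.0, 0.95) == poisson_threshold(
            3.0, 1.0, 0.95
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_threshold(-1.0, 1.0, 0.95)
        with pytest.raises(ValueError):
            poisson_threshold(1.0, 0.0, 0.95)
        with pytest.raises(ValueError):
            poisson_threshold(1.0, 1.0, 1.0)


def _toy_label_map():
    labels = np.zeros((40, 40), dtype=np.int32)
    labels[5:15, 5:15] = 1
    labels[25:35, 20:34] = 2
    areas = {1: 100, 2: 140}
    return NucleusLabelMap(labels=labels, core_labels=labels.copy(),
                           areas=areas)


def _pset(points, channel="p"):
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return PunctaSet(channel=channel, centroids=pts,
                     object_sizes=np.full(len(pts), 6, dtype=int))


class TestCounting:
    def test_no_puncta_all_zero(self):
        lm = _toy_label_map()
        cells = count_puncta_per_nucleus(lm, {"a": _pset([])})
        assert (cells["a"] == 0).all()
        assert cells.attrs["outside"]["a"] == 0

    def test_assignment_and_conservation(self):
        lm = _toy_label_map()
        pts = [(6, 6), (10, 12), (30, 25), (1, 1), (38, 2)]
        cells = count_puncta_per_nucleus(lm, {"a": _pset(pts)})
        assert cells.loc[1, "a"] == 2
        assert cells.loc[2, "a"] == 1
        assert cells.attrs["outside"]["a"] == 2
        assert cells["a"].sum() + cells.attrs["outside"]["a"] == len(pts)

    def test_truth_segmentation_reproduces_planted_counts(
        self, small_scene, truth_label_map
    ):
        """With perfect (truth-derived) segmentation and the planted puncta
        as detections, per-cell counts equal the truth table exactly."""
        _, truth = small_scene
        psets = {
            p: puncta_set_from_truth(truth, p)
            for p in truth.coexpression_spec.probes
        }
        cells = count_puncta_per_nucleus(truth_label_map, psets)
        for probe in psets:
            got = cells[probe].to_numpy()
            want = truth.per_cell_counts[probe].to_numpy()
            np.testing.assert_array_equal(got, want)

    def test_missing_probe_errors(self):
        lm = _toy_label_map()
        with pytest.raises((KeyError, ValueError)):
            count_puncta_per_nucleus(lm, {"a": None})


class TestBackgroundRate:
    def test_zero_outside_puncta(self):
        lm = _toy_label_map()
        assert background_rate(_pset([(6, 6)]), lm) == 0.0

    def test_direct_division(self):
        lm = _toy_label_map()
        n_bg_px = (lm.labels == 0).sum()
        rate = background_rate(_pset([(0, 0), (39, 39)]), lm)
        assert rate == pytest.approx(2 / n_bg_px)

    def test_uniform_background_rate_in_poisson_ci(self):
        rng = np.random.default_rng(11)
        labels = np.zeros((600, 600), dtype=np.int32)
        labels[100:140, 100:140] = 1
        lm = NucleusLabelMap(labels=labels, core_labels=labels.copy(),
                             areas={1: 1600})
        lam0 = 3e-4
        n_px = 600 * 600 - 1600
        n = rng.poisson(lam0 * n_px)
        pts = []
        while len(pts) < n:
            r, c = rng.integers(0, 600, size=2)
            if labels[r, c] == 0:
                pts.append((r, c))
        est = background_rate(_pset(pts), lm)
        lo, hi = stats.poisson.interval(0.99, lam0 * n_px)
        assert lo / n_px <= est <= hi / n_px

    def test_no_background_pixels_errors(self):
        labels = np.ones((10, 10), dtype=np.int32)
        lm = NucleusLabelMap(labels=labels, core_labels=labels.copy(),
                             areas={1: 100})
        with pytest.raises(ValueError):
            background_rate(_pset([]), lm)


class TestCalls:
    def _profiles(self):
        return pd.DataFrame(
            {"area": [1000, 1000, 1000], "a": [0, 30, 31]},
            index=pd.RangeIndex(1, 4, name="cell_id"),
        )

    def test_zero_counts_never_positive(self):
        called = call_positive(self._profiles(), {"a": 1e-3})
        assert not called.loc[1, "pos_a"]

    def test_override_threshold_strict_inequality(self):
        called = call_positive(self._profiles(), {"a": 0.0},
                               override_threshold={"a": 30})
        assert not called.loc[2, "pos_a"]  # 30 > 30 is false
        assert called.loc[3, "pos_a"]      # 31 > 30

    def test_thresholds_recorded_per_cell(self):
        called = call_positive(self._profiles(), {"a": 3e-3})
        assert (called["thr_a"] == poisson_threshold(3e-3, 1000, 0.95)).all()

    def test_call_accuracy_on_planted_scene(self, small_scene,
                                            truth_label_map):
        _, truth = small_scene
        probes = truth.coexpression_spec.probes
        psets = {p: puncta_set_from_truth(truth, p) for p in probes}
        cells = count_puncta_per_nucleus(truth_label_map, psets)
        rates = {p: background_rate(psets[p], truth_label_map) for p in probes}
        called = call_positive(cells, rates)
        for p in probes:
            got = called[f"pos_{p}"].to_numpy()
            want = truth.positivity[p].to_numpy()
            assert (got == want).mean() >= 0.95


class TestSummaries:
    def _called(self, cre, tgt, off):
        n = len(cre)
        df = pd.DataFrame(
            {
                "area": np.full(n, 1000),
                "iCre": np.asarray(cre) * 20,
                "Drd1a": np.asarray(tgt) * 20,
                "Adora2a": np.asarray(off) * 20,
                "pos_iCre": np.asarray(cre, bool),
                "pos_Drd1a": np.asarray(tgt, bool),
                "pos_Adora2a": np.asarray(off, bool),
            }
        )
        return df

    def test_subset_gives_full_specificity(self):
        df = self._called([1, 1, 0], [1, 1, 1], [0, 0, 0])
        s = specificity_consistency(df, "iCre", "Drd1a", "Adora2a")
        assert s.specificity == 100.0

    def test_direct_ratio(self):
        cre = [1] * 90 + [0] * 10
        tgt = [1] * 85 + [0] * 15
        df = self._called(cre, tgt, [0] * 100)
        s = specificity_consistency(df, "iCre", "Drd1a", "Adora2a")
        assert s.specificity == pytest.approx(100 * 85 / 90)

    def test_zero_denominator_is_nan_not_zero(self):
        df = self._called([0, 0], [1, 0], [0, 0])
        s = specificity_consistency(df, "iCre", "Drd1a", "Adora2a")
        assert math.isnan(s.specificity)
        assert not math.isnan(s.consistency)

    def test_probe_swap_exchanges_metric_pairs(self):
        rng = np.random.default_rng(5)
        df = self._called(rng.integers(0, 2, 50), rng.integers(0, 2, 50),
                          rng.integers(0, 2, 50))
        a = specificity_consistency(df, "iCre", "Drd1a", "Adora2a")
        b = specificity_consistency(df, "iCre", "Adora2a", "Drd1a")
        assert a.specificity == b.offtarget_specificity
        assert a.consistency == b.offtarget_consistency
        assert a.offtarget_specificity == b.specificity

    def test_planted_consistency_within_3se_at_n2000(self):
        """Calls drawn from the planted joint recover P(cre+|target+)=0.8."""
        spec = cv.CoexpressionSpec.from_rates(consistency=0.8)
        keys, probs = spec.states()
        rng = np.random.default_rng(42)
        states = keys[rng.choice(len(keys), size=2000, p=probs)]
        df = self._called(states[:, 2], states[:, 0], states[:, 1])
        s = specificity_consistency(df, "iCre", "Drd1a", "Adora2a")
        n_t = states[:, 0].sum()
        se = 100 * math.sqrt(0.8 * 0.2 / n_t)
        assert abs(s.consistency - 80.0) <= 3 * se


class TestPairwiseR2:
    def _df(self, a, b):
        return pd.DataFrame({"area": np.full(len(a), 100), "x": a, "y": b})

    def test_proportional_counts_r2_one(self):
        df = self._df([1, 2, 3, 4], [2, 4, 6, 8])
        assert pairwise_r2(df, "x", "y") == pytest.approx(1.0)

    def test_independent_counts_near_zero(self):
        rng = np.random.default_rng(9)
        df = self._df(rng.poisson(10, 2000), rng.poisson(10, 2000))
        assert pairwise_r2(df, "x", "y") < 0.05

    def test_four_cell_hand_computed_table(self):
        # a=(1,2,3,4), b=(2,4,6,9): r^2 = 11.5^2 / (5 * 26.75)
        df = self._df([1, 2, 3, 4], [2, 4, 6, 9])
        assert pairwise_r2(df, "x", "y") == pytest.approx(132.25 / 133.75,
                                                          abs=1e-12)

    def test_degenerate_inputs_flagged(self):
        with pytest.raises(ValueError):
            pairwise_r2(self._df([1, 1, 1], [1, 2, 3]), "x", "y")
        with pytest.raises(ValueError):
            pairwise_r2(self._df([1, 2], [1, 2]), "x", "y")
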