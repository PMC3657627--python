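"""Steps 1-3: skewness coefficient, k-means voxel filter, tissue masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsnselect import SelectionConfig
from rsnselect.filters import (
    ClusteringError,
    choose_k,
    cluster_filter,
    mean_silhouette,
    pearson_coefficient,
    silhouette_value,
    skewness_filter,
    tissue_filter,
)
from rsnselect.model import ICADecomposition, TissueMaps


def _decomposition_from_rows(rows, n_time=16, tr=2.0):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    k, m = rows.shape
    grid = (m, 1, 1)
    mask = np.ones(grid, dtype=bool)
    rng = np.random.default_rng(0)
    return ICADecomposition(
        mixing=rng.normal(size=(n_time, k)), sources=rows, mask=mask, tr_seconds=tr
    )


class TestPearsonCoefficient:
    def test_symmetric_distribution_is_zero(self):
        assert pearson_coefficient([-1, 0, 1]) == 0.0

    def test_hand_computed_value(self):
        # mean 0.25, median 0, sample sigma 0.5 -> 3 * 0.25 / 0.5 = 1.5
        assert pearson_coefficient([0, 0, 0, 1]) == pytest.approx(1.5)

    def test_constant_input_is_zero(self):
        assert pearson_coefficient([5.0, 5.0, 5.0]) == 0.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            pearson_coefficient([1.0])

    def test_large_gaussian_sample_is_near_zero(self):
        draws = np.random.default_rng(7).normal(size=100_000)
        assert abs(pearson_coefficient(draws)) < 0.05

    @settings(max_examples=50, derandomize=True)
    @given(
        values=st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40),
        scale=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance_and_sign_antisymmetry(self, values, scale):
        values = np.asarray(values)
        base = pearson_coefficient(values)
        assert pearson_coefficient(values * scale) == pytest.approx(base, abs=1e-9)
        assert pearson_coefficient(-values) == pytest.approx(-base, abs=1e-9)


class TestSkewnessFilter:
    def test_threshold_is_median_and_strictly_below_rejected(self):
        # rows engineered so |coefficients| are distinct; TH = their median
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(4, 70))
        for i, n_spikes in enumerate((0, 1, 8, 20)):
            rows[i, :n_spikes] += 30.0  # progressively stronger right skew
        dec = _decomposition_from_rows(rows)
        coeffs = np.abs([pearson_coefficient(r) for r in dec.sources])
        th = np.median(coeffs)
        states = skewness_filter(dec, SelectionConfig())
        for state, c in zip(states, coeffs):
            assert state.is_candidate == (c >= th)
        assert sum(s.is_candidate for s in states) == 2

    def test_identical_rows_all_survive(self):
        row = np.random.default_rng(0).normal(size=30)
        dec = _decomposition_from_rows(np.tile(row, (4, 1)))
        states = skewness_filter(dec, SelectionConfig())
        assert all(s.is_candidate for s in states)  # all equal TH -> none strictly below

    def test_single_component_survives(self):
        dec = _decomposition_from_rows(np.random.default_rng(1).normal(size=(1, 30)))
        states = skewness_filter(dec, SelectionConfig())
        assert states[0].is_candidate

    def test_override_threshold_used(self):
        dec = _decomposition_from_rows(np.random.default_rng(1).normal(size=(3, 50)))
        states = skewness_filter(
            dec, SelectionConfig(skewness_threshold_override=100.0)
        )
        assert all(s.status == "rejected_skewness" for s in states)

    def test_signed_mode_discards_left_skew(self):
        rng = np.random.default_rng(5)
        right = np.abs(rng.normal(size=100)) * 5 + rng.normal(size=100) * 0.1
        left = -right  # exactly mirrored -> coefficients are exact negatives
        dec = _decomposition_from_rows(np.vstack([left, right]))
        signed = skewness_filter(dec, SelectionConfig(skewness_mode="signed"))
        assert not signed[0].is_candidate and signed[1].is_candidate
        absolute = skewness_filter(dec, SelectionConfig(skewness_mode="absolute"))
        assert all(s.is_candidate for s in absolute)  # equal magnitudes tie at TH

    def test_sources_unchanged_by_filtering(self):
        dec = _decomposition_from_rows(np.random.default_rng(2).normal(size=(4, 40)))
        before = dec.sources.copy()
        skewness_filter(dec, SelectionConfig())
        assert np.array_equal(dec.sources, before)


class TestSilhouette:
    def test_hand_computed_example(self):
        values = np.array([0.0, 1.0, 10.0, 11.0])
        labels = np.array([0, 0, 1, 1])
        assert silhouette_value(0, values, labels) == pytest.approx((10.5 - 1) / 10.5)

    def test_coincident_points_score_one(self):
        values = np.array([2.0, 2.0, 50.0, 60.0])
        labels = np.array([0, 0, 1, 1])
        assert silhouette_value(0, values, labels) == 1.0

    def test_singleton_cluster_scores_zero(self):
        values = np.array([0.0, 10.0, 11.0])
        labels = np.array([0, 1, 1])
        assert silhouette_value(0, values, labels) == 0.0

    def test_single_cluster_raises(self):
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette_value(0, np.array([1.0, 2.0]), np.array([0, 0]))

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**16), n=st.integers(6, 50), k=st.integers(2, 4))
    def test_mean_silhouette_matches_direct_formula(self, seed, n, k):
        """The prefix-sum fast path equals averaging the direct per-point formula."""
        rng = np.random.default_rng(seed)
        values = rng.normal(size=n)
        labels = rng.integers(0, k, size=n)
        if np.unique(labels).size < 2:
            labels[0], labels[1] = 0, 1
        direct = np.mean([silhouette_value(j, values, labels) for j in range(n)])
        assert mean_silhouette(values, labels) == pytest.approx(direct, abs=1e-12)

    def test_subsampled_mean_silhouette_is_deterministic(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=500)
        labels = (values > 0).astype(int)
        a = mean_silhouette(values, labels, subsample=100, seed=3)
        b = mean_silhouette(values, labels, subsample=100, seed=3)
        assert a == b


class TestChooseK:
    def test_three_clumps_prefer_k3(self):
        values = np.array([0.0, 0.1, 5.0, 5.1, 10.0, 10.2])
        sol = choose_k(values, SelectionConfig(k_candidates=(2, 3)))
        assert sol.k == 3
        assert sorted(np.round(sol.centroids, 2)) == [0.05, 5.05, 10.1]

    def test_two_point_masses_give_k2(self):
        values = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        sol = choose_k(values, SelectionConfig())
        assert sol.k == 2
        assert sorted(sol.centroids) == [0.0, 10.0]
        assert sol.mean_silhouette == 1.0

    def test_degenerate_values_raise(self):
        values = np.full(20, 3.0)
        with pytest.raises(ClusteringError):
            choose_k(values, SelectionConfig())

    def test_centroids_are_member_means(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(5, 0.1, 30)])
        sol = choose_k(values, SelectionConfig())
        for c in range(sol.k):
            assert sol.centroids[c] == pytest.approx(values[sol.labels == c].mean())

    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=300)
        a = choose_k(values, SelectionConfig(kmeans_seed=5))
        b = choose_k(values, SelectionConfig(kmeans_seed=5))
        assert a.k == b.k
        assert np.array_equal(a.labels, b.labels)
        assert a.mean_silhouette == b.mean_silhouette


class TestClusterFilter:
    def _state_and_dec(self, values, mixing_cols=1):
        dec = _decomposition_from_rows(np.asarray(values, dtype=float)[None, :])
        states = skewness_filter(dec, SelectionConfig(skewness_threshold_override=-np.inf))
        return states[0], dec

    def test_low_value_cluster_removed(self):
        state, dec = self._state_and_dec([0.0, 1.0, 10.0, 11.0])
        cluster_filter(state, dec, SelectionConfig(k_candidates=(2,)))
        assert state.retained_voxels.tolist() == [False, False, True, True]

    def test_negative_cluster_kept_when_farther_from_zero(self):
        state, dec = self._state_and_dec([-10.0, -11.0, 0.0, 1.0])
        cluster_filter(state, dec, SelectionConfig(k_candidates=(2,)))
        assert state.retained_voxels.tolist() == [True, True, False, False]

    def test_near_degenerate_values_do_not_crash(self):
        state, dec = self._state_and_dec([5.0] * 10 + [5.001] * 10)
        cluster_filter(state, dec, SelectionConfig(k_candidates=(2,)))
        assert state.retained_count() == 10  # the smaller-|centroid| half removed
        assert state.is_candidate

    def test_constant_values_demote_to_rejected_empty(self):
        state, dec = self._state_and_dec([3.0] * 10)
        cluster_filter(state, dec, SelectionConfig())
        assert state.status == "rejected_empty"

    def test_retained_set_shrinks(self):
        rng = np.random.default_rng(8)
        values = np.concatenate([rng.normal(0, 0.2, 50), rng.normal(8, 0.5, 20)])
        state, dec = self._state_and_dec(values)
        before = state.retained_count()
        cluster_filter(state, dec, SelectionConfig())
        assert 0 < state.retained_count() < before


class TestTissueFilter:
    def _setup(self, wm_val, csf_val, m=4):
        grid = (m, 1, 1)
        dec = _decomposition_from_rows(np.arange(1.0, m + 1)[None, :])
        tissue = TissueMaps(
            gm=np.zeros(grid),
            wm=np.full(grid, wm_val),
            csf=np.full(grid, csf_val),
        )
        states = skewness_filter(dec, SelectionConfig(skewness_threshold_override=-np.inf))
        return states[0], tissue, dec

    def test_high_wm_probability_removes_voxel(self):
        state, tissue, dec = self._setup(wm_val=0.95, csf_val=0.0)
        tissue_filter(state, tissue, SelectionConfig(), dec.mask)
        assert state.status == "rejected_empty"  # every voxel cancelled

    def test_both_below_threshold_retained_under_either_map(self):
        state, tissue, dec = self._setup(wm_val=0.89, csf_val=0.89)
        tissue_filter(state, tissue, SelectionConfig(), dec.mask)
        assert state.retained_count() == 4

    def test_summed_rule_removes_when_combined(self):
        state, tissue, dec = self._setup(wm_val=0.5, csf_val=0.45)
        tissue_filter(state, tissue, SelectionConfig(tissue_rule="summed"), dec.mask)
        assert state.status == "rejected_empty"

    def test_all_zero_tissue_is_identity(self):
        state, tissue, dec = self._setup(wm_val=0.0, csf_val=0.0)
        before = state.retained_voxels.copy()
        tissue_filter(state, tissue, SelectionConfig(), dec.mask)
        assert np.array_equal(state.retained_voxels, before)

    def test_grid_mismatch_raises(self):
        state, _, dec = self._setup(0.0, 0.0)
        bad = TissueMaps(
            gm=np.zeros((2, 2, 2)), wm=np.zeros((2, 2, 2)), csf=np.zeros((2, 2, 2))
        )
        with pytest.raises(ValueError, match="grid"):
            tissue_filter(state, bad, SelectionConfig(), dec.mask)
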