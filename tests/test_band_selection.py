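import math

import numpy as np
import pytest

import leafndiff as L
from leafndiff.band_selection import (N_INTERVALS, sipls_joint_interval,
                                      spa_chain, spa_project)


def _gram_schmidt_step(X, pivot, cols):
    """Independent single-step Gram-Schmidt oracle."""
    p = X[:, pivot]
    out = []
    for j in cols:
        x = X[:, j]
        out.append(x - (x @ p) / (p @ p) * p)
    return np.column_stack(out)


class TestSpaProjection:
    def test_matches_gram_schmidt_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 8))
        S = [0, 2, 3, 5, 7]
        got = spa_project(X, 4, S)
        assert np.allclose(got, _gram_schmidt_step(X, 4, S), atol=1e-10)

    def test_orthogonal_column_unchanged(self):
        X = np.zeros((4, 2))
        X[:, 0] = [1, 0, 0, 0]
        X[:, 1] = [0, 1, 2, 3]
        assert np.allclose(spa_project(X, 0, [1])[:, 0], X[:, 1])

    def test_projection_onto_self_vanishes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        X[:, 2] = X[:, 0]
        assert np.max(np.abs(spa_project(X, 0, [2]))) < 1e-12

    def test_all_projections_orthogonal_to_pivot(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 6))
        proj = spa_project(X, 1, [0, 2, 3, 4, 5])
        dots = np.abs(X[:, 1] @ proj) / np.linalg.norm(X[:, 1])
        assert np.max(dots / np.linalg.norm(proj, axis=0)) < 1e-8

    def test_zero_pivot_raises(self):
        X = np.zeros((5, 2))
        X[:, 1] = 1.0
        with pytest.raises(ValueError):
            spa_project(X, 0, [1])


class TestSpaChain:
    @pytest.mark.parametrize("J,N", [(10, 3), (12, 5), (20, 7), (8, 2)])
    def test_projection_count_formula(self, J, N):
        """An instrumented run performs exactly (N-1)(J - N/2) projections."""
        rng = np.random.default_rng(J * N)
        X = rng.normal(size=(25, J))
        _, n_proj = spa_chain(X, 0, N)
        assert n_proj == (N - 1) * (J - N / 2)

    def test_single_band_chain_no_projections(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 6))
        chain, n_proj = spa_chain(X, 4, 1)
        assert chain == [4] and n_proj == 0

    def test_chain_matches_exhaustive_argmax_oracle(self):
        """Each step must pick the band maximizing the projected norm."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 12))
            chain, _ = spa_chain(X, seed % 12, 5)
            # independent re-run with explicit per-column projections
            Xw = X.copy()
            expect = [seed % 12]
            for _ in range(4):
                S = [j for j in range(12) if j not in expect]
                p = Xw[:, expect[-1]]
                norms = {}
                for j in S:
                    v = Xw[:, j] - (Xw[:, j] @ p) / (p @ p) * p
                    Xw[:, j] = v
                    norms[j] = np.linalg.norm(v)
                expect.append(max(S, key=lambda j: norms[j]))
            assert chain == expect

    def test_chain_entries_distinct(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 15))
        chain, _ = spa_chain(X, 2, 10)
        assert len(set(chain)) == 10

    def test_n_beyond_rank_raises(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 10))
        with pytest.raises(ValueError):
            spa_chain(X, 0, 8)


class TestSpaSelect:
    def test_planted_bands_recovered(self):
        X, y = L.make_planted_problem(189, 600, (50, 200, 400), seed=0)
        sel = L.spa_select(X, y, candidate_N_range=(5,), seed=0)
        assert set(sel) >= {50, 200, 400}
        assert len(sel) <= 5

    def test_fixed_candidate_five_returns_five_bands(self):
        """With five informative bands and N fixed at 5, all are kept."""
        planted = (40, 120, 260, 380, 520)
        X, y = L.make_planted_problem(189, 600, planted, seed=1)
        sel = L.spa_select(X, y, candidate_N_range=(5,), seed=1)
        assert len(sel) == 5
        assert set(sel) == set(planted)

    def test_pure_noise_returns_valid_subset(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 40))
        y = rng.normal(size=60)
        sel = L.spa_select(X, y, candidate_N_range=(3,), seed=5,
                           k0_candidates=range(0, 40, 4))
        assert 1 <= len(sel) <= 3
        assert all(0 <= b < 40 for b in sel)


class TestPca:
    def test_low_rank_data_has_vanishing_trailing_components(self, split_diffs):
        import dataclasses
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 600))
        coefs = rng.normal(size=(len(split_diffs), 2))
        flat = dataclasses.replace(split_diffs, delta_r=coefs @ basis)
        result, _ = L.pca_extract(flat, n_components=5)
        assert np.all(result.explained_variance[2:] < 1e-10)

    def test_explained_variance_non_increasing(self, split_diffs):
        result, _ = L.pca_extract(split_diffs, n_components=5)
        assert np.all(np.diff(result.explained_variance) <= 1e-12)

    def test_training_scores_have_diagonal_covariance(self, split_diffs):
        _, feats = L.pca_extract(split_diffs, n_components=5)
        C = np.cov(feats.X_train, rowvar=False)
        off = C - np.diag(np.diag(C))
        assert np.max(np.abs(off)) < 1e-8

    def test_rank5_data_reconstructs_exactly(self, split_diffs):
        import dataclasses
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(5, 600))
        coefs = rng.normal(size=(len(split_diffs), 5))
        flat = dataclasses.replace(split_diffs, delta_r=coefs @ basis)
        result, feats = L.pca_extract(flat, n_components=5)
        recon = feats.X @ result.loadings.T + result.mean
        assert np.max(np.abs(recon - flat.delta_r)) < 1e-8

    def test_validation_scores_use_training_loadings(self, split_diffs):
        result, feats = L.pca_extract(split_diffs, n_components=5)
        expect = (split_diffs.delta_r[split_diffs.validation_mask]
                  - result.mean) @ result.loadings
        assert np.allclose(feats.X_val, expect)

    def test_excessive_components_raise(self, split_diffs):
        import dataclasses
        small = dataclasses.replace(
            split_diffs,
            delta_r=split_diffs.delta_r[:6], delta_n=split_diffs.delta_n[:6],
            sample_ids=split_diffs.sample_ids[:6],
            split=np.array(["train"] * 6, dtype=object))
        with pytest.raises(ValueError):
            L.pca_extract(small, n_components=10)


class TestIntervals:
    @pytest.mark.parametrize("k,lo,hi", [(1, 401, 420), (5, 481, 500),
                                         (9, 561, 580), (10, 581, 600),
                                         (16, 701, 720), (30, 981, 1000)])
    def test_interval_bounds(self, k, lo, hi):
        assert L.interval_bounds(k) == (lo, hi)

    @pytest.mark.parametrize("k", [0, 31, -3])
    def test_out_of_range_raises(self, k):
        with pytest.raises(ValueError):
            L.interval_bounds(k)

    def test_intervals_tile_grid_exactly(self):
        ivs = L.iriv_intervals()
        assert len(ivs) == N_INTERVALS
        assert np.array_equal(np.concatenate(ivs), np.arange(600))


class TestSipls:
    def test_small_grid_planted_recovery(self):
        """Exhaustive interval search finds the intervals carrying signal."""
        intervals = [np.arange(k * 20, (k + 1) * 20) for k in range(6)]
        X, y = L.make_planted_problem(100, 120, (25, 85), seed=2)
        res = sipls_joint_interval(X, y, n_intervals_joint=2, seed=2,
                                   intervals=intervals)
        assert res.combo == (2, 5)  # 1-based intervals containing 25 and 85
        assert res.n_combinations == math.comb(6, 2)

    def test_seeded_reproducibility(self):
        intervals = [np.arange(k * 20, (k + 1) * 20) for k in range(6)]
        X, y = L.make_planted_problem(80, 120, (10, 70), seed=3,
                                      noise_sd=0.5)
        a = sipls_joint_interval(X, y, n_intervals_joint=2, seed=7,
                                 intervals=intervals)
        b = sipls_joint_interval(X, y, n_intervals_joint=2, seed=7,
                                 intervals=intervals)
        assert a.combo == b.combo and a.rmsecv == b.rmsecv

    def test_full_grid_planted_recovery_and_count(self):
        """All C(30,4)=27405 combinations are enumerated and the planted
        joint interval wins on the full 600-band grid."""
        X, y = L.make_planted_problem(189, 600, (85, 165, 185, 305), seed=3)
        res = sipls_joint_interval(X, y, seed=3)
        assert res.n_combinations == math.comb(30, 4) == 27405
        assert res.combo == (5, 9, 10, 16)

    def test_too_many_folds_raise(self):
        X, y = L.make_planted_problem(8, 120, (10,), seed=0)
        intervals = [np.arange(k * 20, (k + 1) * 20) for k in range(6)]
        with pytest.raises(ValueError):
            sipls_joint_interval(X, y, n_intervals_joint=2, folds=10,
                                 intervals=intervals)


class TestIrivIterate:
    def test_planted_bands_retained_noise_dropped(self):
        """Informative bands survive, at least 80% of noise bands fall."""
        for seed in range(10):
            X, y = L.make_planted_problem(150, 40, (10, 30), seed=seed)
            res = L.iriv_iterate(X, y, list(range(40)), seed=seed)
            assert {10, 30} <= set(res.retained)
            noise_kept = len(set(res.retained) - {10, 30})
            assert noise_kept <= 0.2 * 38

    def test_single_band_returned_unchanged(self):
        X, y = L.make_planted_problem(50, 40, (10,), seed=0)
        assert L.iriv_iterate(X, y, [10]).retained == [10]

    def test_retained_is_subset_of_input(self):
        X, y = L.make_planted_problem(100, 40, (5, 20), seed=4, noise_sd=0.5)
        bands = list(range(0, 40, 2))
        res = L.iriv_iterate(X, y, bands, seed=4)
        assert set(res.retained) <= set(bands)

    def test_round_history_records_classes(self):
        X, y = L.make_planted_problem(100, 40, (10, 30), seed=1)
        res = L.iriv_iterate(X, y, list(range(40)), seed=1)
        assert len(res.history) >= 1
        assert set(res.history[0]) >= {"round", "dmean", "p_values", "classes"}


class TestCorrelationPrune:
    def test_identical_bands_collapse_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=80)
        X = np.column_stack([x, x, rng.normal(size=80)])
        y = x + rng.normal(size=80) * 0.1
        assert len(L.correlation_prune(X, y, [0, 1])) == 1

    def test_uncorrelated_bands_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 4))
        y = rng.normal(size=100)
        assert L.correlation_prune(X, y, [0, 1, 2, 3]) == [0, 1, 2, 3]

    def test_clique_plus_singleton_leaves_two(self):
        """Three mutually correlated bands and one independent band."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=120)
        X = np.column_stack([base + 0.01 * rng.normal(size=120)
                             for _ in range(3)] + [rng.normal(size=120)])
        y = base + 0.1 * rng.normal(size=120)
        kept = L.correlation_prune(X, y, [0, 1, 2, 3])
        assert len(kept) == 2 and 3 in kept

    def test_representative_is_most_correlated_with_target(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=200)
        X = np.column_stack([base + 0.05 * rng.normal(size=200),
                             base + 0.001 * rng.normal(size=200)])
        y = base
        assert L.correlation_prune(X, y, [0, 1]) == [1]


def test_iriv_pipeline_features_align_with_split(split_diffs):
    """End-to-end IRIV reduction on a small custom interval set."""
    feats = L.spa_features(split_diffs, candidate_N_range=(3,), seed=0)
    assert feats.X.shape == (len(split_diffs), len(feats.meta["bands"]))
    assert feats.X_train.shape[0] == int(split_diffs.train_mask.sum())
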