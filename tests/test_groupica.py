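"""Decomposition schemes: recovery oracles, alignment, dual regression."""

import itertools

import numpy as np
import pytest
from scipy import stats

from netseg import (CohortSimConfig, default_sources, iva_l, make_grid,
                    raicar, simulate_cohort, tcgica)
from netseg.fixtures import SourceSpec
from netseg.groupica import (SubjectICA, dual_regression,
                             fit_single_subject_ica, greedy_align,
                             raicar_align)
from conftest import matched_abs_corr


def best_permutation_abs_corr(maps, truth):
    """Exhaustive-permutation matching oracle (small K only)."""
    K = truth.shape[0]
    best = -1.0
    C = np.abs(np.corrcoef(maps, truth)[:K, K:])
    for perm in itertools.permutations(range(K)):
        score = min(C[i, perm[i]] for i in range(K))
        best = max(best, score)
    return best


class TestSingleSubjectICA:
    def test_recovers_three_noiseless_sources(self, small_cohort):
        cohort, truth = small_cohort
        res = fit_single_subject_ica(cohort[0], model_order=3, seed=0)
        assert best_permutation_abs_corr(res.maps, truth.subject_maps[0]) > 0.95
        assert res.converged

    def test_single_component_on_rank_one_data(self, grid16):
        src = [SourceSpec("blob", [((8, 9, 8), 2, 1.0)])]
        cfg = CohortSimConfig(n_subjects=1, n_timepoints=60, noise_sd=0.0,
                              jitter_sd_voxels=0.0, baseline=0.0, seed=0)
        cohort, truth = simulate_cohort(grid16, src, cfg)
        res = fit_single_subject_ica(cohort[0], model_order=1, seed=0)
        r = np.corrcoef(res.maps[0], truth.subject_maps[0, 0])[0, 1]
        assert abs(r) > 0.999

    def test_same_seed_identical_output(self, small_cohort):
        cohort, _ = small_cohort
        a = fit_single_subject_ica(cohort[1], 3, seed=5)
        b = fit_single_subject_ica(cohort[1], 3, seed=5)
        assert np.array_equal(a.maps, b.maps)
        assert np.array_equal(a.timecourses, b.timecourses)

    def test_order_beyond_rank_is_reduced_with_warning(self, small_cohort):
        cohort, _ = small_cohort  # noiseless: rank = 3 sources
        with pytest.warns(UserWarning, match="rank"):
            res = fit_single_subject_ica(cohort[0], model_order=10, seed=0)
        assert res.maps.shape[0] <= 4

    def test_maps_have_positive_skew(self, small_cohort):
        cohort, _ = small_cohort
        res = fit_single_subject_ica(cohort[0], 3, seed=0)
        assert (stats.skew(res.maps, axis=1) >= 0).all()


class TestDualRegression:
    def test_exact_linear_model_recovered(self):
        rng = np.random.default_rng(0)
        K, T, V = 4, 50, 300
        G = rng.standard_normal((K, V))
        tc = rng.standard_normal((T, K))
        tc /= tc.std(axis=0)  # unit variance: stage-2 scale is then exact
        X = tc @ G
        tcs, maps = dual_regression(G, X)
        np.testing.assert_allclose(tcs, tc, atol=1e-6)
        np.testing.assert_allclose(maps, G, atol=1e-6)

    def test_matches_pseudoinverse_oracle_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            K, T, V = 5, 40, 200
            G = rng.standard_normal((K, V))
            X = rng.standard_normal((T, V))
            tcs, maps = dual_regression(G, X)
            tc_o = (np.linalg.pinv(G.T) @ X.T).T
            D = tc_o / tc_o.std(axis=0)
            maps_o = np.linalg.pinv(D) @ X
            np.testing.assert_allclose(tcs, tc_o, atol=1e-8)
            np.testing.assert_allclose(maps, maps_o, atol=1e-8)

    def test_single_map_stage1_is_weighted_spatial_mean(self):
        rng = np.random.default_rng(2)
        G = rng.standard_normal((1, 150))
        X = rng.standard_normal((30, 150))
        tcs, _ = dual_regression(G, X)
        proj = X @ G[0] / (G[0] @ G[0])  # closed-form projection
        np.testing.assert_allclose(tcs[:, 0], proj, atol=1e-10)

    def test_collinear_design_raises_with_pair_named(self):
        rng = np.random.default_rng(3)
        g = rng.standard_normal(100)
        G = np.stack([g, g * 2.0, rng.standard_normal(100)])
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            dual_regression(G, rng.standard_normal((20, 100)))


class TestTCgICA:
    def test_recovers_all_noiseless_sources(self, small_cohort):
        cohort, truth = small_cohort
        d = tcgica(cohort, model_order=3, seed=0)
        assert best_permutation_abs_corr(d.group_maps, truth.clean_maps) > 0.95

    def test_group_maps_are_z_scored(self, small_cohort):
        cohort, _ = small_cohort
        d = tcgica(cohort, 3, seed=0)
        np.testing.assert_allclose(d.group_maps.mean(axis=1), 0, atol=1e-6)
        np.testing.assert_allclose(d.group_maps.std(axis=1), 1, atol=1e-6)

    def test_low_model_order_merges_coupled_posterior_sources(self, grid24,
                                                              templates24):
        """With a strongly coupled PMN/pDMN pair, smoothing plus a model
        order below the source count funnels both networks into the same
        component (post-hoc template-correlation argmax)."""
        from netseg.preprocess import smooth_spatial
        from netseg.selection import pick_candidates

        src = default_sources(grid24)[:4]
        cfg = CohortSimConfig(n_subjects=4, n_timepoints=140, noise_sd=0.2,
                              jitter_sd_voxels=0.0, seed=5,
                              tc_corr=(("PMN", "pDMN", 0.85),
                                       ("aDMN", "pDMN", 0.4),
                                       ("PMN", "aDMN", 0.3)))
        cohort, _ = simulate_cohort(grid24, src, cfg)
        smoothed = [smooth_spatial(s, 6.0) for s in cohort]
        d = tcgica(smoothed, model_order=2, seed=0)
        cands = pick_candidates(d, templates24)
        assert cands["PMN"][0] == cands["pDMN"][0]

    def test_subject_order_permutation_changes_nothing(self, small_cohort):
        cohort, _ = small_cohort
        a = tcgica(list(cohort), 3, seed=0)
        b = tcgica(list(cohort)[::-1], 3, seed=0)
        assert matched_abs_corr(a.group_maps, b.group_maps).min() > 0.999


class TestRaicarAlignment:
    def _identical_icas(self, n_subjects=3, K=3, V=400, seed=0):
        rng = np.random.default_rng(seed)
        maps = rng.standard_normal((K, V))
        maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
        return [SubjectICA(maps=maps.copy(),
                           timecourses=rng.standard_normal((K, 30)),
                           converged=True, n_restarts=0)
                for _ in range(n_subjects)]

    def test_identical_subjects_align_perfectly(self, grid16):
        icas = self._identical_icas(V=grid16.n_voxels)
        d = raicar_align(icas, grid16)
        assert d.n_components == 3
        np.testing.assert_allclose(d.reproducibility, 1.0, atol=1e-10)
        # one member per subject per group: no NaN rows anywhere
        assert not np.isnan(d.subject_maps).any()

    def test_group_maps_are_z_scored(self, grid16):
        d = raicar_align(self._identical_icas(V=grid16.n_voxels), grid16)
        np.testing.assert_allclose(d.group_maps.mean(axis=1), 0, atol=1e-6)
        np.testing.assert_allclose(d.group_maps.std(axis=1), 1, atol=1e-6)

    def test_greedy_matches_exhaustive_assignment(self):
        # 2 subjects x 2 components, block-structured similarity
        subject_of = np.array([0, 0, 1, 1])
        sim = np.zeros((4, 4))
        pairs = {(0, 2): 0.9, (1, 3): 0.8, (0, 3): 0.1, (1, 2): 0.2}
        for (i, j), v in pairs.items():
            sim[i, j] = sim[j, i] = v
        groups = greedy_align(sim, subject_of, floor=0.05)
        # exhaustive search over the two possible matchings
        options = [[(0, 2), (1, 3)], [(0, 3), (1, 2)]]
        best = max(options, key=lambda opt: sum(pairs[p] for p in opt))
        assert groups == [sorted(p) for p in best]

    def test_greedy_three_subjects_blocks(self):
        # 3 subjects x 2 comps; comp 0s mutually similar, comp 1s likewise
        subject_of = np.array([0, 0, 1, 1, 2, 2])
        sim = np.full((6, 6), 0.05)
        strong = [0, 2, 4]
        weak = [1, 3, 5]
        for grp, v in ((strong, 0.9), (weak, 0.7)):
            for i in grp:
                for j in grp:
                    if i != j:
                        sim[i, j] = v
        sim[subject_of[:, None] == subject_of[None, :]] = 0.0
        groups = greedy_align(sim, subject_of, floor=0.2)
        assert groups == [strong, weak]

    def test_floor_too_high_gives_empty_decomposition(self, grid16):
        rng = np.random.default_rng(4)
        icas = [SubjectICA(maps=rng.standard_normal((2, grid16.n_voxels)),
                           timecourses=rng.standard_normal((2, 30)),
                           converged=True, n_restarts=0) for _ in range(2)]
        with pytest.warns(UserWarning, match="floor"):
            d = raicar_align(icas, grid16, floor=0.99)
        assert d.n_components == 0

    def test_full_pipeline_recovers_sources(self, small_cohort):
        cohort, truth = small_cohort
        d = raicar(cohort, model_order=3, seed=0)
        assert best_permutation_abs_corr(d.group_maps, truth.clean_maps) > 0.9


class TestIVA:
    def test_single_subject_degenerates_to_laplacian_ica(self, grid16):
        src = default_sources(grid16, n_background=0)[:2]
        cfg = CohortSimConfig(n_subjects=1, n_timepoints=100, noise_sd=0.0,
                              jitter_sd_voxels=0.0, baseline=0.0,
                              tc_corr=(), seed=6)
        cohort, truth = simulate_cohort(grid16, src, cfg)
        d = iva_l(cohort, model_order=2, seed=0)
        assert best_permutation_abs_corr(d.group_maps, truth.clean_maps) > 0.9

    def test_components_aligned_across_subjects(self, small_cohort):
        cohort, truth = small_cohort
        d = iva_l(cohort, model_order=3, seed=0)
        K = truth.clean_maps.shape[0]
        # per subject, which true source each component matches best
        for k in range(K):
            matches = []
            for s in range(len(cohort)):
                rs = [abs(np.corrcoef(d.subject_maps[s, k],
                                      truth.subject_maps[s, j])[0, 1])
                      for j in range(K)]
                assert max(rs) > 0.9
                matches.append(int(np.argmax(rs)))
            assert len(set(matches)) == 1  # same source in every subject

    def test_group_maps_are_z_scored(self, small_cohort):
        cohort, _ = small_cohort
        d = iva_l(cohort, 3, seed=0)
        np.testing.assert_allclose(d.group_maps.mean(axis=1), 0, atol=1e-6)
        np.testing.assert_allclose(d.group_maps.std(axis=1), 1, atol=1e-6)

    def test_nonconvergence_is_surfaced_not_silent(self, small_cohort):
        cohort, _ = small_cohort
        d = iva_l(cohort, 3, seed=0, max_iter=3)
        assert d.diagnostics["converged"] is False
        assert d.diagnostics["n_iterations"] == 3
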