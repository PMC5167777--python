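"""The template-matching identification procedure."""

import numpy as np
import pytest

from netseg.core import zscore_masked
from netseg.groupica import Decomposition
from netseg.selection import (FOUND, FOUND_AS_POSTERIOR, NOT_FOUND,
                              SelectionConfig, anchors_included,
                              pick_candidates, select_networks,
                              template_correlation)


def decomp_from_volumes(grid, volumes, algorithm="RAICAR"):
    maps = np.stack([zscore_masked(grid.extract(np.asarray(v, dtype=float)))
                     for v in volumes])
    K = maps.shape[0]
    return Decomposition(algorithm=algorithm, model_order=K, grid=grid,
                         group_maps=maps,
                         subject_maps=np.empty((0, K, grid.n_voxels)),
                         subject_timecourses=np.empty((0, K, 1)))


def pearson_two_pass(x, y):
    """Independent brute-force Pearson oracle."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


class TestTemplateCorrelation:
    def test_self_correlation_is_one(self, grid24, templates24):
        mask = grid24.brain_mask
        tvec = templates24.masks["PMN"][mask].astype(float)
        assert template_correlation(zscore_masked(tvec), tvec) == pytest.approx(1.0)

    def test_matches_bruteforce_pearson(self, grid16):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        t = (rng.random(200) > 0.8).astype(float)
        assert template_correlation(x, t) == pytest.approx(
            pearson_two_pass(x, t), abs=1e-12)

    def test_noise_maps_weakly_correlated(self, grid24, templates24):
        mask = grid24.brain_mask
        tvec = templates24.masks["DMN"][mask].astype(float)
        rng = np.random.default_rng(1)
        rs = [template_correlation(rng.standard_normal(mask.sum()), tvec)
              for _ in range(100)]
        assert max(abs(r) for r in rs) < 0.1

    def test_constant_map_reports_zero_with_flag(self):
        with pytest.warns(UserWarning, match="constant"):
            r = template_correlation(np.ones(100), np.arange(100) % 2)
        assert r == 0.0


class TestPickCandidates:
    def test_exact_indicators_are_their_own_candidates(self, grid24, templates24):
        vols = [templates24.masks["PMN"].astype(float),
                templates24.masks["pDMN"].astype(float)]
        d = decomp_from_volumes(grid24, vols)
        cands = pick_candidates(d, templates24)
        assert cands["PMN"][0] == 0 and cands["PMN"][1] == pytest.approx(1.0, abs=1e-9)
        assert cands["pDMN"][0] == 1 and cands["pDMN"][1] == pytest.approx(1.0, abs=1e-9)

    def test_union_component_is_candidate_for_all_templates(self, grid24,
                                                            templates24):
        union = (templates24.masks["PMN"] | templates24.masks["pDMN"]).astype(float)
        noise = np.zeros(grid24.dims)
        noise[grid24.dims[0] // 2, 2, grid24.dims[2] // 2] = 1.0
        d = decomp_from_volumes(grid24, [union, noise])
        cands = pick_candidates(d, templates24)
        assert cands["PMN"][0] == cands["DMN"][0] == cands["pDMN"][0] == 0
        # oracle: the union map really does correlate best with each template
        mask = grid24.brain_mask
        for label in ("PMN", "DMN", "pDMN"):
            tvec = templates24.masks[label][mask].astype(float)
            r0 = pearson_two_pass(d.group_maps[0], tvec)
            r1 = pearson_two_pass(d.group_maps[1], tvec)
            assert r0 > r1

    def test_tie_broken_toward_lower_index(self, grid24, templates24):
        vol = templates24.masks["PMN"].astype(float)
        d = decomp_from_volumes(grid24, [vol, vol.copy()])
        assert pick_candidates(d, templates24)["PMN"][0] == 0


class TestAnchorsIncluded:
    def test_suprathreshold_anchors_pass(self, grid24, templates24):
        vol = np.zeros(grid24.dims)
        for a in templates24.anchors["PMN"]:
            vol[tuple(a)] = 3.0
        assert anchors_included(vol, 2.0, templates24.anchors["PMN"])

    def test_threshold_is_strict(self, grid24, templates24):
        a1, a2 = templates24.anchors["PMN"]
        vol = np.zeros(grid24.dims)
        vol[tuple(a1)] = 2.5
        vol[tuple(a2)] = 1.9
        assert not anchors_included(vol, 2.0, templates24.anchors["PMN"])
        vol[tuple(a2)] = 2.0  # exactly at threshold still fails
        assert not anchors_included(vol, 2.0, templates24.anchors["PMN"])

    def test_higher_threshold_flips_outcome(self, grid24, templates24):
        vol = np.zeros(grid24.dims)
        for a in templates24.anchors["PMN"]:
            vol[tuple(a)] = 3.0
        assert anchors_included(vol, 2.0, templates24.anchors["PMN"])
        assert not anchors_included(vol, 5.0, templates24.anchors["PMN"])

    def test_anchor_outside_grid_raises(self, grid24):
        with pytest.raises(ValueError, match="outside"):
            anchors_included(np.zeros(grid24.dims), 2.0, [(99, 0, 0)])

    def test_cluster_membership_mode_accepts_neighbor(self, grid24):
        vol = np.zeros(grid24.dims)
        vol[10, 10, 10] = 3.0
        assert not anchors_included(vol, 2.0, [(10, 11, 10)])
        assert anchors_included(vol, 2.0, [(10, 11, 10)], cluster_membership=True)


class TestSelectNetworks:
    def _clean_decomp(self, grid, templates):
        """Distinct strong PMN and pDMN components plus a noise one."""
        rng = np.random.default_rng(0)
        vols = []
        for label in ("PMN", "pDMN"):
            v = templates.masks[label].astype(float) * 5.0
            v += 0.1 * rng.standard_normal(grid.dims)
            vols.append(v)
        vols.append(rng.standard_normal(grid.dims))
        return decomp_from_volumes(grid, vols)

    def test_distinct_components_found_and_posterior(self, grid24, templates24):
        d = self._clean_decomp(grid24, templates24)
        sel = select_networks(d, SelectionConfig(templates=templates24,
                                                 z_threshold=2.0))
        assert sel.pmn.status == FOUND and sel.pmn.component == 0
        # aDMN anchor never suprathreshold -> full DMN fails, pDMN stands in
        assert sel.dmn.status == FOUND_AS_POSTERIOR and sel.dmn.component == 1
        assert sel.pmn.component != sel.dmn.component

    def test_anchor_failure_labels_not_found(self, grid24, templates24):
        d = self._clean_decomp(grid24, templates24)
        # threshold 5: z-scored cluster values sit below it
        sel = select_networks(d, SelectionConfig(templates=templates24,
                                                 z_threshold=20.0))
        assert sel.pmn.status == NOT_FOUND and sel.pmn.component is None
        assert sel.dmn.status == NOT_FOUND

    def test_merged_component_assigned_to_higher_correlation(self, grid24,
                                                             templates24):
        # one component covering PMN (strongly) and pDMN (weaker)
        vol = (templates24.masks["PMN"].astype(float) * 6.0
               + templates24.masks["pDMN"].astype(float) * 4.0)
        d = decomp_from_volumes(grid24, [vol])
        sel = select_networks(d, SelectionConfig(templates=templates24,
                                                 z_threshold=2.0))
        assert sel.candidates["PMN"][1] > sel.candidates["pDMN"][1]
        assert sel.pmn.status == FOUND and sel.pmn.component == 0
        assert sel.dmn.status == NOT_FOUND

    def test_all_noise_decompositions_find_nothing(self, grid24, templates24):
        cfg = SelectionConfig(templates=templates24, z_threshold=2.0)
        both_not_found = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            maps = np.stack([zscore_masked(rng.standard_normal(grid24.n_voxels))
                             for _ in range(4)])
            d = Decomposition(algorithm="RAICAR", model_order=4, grid=grid24,
                              group_maps=maps,
                              subject_maps=np.empty((0, 4, grid24.n_voxels)),
                              subject_timecourses=np.empty((0, 4, 1)))
            sel = select_networks(d, cfg)
            both_not_found += (sel.pmn.status == NOT_FOUND
                               and sel.dmn.status == NOT_FOUND)
        assert both_not_found >= 95

    def test_raising_threshold_never_creates_found(self, grid24, templates24):
        d = self._clean_decomp(grid24, templates24)
        rank = {FOUND: 2, FOUND_AS_POSTERIOR: 1, NOT_FOUND: 0}
        prev = None
        for thr in (1.0, 2.0, 5.0, 8.0, 20.0):
            sel = select_networks(d, SelectionConfig(templates=templates24,
                                                     z_threshold=thr))
            cur = (rank[sel.pmn.status], rank[sel.dmn.status])
            if prev is not None:
                assert cur[0] <= prev[0] and cur[1] <= prev[1]
            prev = cur

    def test_component_reordering_is_immaterial(self, grid24, templates24):
        d = self._clean_decomp(grid24, templates24)
        d_rev = Decomposition(
            algorithm=d.algorithm, model_order=d.model_order, grid=d.grid,
            group_maps=d.group_maps[::-1].copy(),
            subject_maps=d.subject_maps, subject_timecourses=d.subject_timecourses)
        cfg = SelectionConfig(templates=templates24, z_threshold=2.0)
        a, b = select_networks(d, cfg), select_networks(d_rev, cfg)
        n = d.group_maps.shape[0]
        assert a.pmn.status == b.pmn.status
        assert a.dmn.status == b.dmn.status
        assert b.pmn.component == n - 1 - a.pmn.component
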