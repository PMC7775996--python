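"""Smoothness estimation, cluster decomposition, RFT p-values, permutation."""

import numpy as np
import pytest
from scipy import stats

from boundaryprofile.core_io import SurfaceMesh, VertexMap
from boundaryprofile.rft_cluster_inference import (
    InferenceError,
    define_clusters,
    estimate_smoothness,
    permutation_cluster_test,
    rft_cluster_p,
    rft_correct,
)
from boundaryprofile.synthetic_cohort import simulate_smooth_vertex_data
from boundaryprofile.vertex_glm import StatMap, contrast_t, fit_glm


def _tmap(values, df=76, mask=None):
    return StatMap(vmap=VertexMap(values=np.asarray(values, float),
                                  valid_mask=mask, modality_tag="t"),
                   df=(df,))


class TestSmoothness:
    def test_white_noise_matches_theory(self, slab_white, design80, rng):
        Y = rng.standard_normal((design80.n_subjects, slab_white.n_vertices))
        sm = estimate_smoothness(fit_glm(Y, design80), slab_white)
        # per-edge white-noise lambda is 2/d^2; predict FWHM from edge lengths
        d2 = slab_white.edge_lengths() ** 2
        expected = np.sqrt(4 * np.log(2) / np.mean(2.0 / d2))
        assert abs(np.nanmean(sm.local_fwhm) - expected) / expected < 0.15

    def test_smoothed_noise_recovers_fwhm(self, slab_white, design80, rng):
        Y = simulate_smooth_vertex_data(slab_white, design80.n_subjects,
                                        15.0, rng)
        sm = estimate_smoothness(fit_glm(Y, design80), slab_white)
        assert 12.75 <= sm.global_fwhm <= 17.25

    def test_scale_equivariance(self, slab_white, design80, rng):
        Y = rng.standard_normal((design80.n_subjects, slab_white.n_vertices))
        fit = fit_glm(Y, design80)
        sm1 = estimate_smoothness(fit, slab_white)
        doubled = SurfaceMesh(slab_white.coords * 2.0, slab_white.faces)
        sm2 = estimate_smoothness(fit, doubled)
        ratio = sm2.global_fwhm / sm1.global_fwhm
        assert abs(ratio - 2.0) < 1e-6


class TestDefineClusters:
    def test_zero_map_no_clusters(self, slab_white):
        table = define_clusters(_tmap(np.zeros(slab_white.n_vertices)),
                                slab_white, 0.001)
        assert len(table) == 0

    def test_two_discs_two_clusters(self, slab_white):
        xy = slab_white.coords[:, :2]
        disc1 = np.linalg.norm(xy - [8, 8], axis=1) <= 4
        disc2 = np.linalg.norm(xy - [22, 22], axis=1) <= 4
        t = np.where(disc1 | disc2, 6.0, 0.5)  # separated by sub-threshold
        table = define_clusters(_tmap(t), slab_white, 0.001)
        assert len(table) == 2
        sets = sorted((set(c.vertices.tolist()) for c in table), key=len)
        expect = sorted((set(np.flatnonzero(d)) for d in (disc1, disc2)),
                        key=len)
        assert sets == expect

    def test_negative_tail_separate_sign(self, slab_white):
        xy = slab_white.coords[:, :2]
        t = np.where(np.linalg.norm(xy - [15, 15], axis=1) <= 4, -6.0, 0.0)
        table = define_clusters(_tmap(t), slab_white, 0.001)
        assert len(table) == 1 and table.clusters[0].sign == -1
        assert table.clusters[0].peak_t < 0

    def test_partition_property(self, slab_white, rng):
        for _ in range(20):
            t = rng.standard_normal(slab_white.n_vertices) * 2.5
            table = define_clusters(_tmap(t), slab_white, 0.05)
            t_cdt = stats.t.isf(0.025, 76)
            supra = set(np.flatnonzero(np.abs(t) >= t_cdt))
            union = set()
            for c in table:
                assert union.isdisjoint(c.vertices)
                union.update(c.vertices.tolist())
            assert union == supra

    def test_components_match_bfs_oracle(self, slab_white, rng):
        adj = slab_white.vertex_adjacency()
        indptr, indices = adj.indptr, adj.indices
        for _ in range(100):
            mask = rng.random(slab_white.n_vertices) < 0.15
            t = np.where(mask, 5.0, 0.0)
            table = define_clusters(_tmap(t), slab_white, 0.001)
            # breadth-first-search oracle
            seen = np.zeros(len(mask), bool)
            comps = []
            for start in np.flatnonzero(mask):
                if seen[start]:
                    continue
                queue, comp = [start], set()
                seen[start] = True
                while queue:
                    v = queue.pop()
                    comp.add(v)
                    for w in indices[indptr[v]:indptr[v + 1]]:
                        if mask[w] and not seen[w]:
                            seen[w] = True
                            queue.append(w)
                comps.append(comp)
            assert sorted(map(sorted, (c.vertices for c in table))) == \
                sorted(map(sorted, comps))


class TestRftP:
    def test_monotone_in_extent(self):
        ps = [rft_cluster_p(e, total_resels=50, cdt_p=0.001, df=76)
              for e in (0.1, 0.5, 1.0, 2.0, 5.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_small_extent_limit_is_one(self):
        # with many resels the expected cluster count is >> 1
        p = rft_cluster_p(1e-6, total_resels=5000, cdt_p=0.01, df=76)
        assert p > 0.999

    def test_low_df_rejected(self):
        with pytest.raises(InferenceError):
            rft_cluster_p(1.0, 50, 0.001, df=2)

    def test_fwer_calibration_on_null_smooth_data(self, slab_white, cohort80,
                                                  design80, rng):
        hits = 0
        n_datasets = 200
        for _ in range(n_datasets):
            Y = simulate_smooth_vertex_data(slab_white, design80.n_subjects,
                                            6.0, rng)
            fit = fit_glm(Y, design80)
            sm = estimate_smoothness(fit, slab_white)
            table = rft_correct(define_clusters(
                contrast_t(fit, "group"), slab_white, 0.001, sm))
            hits += any(c.p_corrected < 0.05 for c in table)
        assert 0.01 <= hits / n_datasets <= 0.10


class TestPermutation:
    def test_determinism(self, slab_white, design80, rng):
        Y = simulate_smooth_vertex_data(slab_white, design80.n_subjects,
                                        6.0, rng)
        asd = design80.X[:, design80.column_index("group")] > 0
        xy = slab_white.coords[:, :2]
        Y[np.ix_(asd, np.linalg.norm(xy - [15, 15], axis=1) <= 5)] += 1.5
        a = permutation_cluster_test(Y, design80, "group", slab_white,
                                     n_perm=100, seed=5)
        b = permutation_cluster_test(Y, design80, "group", slab_white,
                                     n_perm=100, seed=5)
        assert [c.p_corrected for c in a] == [c.p_corrected for c in b]
        assert len(a) > 0

    def test_small_n_perm_warns_and_floors(self, slab_white, design80, rng):
        Y = simulate_smooth_vertex_data(slab_white, design80.n_subjects,
                                        6.0, rng)
        with pytest.warns(UserWarning, match="n_perm"):
            table = permutation_cluster_test(Y, design80, "group", slab_white,
                                             n_perm=50, seed=1)
        for c in table:
            assert c.p_corrected >= 1.0 / 51.0

    def test_fwer_calibration(self, slab_white, design80, rng):
        hits = 0
        n_datasets = 200
        for i in range(n_datasets):
            Y = simulate_smooth_vertex_data(slab_white, design80.n_subjects,
                                            6.0, rng)
            table = permutation_cluster_test(Y, design80, "group", slab_white,
                                             cdt_p=0.001, n_perm=100,
                                             seed=7000 + i)
            hits += any(c.p_corrected <= 0.05 for c in table)
        assert 0.01 <= hits / n_datasets <= 0.10

    def test_agrees_with_rft_within_factor_three(self, slab_white, design80,
                                                 rng):
        """On smooth data, RFT and permutation p-values agree to 3x for
        clusters in the informative range."""
        compared = 0
        for i in range(40):
            Y = simulate_smooth_vertex_data(slab_white, design80.n_subjects,
                                            8.0, rng)
            fit = fit_glm(Y, design80)
            sm = estimate_smoothness(fit, slab_white)
            tmap = contrast_t(fit, "group")
            rft_table = rft_correct(define_clusters(tmap, slab_white, 0.01, sm))
            perm_table = permutation_cluster_test(
                Y, design80, "group", slab_white, cdt_p=0.01, n_perm=500,
                seed=900 + i, smoothness=sm)
            for cr, cp in zip(rft_table, perm_table):
                if 0.01 <= cp.p_corrected <= 0.2:
                    assert cr.p_corrected / cp.p_corrected < 3.0
                    assert cp.p_corrected / cr.p_corrected < 3.0
                    compared += 1
            if compared >= 10:
                break
        assert compared >= 3
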