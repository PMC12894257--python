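"""Coordinate-based meta-analysis: kernel reconstruction, pooling oracles,
thresholding, heterogeneity, and publication-bias diagnostics."""

import numpy as np
import pytest
from scipy import stats

from imtx import cbma, synth
from imtx.cbma import (
    ClusterRecord,
    _clusters_from_binary,
    _pool_arrays,
    egger_and_funnel,
    hedges_g,
    pool_random_effects,
    reconstruct_effect_map,
)
from imtx.volumes import PeakRecord, Study, StudySet, VolumeGrid


@pytest.fixture(scope="module")
def small_grid():
    g = VolumeGrid((30, 30, 30), np.diag([4.0, 4.0, 4.0, 1.0]), np.ones((30, 30, 30), bool))
    return g


def _one_peak_study(xyz, t=3.0, n1=25, n2=25, sign="increase"):
    return Study("s", n1, n2, [PeakRecord(np.asarray(xyz, float), abs(t), "t", "MNI", sign)])


class TestKernelReconstruction:
    def test_peak_center_value_is_exact_g(self, small_grid):
        xyz = small_grid.voxel_to_world(np.array([15, 15, 15]))
        s = _one_peak_study(xyz, t=3.0)
        d_map, v_map = reconstruct_effect_map(s, small_grid, fwhm=20.0)
        g = hedges_g(3.0, 25, 25)
        assert d_map.data[15, 15, 15] == pytest.approx(g, abs=1e-12)
        # variance at the peak follows the standard formula
        expected_v = 50 / (25 * 25) + g**2 / 100
        assert v_map.data[15, 15, 15] == pytest.approx(expected_v, rel=1e-12)

    def test_half_maximum_at_fwhm_over_two(self, small_grid):
        xyz = small_grid.voxel_to_world(np.array([15, 15, 15]))
        s = _one_peak_study(xyz, t=3.0)
        d_map, _ = reconstruct_effect_map(s, small_grid, fwhm=24.0)
        g = hedges_g(3.0, 25, 25)
        # FWHM 24 mm -> half maximum at 12 mm = 3 voxels along an axis
        assert d_map.data[18, 15, 15] == pytest.approx(0.5 * g, rel=1e-9)

    def test_signed_max_combination_of_nearby_peaks(self, small_grid):
        xyz1 = small_grid.voxel_to_world(np.array([14, 15, 15]))
        xyz2 = small_grid.voxel_to_world(np.array([16, 15, 15]))
        s = Study(
            "s", 25, 25,
            [
                PeakRecord(xyz1, 4.0, "t", "MNI", "increase"),
                PeakRecord(xyz2, 2.0, "t", "MNI", "increase"),
            ],
        )
        d_map, _ = reconstruct_effect_map(s, small_grid, fwhm=20.0)
        # brute-force kernel oracle at the midpoint voxel (15,15,15)
        sigma = 20.0 / (2 * np.sqrt(2 * np.log(2)))
        w = np.exp(-(4.0**2) / (2 * sigma**2))  # both peaks 4 mm away
        expect = hedges_g(4.0, 25, 25) * w  # larger-magnitude contribution wins
        assert d_map.data[15, 15, 15] == pytest.approx(expect, rel=1e-9)

    def test_zero_peak_study_gives_flat_map(self, small_grid):
        s = Study("empty", 20, 20, [])
        d_map, _ = reconstruct_effect_map(s, small_grid)
        assert np.all(d_map.data == 0.0)


class TestRandomEffectsPooling:
    def test_dl_closed_form_oracle(self):
        # hand-computed DerSimonian-Laird arithmetic at one voxel
        d = np.array([[0.5], [0.3], [0.1]])
        v = np.array([[0.1], [0.2], [0.4]])
        mean, se, tau2, Q = _pool_arrays(d, v)
        w = 1 / v[:, 0]
        dbar = (w * d[:, 0]).sum() / w.sum()
        Q_o = (w * (d[:, 0] - dbar) ** 2).sum()
        c = w.sum() - (w**2).sum() / w.sum()
        tau2_o = max(0.0, (Q_o - 2) / c)
        ws = 1 / (v[:, 0] + tau2_o)
        mean_o = (ws * d[:, 0]).sum() / ws.sum()
        se_o = np.sqrt(1 / ws.sum())
        assert Q[0] == pytest.approx(Q_o, abs=1e-10)
        assert tau2[0] == pytest.approx(tau2_o, abs=1e-10)
        assert mean[0] == pytest.approx(mean_o, abs=1e-10)
        assert se[0] == pytest.approx(se_o, abs=1e-10)

    def test_dl_with_positive_tau2(self):
        d = np.array([[0.9], [0.1], [0.5]])
        v = np.full((3, 1), 0.05)
        mean, se, tau2, Q = _pool_arrays(d, v)
        # equal variances: Q = sum (d-dbar)^2 / v; tau2 = (Q-2)/c with c = 40
        assert Q[0] == pytest.approx((0.16 + 0.16) / 0.05, abs=1e-10)
        assert tau2[0] == pytest.approx((Q[0] - 2) / 40.0, abs=1e-10)
        assert mean[0] == pytest.approx(0.5, abs=1e-10)

    def test_identical_studies_zero_heterogeneity(self, small_grid, rng):
        s = _one_peak_study(small_grid.voxel_to_world(np.array([15, 15, 15])))
        maps = [reconstruct_effect_map(s, small_grid) for _ in range(4)]
        pooled = pool_random_effects(maps)
        assert np.allclose(pooled.tau2, 0.0)
        np.testing.assert_allclose(pooled.mean, maps[0][0].values, atol=1e-12)

    def test_opposite_effects_cancel(self, small_grid):
        xyz = small_grid.voxel_to_world(np.array([15, 15, 15]))
        up = _one_peak_study(xyz, t=3.0, sign="increase")
        down = _one_peak_study(xyz, t=3.0, sign="decrease")
        pooled = pool_random_effects(
            [reconstruct_effect_map(s, small_grid) for s in (up, down)]
        )
        np.testing.assert_allclose(pooled.mean, 0.0, atol=1e-12)

    def test_reorder_invariance_and_sign_equivariance(self, small_grid):
        xyz = small_grid.voxel_to_world(np.array([10, 20, 15]))
        studies = [
            _one_peak_study(xyz, t=t, n1=n, n2=n + 2)
            for t, n in [(2.0, 20), (3.0, 30), (2.5, 18)]
        ]
        maps = [reconstruct_effect_map(s, small_grid) for s in studies]
        z1 = pool_random_effects(maps).z
        z2 = pool_random_effects(maps[::-1]).z
        np.testing.assert_allclose(z1, z2, atol=1e-12)
        flipped = [
            reconstruct_effect_map(
                Study(s.id, s.n_patients, s.n_controls,
                      [PeakRecord(p.xyz, p.stat_value, "t", "MNI", "decrease") for p in s.peaks]),
                small_grid,
            )
            for s in studies
        ]
        z3 = pool_random_effects(flipped).z
        np.testing.assert_allclose(z3, -z1, atol=1e-12)


class TestThresholdAndCluster:
    def test_extent_rule(self, small_grid):
        # one 49-voxel and one 50-voxel blob with strong z
        binary = np.zeros(small_grid.dims, bool)
        z = np.zeros(small_grid.dims)
        blob49 = [(2 + i, 2 + j, 2 + k) for i in range(4) for j in range(4) for k in range(4)][:49]
        blob50 = [(20 + i, 20 + j, 20 + k) for i in range(4) for j in range(4) for k in range(4)][:50]
        for ijk in blob49 + blob50:
            binary[ijk] = True
            z[ijk] = 5.0
        p_full = np.where(binary, 0.001, 1.0)
        out = _clusters_from_binary(binary, z, small_grid, "increase", peak_z=1.0, extent=50, p_full=p_full)
        assert len(out) == 1
        assert out[0].extent == 50

    def test_peak_height_rule(self, small_grid):
        binary = np.zeros(small_grid.dims, bool)
        z = np.zeros(small_grid.dims)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    binary[3 + i, 3 + j, 3 + k] = True
                    z[3 + i, 3 + j, 3 + k] = 0.8  # below the peak-z threshold
        out = _clusters_from_binary(binary, z, small_grid, "increase", 1.0, 50, np.ones(small_grid.dims))
        assert out == []

    def test_empty_null_rejected(self, small_grid):
        s = _one_peak_study(small_grid.voxel_to_world(np.array([15, 15, 15])))
        pooled = pool_random_effects([reconstruct_effect_map(s, small_grid)] * 2)
        with pytest.raises(ValueError, match="null"):
            cbma.threshold_and_cluster(pooled, np.array([]))


class TestHeterogeneity:
    def test_q_oracle_single_voxel(self):
        d = np.array([[1.0], [1.0], [3.0]])
        v = np.ones((3, 1))
        _, _, _, Q = _pool_arrays(d, v)
        assert Q[0] == pytest.approx(8.0 / 3.0, abs=1e-12)

    def test_identical_maps_no_heterogeneity_clusters(self, small_grid):
        s = _one_peak_study(small_grid.voxel_to_world(np.array([15, 15, 15])))
        pooled = pool_random_effects([reconstruct_effect_map(s, small_grid) for _ in range(5)])
        assert cbma.heterogeneity_clusters(pooled) == []

    def test_planted_disagreement_detected(self, small_grid):
        xyz = small_grid.voxel_to_world(np.array([15, 15, 15]))
        studies = [_one_peak_study(xyz, t=4.0, sign="increase") for _ in range(4)]
        studies += [_one_peak_study(xyz, t=4.0, sign="decrease") for _ in range(4)]
        pooled = pool_random_effects([reconstruct_effect_map(s, small_grid) for s in studies])
        het = cbma.heterogeneity_clusters(pooled, extent=10)
        assert het, "expected a heterogeneity cluster at the disputed locus"
        dist = np.linalg.norm(het[0].peak_xyz - xyz)
        assert dist <= 12.0


class TestEgger:
    # fixed 10-study funnel fixture
    D = np.array([0.62, 0.45, 0.71, 0.30, 0.52, 0.48, 0.66, 0.38, 0.55, 0.42])
    V = np.array([0.02, 0.05, 0.01, 0.09, 0.03, 0.04, 0.015, 0.07, 0.025, 0.06])

    def test_matches_closed_form_ols(self):
        intercept, p, funnel = egger_and_funnel(self.D, self.V)
        # independent weighted-regression oracle: explicit normal equations
        se = np.sqrt(self.V)
        y = self.D / se
        X = np.column_stack([np.ones_like(se), 1 / se])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - 2)
        se_b0 = np.sqrt(sigma2 * XtX_inv[0, 0])
        t0 = beta[0] / se_b0
        p_o = 2 * stats.t.sf(abs(t0), len(y) - 2)
        assert intercept == pytest.approx(beta[0], abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)
        assert len(funnel) == 10

    def test_planted_small_study_bias_detected(self, rng):
        se = np.linspace(0.05, 0.6, 15)
        d = 2.0 * se + rng.normal(0, 0.02, 15)  # effect proportional to SE
        _, p, _ = egger_and_funnel(d, se**2)
        assert p < 0.05

    def test_fewer_than_three_contributors_missing(self):
        intercept, p, funnel = egger_and_funnel(np.array([0.5, 0.4, 0.0]), np.array([0.1, 0.1, 0.1]))
        assert intercept is None and p is None


class TestEndToEnd:
    def test_planted_loci_recovered_with_full_jackknife(self):
        grid = synth.synthetic_gm_mask(4.0)
        truth = synth.demo_truth(0)
        studies = synth.simulate_study_set(truth, seed=11)
        meta = cbma.meta_analysis(studies, grid, n_null=40, seed=12)
        assert len(meta.clusters) >= 2
        for locus in truth.effect_loci:
            dist = [
                np.linalg.norm(c.peak_xyz - np.asarray(locus.xyz))
                for c in meta.clusters
                if c.sign == locus.sign
            ]
            assert dist and min(dist) <= 10.0
        # the effect is carried by every study, so every cluster survives
        # all leave-one-out runs
        for c in meta.clusters:
            assert c.jackknife == "15/15"
            assert c.egger_p is not None
        table = meta.cluster_table()
        assert set(["x", "y", "z", "extent", "peak_z", "egger_p", "jackknife"]) <= set(table.columns)
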