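"""Generator self-tests: planted quantities recovered by brute force."""

import numpy as np
import pandas as pd
import pytest

from imtx import synth
from imtx.synth import EffectLocus, GroundTruth
from imtx.volumes import write_peak_table


@pytest.fixture(scope="module")
def truth():
    return synth.demo_truth(0)


class TestStudySet:
    def test_noiseless_limit_places_peaks_at_loci(self, truth):
        ss = synth.simulate_study_set(truth, n_studies=4, peak_noise_sd=0.0, miss_rate=0.0, seed=1)
        for s in ss:
            assert len(s.peaks) == len(truth.effect_loci)
            for p, locus in zip(s.peaks, truth.effect_loci):
                np.testing.assert_allclose(p.xyz, locus.xyz)

    def test_group_sizes_within_reported_range(self, truth):
        ss = synth.simulate_study_set(truth, n_studies=15, n_range=(13, 67), seed=2)
        for s in ss:
            assert 13 <= s.n_patients <= 67
            assert 13 <= s.n_controls <= 67

    def test_determinism_byte_identical(self, truth, tmp_path):
        for i in (1, 2):
            ss = synth.simulate_study_set(truth, seed=42)
            write_peak_table(ss, tmp_path / f"t{i}.csv")
        assert (tmp_path / "t1.csv").read_bytes() == (tmp_path / "t2.csv").read_bytes()

    def test_t_sign_matches_locus_direction(self, truth):
        ss = synth.simulate_study_set(truth, n_studies=10, seed=3)
        from imtx.volumes import peak_to_t

        # first peak corresponds to the planted decrease, second to the increase
        for s in ss:
            assert peak_to_t(s.peaks[0], s.df) < 0
            assert peak_to_t(s.peaks[1], s.df) > 0


class TestExpressionAtlas:
    def test_rho_one_noiseless_is_affine_image(self, gm_grid_6mm, smooth_map_6mm):
        truth = GroundTruth(signal_genes=[("SIG000", 1.0)], seed=0)
        atlas = synth.simulate_expression_atlas(
            truth, gm_grid_6mm, smooth_map_6mm, n_genes=10, n_samples_per_donor=40, seed=4
        )
        vox = gm_grid_6mm.nearest_voxel(atlas.samples[["x", "y", "z"]].to_numpy())
        in_mask = gm_grid_6mm.mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        eff = smooth_map_6mm.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        # rho=1 makes the latent gene expression an exact affine image of the
        # map; the faithful probe adds only its small measurement noise
        probe = atlas.expression.loc["P_SIG000_0"].to_numpy()
        r = np.corrcoef(probe[in_mask], eff[in_mask])[0, 1]
        assert r > 0.99

    def test_planted_rho_recovered_by_direct_correlation(self, gm_grid_6mm, smooth_map_6mm):
        truth = GroundTruth(signal_genes=[("SIG000", 0.6), ("SIG001", -0.4)], seed=0)
        atlas = synth.simulate_expression_atlas(
            truth, gm_grid_6mm, smooth_map_6mm, n_genes=20, n_samples_per_donor=100, seed=5
        )
        vox = gm_grid_6mm.nearest_voxel(atlas.samples[["x", "y", "z"]].to_numpy())
        in_mask = gm_grid_6mm.mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        eff = smooth_map_6mm.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        for g, rho in truth.signal_genes:
            probe = atlas.expression.loc[f"P_{g}_0"].to_numpy()
            r = np.corrcoef(probe[in_mask], eff[in_mask])[0, 1]
            assert r == pytest.approx(rho, abs=0.05)

    def test_right_hemisphere_restricted_to_two_donors(self, gm_grid_6mm, smooth_map_6mm):
        truth = GroundTruth(seed=0)
        atlas = synth.simulate_expression_atlas(
            truth, gm_grid_6mm, smooth_map_6mm, n_donors=6, n_genes=5,
            n_samples_per_donor=50, seed=6,
        )
        right = atlas.samples[atlas.samples["x"] > 0]
        assert set(right["donor"]) <= {"donor0", "donor1"}
        assert len(right) > 0

    def test_outside_mask_fraction(self, gm_grid_6mm, smooth_map_6mm):
        truth = GroundTruth(seed=0)
        atlas = synth.simulate_expression_atlas(
            truth, gm_grid_6mm, smooth_map_6mm, n_genes=5,
            n_samples_per_donor=100, frac_outside_mask=0.3, seed=7,
        )
        vox = gm_grid_6mm.nearest_voxel(atlas.samples[["x", "y", "z"]].to_numpy())
        in_mask = gm_grid_6mm.mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        assert (~in_mask).mean() == pytest.approx(0.3, abs=0.01)

    def test_bundle_round_trip(self, gm_grid_6mm, smooth_map_6mm, tmp_path):
        truth = GroundTruth(seed=0)
        atlas = synth.simulate_expression_atlas(
            truth, gm_grid_6mm, smooth_map_6mm, n_genes=6, n_samples_per_donor=20, seed=8
        )
        atlas.write(tmp_path)
        back = synth.AtlasBundle.read(tmp_path)
        assert list(back.expression.index) == list(atlas.expression.index)
        assert back.above_background.shape == atlas.above_background.shape
        np.testing.assert_allclose(
            back.expression.to_numpy(), atlas.expression.to_numpy(), atol=1e-5
        )


class TestCategorySets:
    def test_enriched_fraction_one_all_signal(self):
        truth = GroundTruth(
            signal_genes=[(f"S{i}", 0.5) for i in range(30)],
            enriched_categories=["E0"],
            seed=0,
        )
        genes = [f"S{i}" for i in range(30)] + [f"G{i}" for i in range(100)]
        sets = synth.simulate_category_sets(
            truth, genes, n_categories=5, size_range=(10, 12), enriched_fraction=1.0, seed=9
        )
        assert set(sets["E0"]) <= {f"S{i}" for i in range(30)}

    def test_determinism(self):
        truth = GroundTruth(seed=0)
        genes = [f"G{i}" for i in range(200)]
        a = synth.simulate_category_sets(truth, genes, n_categories=20, seed=10)
        b = synth.simulate_category_sets(truth, genes, n_categories=20, seed=10)
        assert a == b

    def test_size_range_respected(self):
        truth = GroundTruth(seed=0)
        genes = [f"G{i}" for i in range(100)]
        sets = synth.simulate_category_sets(truth, genes, n_categories=30, size_range=(10, 20), seed=11)
        assert all(10 <= len(v) <= 20 for v in sets.values())


class TestPpiEdges:
    def test_planted_hub_degrees_after_filter(self, truth):
        edges = synth.simulate_ppi_edges(truth, n_nodes=100, hub_degree=30, seed=12)
        strong = edges[edges["combined_score"] >= 0.9]
        deg = pd.concat([strong["node1"], strong["node2"]]).value_counts()
        for h in truth.hub_nodes:
            assert deg[h] >= 30

    def test_low_confidence_fraction_present(self, truth):
        edges = synth.simulate_ppi_edges(truth, seed=13)
        assert (edges["combined_score"] < 0.9).sum() > 0

    def test_determinism(self, truth):
        a = synth.simulate_ppi_edges(truth, seed=14)
        b = synth.simulate_ppi_edges(truth, seed=14)
        pd.testing.assert_frame_equal(a, b)


class TestReceptorMaps:
    def test_planted_correlations_exact(self, gm_grid_6mm, smooth_map_6mm, truth):
        maps = synth.simulate_receptor_maps(truth, gm_grid_6mm, smooth_map_6mm, seed=15)
        gm = smooth_map_6mm.values
        for name, rho in truth.receptor_truth.items():
            r = np.corrcoef(maps[name].values, gm)[0, 1]
            assert r == pytest.approx(rho, abs=1e-9)

    def test_rho_one_is_the_map_itself(self, gm_grid_6mm, smooth_map_6mm):
        t = GroundTruth(receptor_truth={"self": 1.0}, seed=0)
        maps = synth.simulate_receptor_maps(t, gm_grid_6mm, smooth_map_6mm, seed=16)
        r = np.corrcoef(maps["self"].values, smooth_map_6mm.values)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_population_mode_converges(self, gm_grid_6mm, smooth_map_6mm):
        t = GroundTruth(receptor_truth={"m": -0.38}, seed=0)
        maps = synth.simulate_receptor_maps(
            t, gm_grid_6mm, smooth_map_6mm, exact=False, seed=17
        )
        r = np.corrcoef(maps["m"].values, smooth_map_6mm.values)[0, 1]
        assert r == pytest.approx(-0.38, abs=0.3)  # loose: finite spatial dof


class TestGroundTruth:
    def test_json_round_trip(self, truth, tmp_path):
        truth.to_json(tmp_path / "t.json")
        back = GroundTruth.from_json(tmp_path / "t.json")
        assert back == truth

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(signal_genes=[("G", 1.5)])
        with pytest.raises(ValueError):
            GroundTruth(receptor_truth={"m": -2.0})

    def test_effect_map_peaks_at_loci(self, gm_grid_6mm):
        t = GroundTruth(effect_loci=[EffectLocus((-32.0, -6.0, -4.0), "decrease", 0.8)])
        m = synth.effect_map_from_truth(t, gm_grid_6mm)
        idx = np.unravel_index(np.argmax(np.abs(m.data)), m.data.shape)
        xyz = gm_grid_6mm.voxel_to_world(np.array(idx))
        assert np.linalg.norm(xyz - np.array([-32, -6, -4])) <= 6.0
        # amplitude is the planted d attenuated only by the offset between
        # the locus and the nearest voxel center (< half a voxel diagonal)
        assert -0.8 - 1e-9 <= m.data[idx] <= -0.6
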