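"""Expression preprocessing: probe rules, SRS normalization, differential
stability, and mask restriction."""

import numpy as np
import pandas as pd
import pytest

from imtx import synth
from imtx.expression import (
    _srs_vector,
    differential_stability,
    filter_probes_by_intensity,
    filter_top_fraction,
    preprocess_atlas,
    restrict_to_mask,
    select_probe_per_gene,
    spatial_parcels,
    srs_normalize,
)
from imtx.synth import GroundTruth


def _frame(arr, probes, samples):
    return pd.DataFrame(arr, index=pd.Index(probes, name="probe_id"), columns=samples)


class TestIntensityFilter:
    def test_half_rule(self):
        samples = [f"s{i}" for i in range(100)]
        expr = _frame(np.ones((3, 100)), ["p49", "p50", "p100"], samples)
        above = _frame(np.zeros((3, 100), bool), ["p49", "p50", "p100"], samples)
        above.iloc[0, :49] = True
        above.iloc[1, :50] = True
        above.iloc[2, :] = True
        kept = filter_probes_by_intensity(expr, above, 0.5)
        assert list(kept.index) == ["p50", "p100"]

    def test_vacuous_filter(self):
        samples = ["a", "b"]
        expr = _frame(np.ones((2, 2)), ["p1", "p2"], samples)
        above = _frame(np.zeros((2, 2), bool), ["p1", "p2"], samples)
        kept = filter_probes_by_intensity(expr, above, 0.0)
        assert len(kept) == 2


class TestProbeSelection:
    def _setup(self, rs):
        """Three probes for one gene with chosen RNA-seq correlations."""
        rng = np.random.default_rng(0)
        n = 200
        ref = rng.standard_normal(n)
        samples = [f"s{i}" for i in range(n)]
        rows = []
        for target in rs:
            if target >= 0.999:
                rows.append(ref.copy())
            else:
                noise = rng.standard_normal(n)
                noise -= noise @ ref / (ref @ ref) * ref
                x = target * ref / np.std(ref) + np.sqrt(1 - target**2) * noise / np.std(noise)
                rows.append(x)
        expr = _frame(np.array(rows), [f"p{i}" for i in range(len(rs))], samples)
        ann = pd.DataFrame({"probe_id": [f"p{i}" for i in range(len(rs))], "gene": "G1"})
        rnaseq = pd.DataFrame([ref], index=pd.Index(["G1"], name="gene"), columns=samples)
        return expr, ann, rnaseq

    def test_max_r_probe_selected(self):
        expr, ann, rnaseq = self._setup([0.1, 0.6, 0.9])
        out = select_probe_per_gene(expr, ann, rnaseq)
        assert list(out.index) == ["G1"]
        np.testing.assert_allclose(out.loc["G1"].to_numpy(), expr.loc["p2"].to_numpy())

    def test_low_r_gene_dropped(self):
        expr, ann, rnaseq = self._setup([0.15])
        out = select_probe_per_gene(expr, ann, rnaseq)
        assert len(out) == 0

    def test_perfect_probe_selected(self):
        expr, ann, rnaseq = self._setup([1.0, 0.5])
        out = select_probe_per_gene(expr, ann, rnaseq)
        np.testing.assert_allclose(out.loc["G1"].to_numpy(), rnaseq.loc["G1"].to_numpy())

    def test_fallback_without_reference(self, caplog):
        expr, ann, _ = self._setup([0.3, 0.9])
        expr.loc["p0"] *= 10.0  # max-variance probe
        out = select_probe_per_gene(expr, ann, None)
        np.testing.assert_allclose(out.loc["G1"].to_numpy(), expr.loc["p0"].to_numpy())


class TestSrs:
    def test_frozen_oracle_vector(self):
        # direct formula evaluation for x=(0,1,2,3,100): median 2, IQR 2,
        # sigmoid then min-max
        out = _srs_vector(np.array([0.0, 1, 2, 3, 100]))
        np.testing.assert_allclose(
            out, [0.0, 0.16559991, 0.37037987, 0.57515983, 1.0], atol=1e-7
        )

    def test_sigmoid_symmetry(self):
        x = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        med = np.median(x)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        y = 1 / (1 + np.exp(-(x - med) / (iqr / 1.35)))
        np.testing.assert_allclose(y + y[::-1], 1.0, atol=1e-12)

    def test_rank_preservation_under_monotone_transform(self, rng):
        x = rng.standard_normal(50)
        a = _srs_vector(x)
        b = _srs_vector(np.exp(x))  # same ranks
        np.testing.assert_array_equal(np.argsort(a), np.argsort(b))

    def test_zero_iqr_maps_to_half(self):
        np.testing.assert_array_equal(_srs_vector(np.ones(10)), 0.5)

    def test_matrix_output_in_unit_interval(self, rng):
        df = pd.DataFrame(rng.standard_normal((20, 15)))
        out = srs_normalize(df)
        assert out.to_numpy().min() >= 0.0
        assert out.to_numpy().max() <= 1.0
        assert not out.isna().any().any()


class TestDifferentialStability:
    def test_identical_profiles_ds_one(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.5])
        data = np.tile(profile, 3)[None, :]
        df = pd.DataFrame(data, index=["g1"])
        donors = np.repeat(["d1", "d2", "d3"], 6)
        regions = np.tile(np.arange(6), 3)
        ds = differential_stability(df, donors, regions)
        assert ds["g1"] == pytest.approx(1.0, abs=1e-12)

    def test_noise_gene_ranks_below_stable_gene(self, rng):
        n_donors, n_regions = 6, 30
        stable = np.tile(rng.standard_normal(n_regions), n_donors)
        noisy = rng.standard_normal(n_donors * n_regions)
        df = pd.DataFrame([stable, noisy], index=["stable", "noisy"])
        donors = np.repeat([f"d{i}" for i in range(n_donors)], n_regions)
        regions = np.tile(np.arange(n_regions), n_donors)
        ds = differential_stability(df, donors, regions)
        assert ds["stable"] > 0.99
        assert abs(ds["noisy"]) < 0.5
        assert ds["stable"] > ds["noisy"]

    def test_invariant_to_monotone_donor_transform(self, rng):
        n_donors, n_regions = 3, 20
        base = rng.standard_normal((2, n_donors * n_regions))
        df = pd.DataFrame(base, index=["g1", "g2"])
        donors = np.repeat(["a", "b", "c"], n_regions)
        regions = np.tile(np.arange(n_regions), n_donors)
        ds1 = differential_stability(df, donors, regions)
        warped = base.copy()
        warped[:, donors == "b"] = np.exp(warped[:, donors == "b"])  # monotone
        ds2 = differential_stability(pd.DataFrame(warped, index=["g1", "g2"]), donors, regions)
        pd.testing.assert_series_equal(ds1, ds2)

    def test_top_fraction_count_matches_ceiling(self, rng):
        ds = pd.Series(rng.uniform(size=5013), index=[f"g{i}" for i in range(5013)])
        assert len(filter_top_fraction(ds, 0.5)) == 2507  # ceil(5013/2)
        assert len(filter_top_fraction(ds, 0.4)) == int(np.ceil(0.4 * 5013))
        assert len(filter_top_fraction(ds, 0.6)) == int(np.ceil(0.6 * 5013))

    def test_pair_with_few_shared_regions_skipped(self):
        df = pd.DataFrame([[1.0, 2.0, 1.5, 2.5, 1.0, 2.0, 3.0, 4.0]], index=["g"])
        donors = np.array(["a", "a", "a", "a", "b", "b", "c", "c"])
        regions = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        # pair (b, c) shares no regions; (a,b) and (a,c) share two each
        ds = differential_stability(df, donors, regions)
        assert np.isfinite(ds["g"])


class TestMaskRestriction:
    def test_outside_samples_dropped(self, gm_grid_6mm):
        inside = gm_grid_6mm.mask_world_coords()[0]
        samples = pd.DataFrame(
            {"sample_id": ["in", "out"], "donor": ["d", "d"],
             "x": [inside[0], -200.0], "y": [inside[1], 0.0], "z": [inside[2], 0.0]}
        )
        keep = restrict_to_mask(samples, gm_grid_6mm)
        np.testing.assert_array_equal(keep, [True, False])

    def test_planted_outside_fraction_recovered(self, gm_grid_6mm, smooth_map_6mm):
        truth = GroundTruth(seed=0)
        atlas = synth.simulate_expression_atlas(
            truth, gm_grid_6mm, smooth_map_6mm, n_genes=5,
            n_samples_per_donor=100, frac_outside_mask=0.3, seed=21,
        )
        keep = restrict_to_mask(atlas.samples, gm_grid_6mm)
        assert keep.sum() == 6 * 70  # planted in-mask count

    def test_all_outside_raises(self, gm_grid_6mm):
        samples = pd.DataFrame(
            {"sample_id": ["a"], "donor": ["d"], "x": [-200.0], "y": [0.0], "z": [0.0]}
        )
        with pytest.raises(ValueError, match="outside"):
            restrict_to_mask(samples, gm_grid_6mm)


class TestFullPipeline:
    def test_output_invariants_and_determinism(self, gm_grid_6mm, smooth_map_6mm):
        truth = GroundTruth(signal_genes=[("SIG000", 0.7)], seed=0)
        atlas = synth.simulate_expression_atlas(
            truth, gm_grid_6mm, smooth_map_6mm, n_genes=60, n_samples_per_donor=40, seed=22
        )
        a = preprocess_atlas(atlas, gm_grid_6mm, seed=23)
        b = preprocess_atlas(atlas, gm_grid_6mm, seed=23)
        pd.testing.assert_frame_equal(a.data, b.data)
        vals = a.data.to_numpy()
        assert not np.isnan(vals).any()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        # retained samples all fall inside the mask
        vox = gm_grid_6mm.nearest_voxel(a.meta[["x", "y", "z"]].to_numpy())
        assert gm_grid_6mm.mask[vox[:, 0], vox[:, 1], vox[:, 2]].all()
        # left-only default drops right-hemisphere samples
        assert (a.meta["x"] <= 0).all()

    def test_parcels_deterministic(self, rng):
        coords = rng.uniform(-50, 50, size=(200, 3))
        a = spatial_parcels(coords, 10, seed=5)
        b = spatial_parcels(coords, 10, seed=5)
        np.testing.assert_array_equal(a, b)
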