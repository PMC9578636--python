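"""Generator contracts: determinism, geometry, calibration, feasibility."""

import numpy as np
import pandas as pd
import pytest

from testisquant import (SceneSpec, make_coloc_pair, make_fertility_table,
                         make_ic_scene, make_nuclei_scene,
                         pearson_coefficient)
from testisquant.errors import SceneInfeasibleError


class TestNucleiScene:
    def test_identical_seed_gives_bit_identical_output(self):
        spec = SceneSpec(shape=(16, 64, 64), n_cells=4, seed=3)
        stack1, truth1 = make_nuclei_scene(spec)
        stack2, truth2 = make_nuclei_scene(spec)
        np.testing.assert_array_equal(stack1.voxels, stack2.voxels)
        assert [c.centroid_um for c in truth1.cells] == \
               [c.centroid_um for c in truth2.cells]

    def test_different_seed_changes_realization(self):
        a, _ = make_nuclei_scene(SceneSpec(shape=(16, 64, 64), n_cells=4, seed=3))
        b, _ = make_nuclei_scene(SceneSpec(shape=(16, 64, 64), n_cells=4, seed=4))
        assert not np.array_equal(a.voxels, b.voxels)

    def test_empty_scene_is_noise_only(self):
        spec = SceneSpec(shape=(8, 32, 32), n_cells=0, noise="none",
                         background=7.0, seed=0)
        stack, truth = make_nuclei_scene(spec)
        assert truth.cells == []
        assert np.all(stack.channel("nuclear") == 7)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_centroids_inside_volume(self, seed):
        spec = SceneSpec(shape=(20, 96, 96), n_cells=12,
                         min_separation_um=5.0, seed=seed)
        _, truth = make_nuclei_scene(spec)
        extent = spec.extent_um
        for c in truth.cells:
            idx = [p / v for p, v in zip(c.centroid_um, spec.voxel_size)]
            assert all(0 <= i <= s - 1 for i, s in zip(idx, spec.shape))
            assert all(0 <= p <= e for p, e in zip(c.centroid_um, extent))

    def test_min_separation_respected(self):
        spec = SceneSpec(shape=(24, 128, 128), n_cells=8,
                         min_separation_um=9.0, seed=7)
        _, truth = make_nuclei_scene(spec)
        pts = np.array([c.centroid_um for c in truth.cells])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 9.0

    def test_infeasible_packing_raises(self):
        spec = SceneSpec(shape=(10, 24, 24), n_cells=50,
                         min_separation_um=6.0, seed=0)
        with pytest.raises(SceneInfeasibleError):
            make_nuclei_scene(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(shape=(0, 10, 10))
        with pytest.raises(ValueError):
            SceneSpec(min_separation_um=-1.0)
        with pytest.raises(ValueError):
            SceneSpec(marker_fractions={"vasa": 1.5})

    def test_marker_channels_light_up_flagged_cells(self):
        spec = SceneSpec(shape=(20, 96, 96), n_cells=10,
                         min_separation_um=8.0, noise="none",
                         marker_fractions={"vasa": 0.5}, seed=2)
        stack, truth = make_nuclei_scene(spec)
        vasa = stack.channel("vasa").astype(float)
        for c in truth.cells:
            idx = tuple(int(round(p / v))
                        for p, v in zip(c.centroid_um, spec.voxel_size))
            val = vasa[idx] - spec.background
            if c.flags["vasa"]:
                assert val > 0.8 * spec.base_intensity
            else:
                assert val < 0.3 * spec.base_intensity

    def test_bundles_group_at_least_two_cells(self):
        spec = SceneSpec(shape=(30, 200, 200), n_cells=0, n_bundles=2,
                         bundle_size=64, noise="none", seed=1)
        _, truth = make_nuclei_scene(spec)
        ids = pd.Series([c.bundle_id for c in truth.cells])
        assert set(ids.unique()) == {0, 1}
        assert (ids.value_counts() == 64).all()


class TestColocPair:
    def test_rho_one_gives_perfect_correlation(self):
        stack, _ = make_coloc_pair((10, 50, 50), 1.0, seed=0)
        assert pearson_coefficient(stack, "zpg", "gfp").r == pytest.approx(1.0)

    def test_rho_minus_one_gives_anticorrelation(self):
        stack, _ = make_coloc_pair((10, 50, 50), -1.0, seed=0)
        assert pearson_coefficient(stack, "zpg", "gfp").r == pytest.approx(-1.0)

    def test_rho_zero_sample_r_small(self):
        # var(r_hat) ~ 1/n at rho=0: 10^5 voxels keep |r_hat| well below 0.05
        stack, _ = make_coloc_pair((10, 100, 100), 0.0, seed=1)
        assert abs(pearson_coefficient(stack, "zpg", "gfp").r) < 0.05

    def test_rho_08_within_fisher_interval(self):
        # Fisher z: sd(z) = 1/sqrt(n-3) ~ 0.003 at n = 10^5, so the sample
        # r at rho = 0.8 stays within [0.78, 0.82] with huge margin
        stack, _ = make_coloc_pair((10, 100, 100), 0.8, seed=2)
        assert 0.78 <= pearson_coefficient(stack, "zpg", "gfp").r <= 0.82

    @pytest.mark.parametrize("rho", [-0.5, 0.0, 0.5, 0.9])
    def test_calibration_mean_over_replicates(self, rho):
        # generator calibration: mean sample r within 0.02 of target rho
        rs = []
        for rep in range(50):
            stack, _ = make_coloc_pair((10, 100, 100), rho, seed=1000 + rep)
            rs.append(pearson_coefficient(stack, "zpg", "gfp").r)
        assert abs(np.mean(rs) - rho) < 0.02

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_coloc_pair((4, 8, 8), 1.2, seed=0)


class TestICScene:
    def test_ground_truth_angle_matches_request(self):
        _, truth = make_ic_scene(135.0, 3, seed=0)
        assert truth.ic_angles_deg == [135.0] * 3
        for p_actin, vertex, p_nucleus in truth.ic_landmarks:
            u = np.asarray(p_actin) - np.asarray(vertex)
            v = np.asarray(p_nucleus) - np.asarray(vertex)
            cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) == \
                pytest.approx(135.0, abs=1e-6)

    def test_zero_complexes_is_empty(self):
        stack, truth = make_ic_scene(180.0, 0, seed=0)
        assert truth.ic_angles_deg == []
        assert stack.shape == (48, 288, 288)

    @pytest.mark.parametrize("angle", [0.0, -10.0, 180.5])
    def test_angle_outside_range_rejected(self, angle):
        with pytest.raises(ValueError):
            make_ic_scene(angle, 2, seed=0)


class TestFertilityTable:
    def test_explicit_counts_one_row_per_male(self):
        df = make_fertility_table(["wt"], {"wt": [45, 52, 60]}, seed=0)
        assert list(df.columns) == ["male_id", "genotype", "offspring_per_day"]
        assert df["offspring_per_day"].tolist() == [45, 52, 60]

    def test_poisson_rule_is_deterministic_under_seed(self):
        rule = {"wt": {"dist": "poisson", "mean": 40, "n": 6}}
        a = make_fertility_table(["wt"], rule, seed=9)
        b = make_fertility_table(["wt"], rule, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_fertility_table(["wt"], {"wt": [5, -1]}, seed=0)
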