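"""Niche classification rules: hub detection, marker flags, GSC/CySC
gating, bundle counting, intensity measurement."""

import numpy as np
import pandas as pd
import pytest

from testisquant import (CellTable, HubRegion, ImageStack, classify_cysc,
                         classify_gsc, count_bundles, count_cells,
                         detect_hub, flag_markers, hub_distances,
                         label_nuclei, measure_intensity, preprocess)
from testisquant.errors import ChannelRoleError, HubNotFoundError

VS = (1.0, 0.31, 0.31)


def _stack_with_blob(shape, blobs, vs=VS):
    """Blobs: list of (centre_um, radius_um, intensity)."""
    img = np.zeros(shape)
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    for centre, radius, value in blobs:
        d2 = ((zz * vs[0] - centre[0]) ** 2 + (yy * vs[1] - centre[1]) ** 2
              + (xx * vs[2] - centre[2]) ** 2)
        img[d2 <= radius ** 2] = value
    return ImageStack(img[np.newaxis], vs, ["hub"])


def _hub_at_origin_corner(radius_um=8.0):
    """A HubRegion whose surface distances are easy to reason about."""
    shape = (32, 192, 192)
    centre = (16.0, 24.8, 24.8)
    stack = _stack_with_blob(shape, [(centre, radius_um, 500.0)])
    return detect_hub(stack, "hub")


class TestDetectHub:
    def test_centroid_within_one_voxel(self, niche_scene):
        spec, stack, truth = niche_scene
        hub = detect_hub(stack, "hub")
        err = np.abs(np.asarray(hub.centroid_um)
                     - np.asarray(truth.hub_centroid_um))
        assert (err <= np.asarray(spec.voxel_size)).all()
        assert hub.equivalent_radius_um == pytest.approx(
            truth.hub_radius_um, rel=0.15)

    def test_blank_channel_hub_not_found(self):
        stack = ImageStack(np.zeros((1, 8, 16, 16)), VS, ["hub"])
        with pytest.raises(HubNotFoundError):
            detect_hub(stack, "hub")

    def test_largest_of_two_blobs_wins(self):
        stack = _stack_with_blob(
            (32, 160, 160),
            [((16.0, 12.0, 12.0), 2.5, 500.0),
             ((16.0, 30.0, 30.0), 8.0, 500.0)])
        hub = detect_hub(stack, "hub")
        assert np.allclose(hub.centroid_um, (16.0, 30.0, 30.0), atol=1.0)


class TestFlagMarkers:
    def test_generator_flags_recovered_exactly(self):
        from testisquant import SceneSpec, make_nuclei_scene
        spec = SceneSpec(shape=(24, 128, 128), n_cells=20,
                         min_separation_um=7.0,
                         marker_fractions={"zfh1": 0.4}, seed=21)
        stack, truth = make_nuclei_scene(spec)
        mask = preprocess(stack, "nuclear")
        lv = label_nuclei(mask, spec.voxel_size)
        table = count_cells(lv, stack, channels=["zfh1"])
        # cutoff between the dimmed-negative (~background + base/10) and
        # positive (~base/2 after averaging over the whole label) means
        table = flag_markers(table, {"zfh1": 80.0})
        assert int(table.df["zfh1_pos"].sum()) == 8  # 0.4 x 20 exactly
        assert len(table) == 20

    def test_threshold_zero_flags_everything(self):
        df = pd.DataFrame({"cell_id": [1, 2], "mean_vasa": [5.0, 50.0]})
        out = flag_markers(CellTable(df), {"vasa": 0.0})
        assert out.df["vasa_pos"].all()

    def test_raising_threshold_is_monotone(self):
        df = pd.DataFrame({"cell_id": range(6),
                           "mean_vasa": [1, 5, 10, 50, 100, 500.0]})
        counts = [flag_markers(CellTable(df), {"vasa": t}).df["vasa_pos"].sum()
                  for t in (0, 4, 20, 99, 1000)]
        assert counts == sorted(counts, reverse=True)

    def test_missing_channel_column_is_config_error(self):
        with pytest.raises(ChannelRoleError):
            flag_markers(CellTable(pd.DataFrame({"cell_id": [1]})),
                         {"eya": 10.0})


def _cells(rows):
    df = pd.DataFrame(rows)
    df["volume_um3"] = df.get("volume_um3", 33.51)  # r = 2 um sphere
    return CellTable(df)


class TestClassifyGsc:
    def test_rule_truth_table(self):
        hub = _hub_at_origin_corner()
        hz, hy, hx = hub.centroid_um
        r_hub = hub.equivalent_radius_um
        rows = [
            # Vasa+ touching the hub, isolated -> GSC
            {"cell_id": 1, "z_um": hz, "y_um": hy, "x_um": hx + r_hub + 1.9,
             "vasa_pos": True},
            # Vasa+ but 20 um from the hub -> not GSC
            {"cell_id": 2, "z_um": hz, "y_um": hy + r_hub + 20.0, "x_um": hx,
             "vasa_pos": True},
            # Vasa- touching the hub -> not GSC
            {"cell_id": 3, "z_um": hz, "y_um": hy - r_hub - 1.9, "x_um": hx,
             "vasa_pos": False},
        ]
        out = classify_gsc(_cells(rows), hub, contact_tol_um=0.5).df
        assert out["cell_class"].tolist() == ["GSC", "other", "other"]

    def test_singleness_disqualifies_paired_vasa_cells(self):
        hub = _hub_at_origin_corner()
        hz, hy, hx = hub.centroid_um
        r_hub = hub.equivalent_radius_um
        touch_x = hx + r_hub + 1.9
        rows = [
            {"cell_id": 1, "z_um": hz, "y_um": hy, "x_um": touch_x,
             "vasa_pos": True},
            # second Vasa+ centroid 4 um away: inside a 2-cell cyst
            {"cell_id": 2, "z_um": hz + 4.0, "y_um": hy, "x_um": touch_x,
             "vasa_pos": True},
        ]
        out = classify_gsc(_cells(rows), hub, contact_tol_um=0.5,
                           singleness_dist_um=8.0).df
        assert (out["cell_class"] == "GSC").sum() == 0
        assert out["vasa_pos"].all()  # GSC subset of Vasa+ is vacuous here


class TestClassifyCysc:
    @pytest.mark.parametrize("gap,expected", [(5.0, "CySC"), (15.0, "other")])
    def test_distance_gate(self, gap, expected):
        hub = _hub_at_origin_corner()
        hz, hy, hx = hub.centroid_um
        cell_r = 2.0
        rows = [{"cell_id": 1, "z_um": hz, "y_um": hy,
                 "x_um": hx + hub.equivalent_radius_um + cell_r + gap,
                 "zfh1_pos": True}]
        out = classify_cysc(_cells(rows), hub).df
        assert out["cell_class"].iloc[0] == expected

    def test_zfh1_negative_near_hub_excluded(self):
        hub = _hub_at_origin_corner()
        hz, hy, hx = hub.centroid_um
        rows = [{"cell_id": 1, "z_um": hz, "y_um": hy,
                 "x_um": hx + hub.equivalent_radius_um + 7.0,
                 "zfh1_pos": False}]
        out = classify_cysc(_cells(rows), hub).df
        assert out["cell_class"].iloc[0] == "other"

    def test_crossing_10um_boundary_flips_exactly_one_cell(self):
        hub = _hub_at_origin_corner()
        hz, hy, hx = hub.centroid_um
        base_x = hx + hub.equivalent_radius_um + 2.0
        fixed = [
            {"cell_id": 1, "z_um": hz, "y_um": hy + 14.0, "x_um": base_x,
             "zfh1_pos": True},
            {"cell_id": 2, "z_um": hz, "y_um": hy - 14.0, "x_um": base_x,
             "zfh1_pos": True},
        ]
        statuses = []
        for gap in (9.0, 11.0):  # surface-to-surface, straddling 10 um
            rows = fixed + [{"cell_id": 3, "z_um": hz, "y_um": hy,
                             "x_um": hx + hub.equivalent_radius_um + 2.0 + gap,
                             "zfh1_pos": True}]
            out = classify_cysc(_cells(rows), hub).df.set_index("cell_id")
            statuses.append(out["cell_class"].to_dict())
        assert statuses[0][3] == "CySC" and statuses[1][3] == "other"
        for cid in (1, 2):
            assert statuses[0][cid] == statuses[1][cid]


class TestEndToEndNicheScene:
    def test_gsc_and_cysc_counts_recovered(self, niche_scene):
        spec, stack, truth = niche_scene
        mask = preprocess(stack, "nuclear")
        lv = label_nuclei(mask, spec.voxel_size)
        table = count_cells(lv, stack, channels=["vasa", "zfh1"])
        table = flag_markers(table, {"vasa": 120.0, "zfh1": 120.0})
        hub = detect_hub(stack, "hub")
        table = hub_distances(table, hub)
        table = classify_gsc(table, hub, contact_tol_um=2.0)
        table = classify_cysc(table, hub)
        df = table.df
        assert (df["cell_class"] == "GSC").sum() == spec.n_gsc
        assert (df["cell_class"] == "CySC").sum() == spec.n_cysc
        # set containment: classes imply their marker flags
        assert df.loc[df["cell_class"] == "GSC", "vasa_pos"].all()
        assert df.loc[df["cell_class"] == "CySC", "zfh1_pos"].all()


class TestCountBundles:
    def test_empty_table_zero_bundles(self):
        n, sizes = count_bundles(CellTable(pd.DataFrame(
            columns=["cell_id", "z_um", "y_um", "x_um"])))
        assert (n, sizes) == (0, [])

    def test_three_canonical_bundles(self):
        from testisquant import SceneSpec, make_nuclei_scene
        spec = SceneSpec(shape=(40, 256, 256), n_cells=0, n_bundles=3,
                         bundle_size=64, noise="none", seed=4)
        _, truth = make_nuclei_scene(spec)
        n, sizes = count_bundles(CellTable(truth.cell_frame()))
        assert n == 3
        assert sizes == [64, 64, 64]

    def test_small_cluster_below_threshold_not_counted(self, rng):
        pts = rng.uniform(0, 2.0, size=(10, 3))  # one tight 10-nucleus clump
        df = pd.DataFrame(pts, columns=["z_um", "y_um", "x_um"])
        df["cell_id"] = range(10)
        n, sizes = count_bundles(CellTable(df), min_bundle_nuclei=48)
        assert (n, sizes) == (0, [])

    def test_bundle_sizes_account_for_all_clustered_nuclei(self):
        from testisquant import SceneSpec, make_nuclei_scene
        spec = SceneSpec(shape=(40, 256, 256), n_cells=0, n_bundles=2,
                         bundle_size=64, noise="none", seed=8)
        _, truth = make_nuclei_scene(spec)
        n, sizes = count_bundles(CellTable(truth.cell_frame()))
        assert n * 64 == sum(sizes) == len(truth.cells)


class TestMeasureIntensity:
    def test_uniform_region(self):
        vox = np.full((1, 4, 4, 4), 100.0)
        stack = ImageStack(vox, (1, 1, 1), ["gfp"])
        region = np.zeros((4, 4, 4), bool)
        region[1:3, 1:3, 1:3] = True
        assert measure_intensity(stack, "gfp", region) == 100.0

    def test_half_zero_half_200_averages_100(self):
        vox = np.zeros((1, 2, 2, 2))
        vox[0, 0] = 200.0
        stack = ImageStack(vox, (1, 1, 1), ["gfp"])
        assert measure_intensity(stack, "gfp",
                                 np.ones((2, 2, 2), bool)) == 100.0

    def test_relative_reduction_between_two_stacks(self):
        wt = ImageStack(np.full((1, 2, 2, 2), 250.0), (1, 1, 1), ["zpg"])
        mut = ImageStack(np.full((1, 2, 2, 2), 148.0), (1, 1, 1), ["zpg"])
        region = np.ones((2, 2, 2), bool)
        m_wt = measure_intensity(wt, "zpg", region)
        m_mut = measure_intensity(mut, "zpg", region)
        assert (1 - m_mut / m_wt) * 100 == pytest.approx(40.8)

    def test_empty_region_rejected(self):
        stack = ImageStack(np.zeros((1, 2, 2, 2)), (1, 1, 1), ["gfp"])
        with pytest.raises(ValueError):
            measure_intensity(stack, "gfp", np.zeros((2, 2, 2), bool))
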