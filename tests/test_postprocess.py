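import numpy as np
import pytest
from scipy import ndimage

from seuneter.phantom import (
    AddLargeBlob,
    AddSmallIsland,
    MergeAdjacent,
    PunchHole,
    make_degraded_prediction,
)
from seuneter.postprocess import (
    PostprocessConfig,
    SegmentationResult,
    fill_cavities,
    postprocess_all,
    reconcile_component_count,
    remove_large_anomalies,
    remove_small_anomalies,
    split_adhesions,
)
from seuneter.schema_io import LabelMap

EIGHT = np.ones((3, 3), dtype=bool)


def n_components(mask):
    return ndimage.label(mask, structure=EIGHT)[1]


def structural_K(labels, schema):
    union = (labels != schema.background_id) & (labels != schema.cord_id)
    return n_components(union)


def run_externals(labelmap, cfg, schema):
    result = SegmentationResult.from_labelmap(labelmap)
    remove_large_anomalies(result, cfg, schema)
    remove_small_anomalies(result, cfg, schema)
    return result


ALL_DEFECTS = [
    AddLargeBlob(3, 75),
    AddSmallIsland(4, 3),
    MergeAdjacent(3, 10),
    PunchHole(15, 10),
]


class TestConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            PostprocessConfig(eta_l=10, eta_s=10, eta_d=1)
        with pytest.raises(ValueError):
            PostprocessConfig(ker_l=3, ker_s=3)

    def test_for_shape_scales_down(self):
        cfg = PostprocessConfig.for_shape((128, 128))
        assert cfg.eta_l < 2000 and cfg.ker_l >= 3
        assert cfg.eta_l > cfg.eta_s > cfg.eta_d >= 1


class TestRemoveLargeAnomalies:
    def test_clean_prediction_unchanged(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        result = SegmentationResult.from_labelmap(truth)
        remove_large_anomalies(result, pp_cfg_128, schema)
        assert np.array_equal(result.prediction.labels, truth.labels)
        assert result.stage_log[0].pixels_changed == 0

    def test_sub_threshold_blob_removed_truth_recovered(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, [AddLargeBlob(3, pp_cfg_128.eta_l - 50)],
                                       seed=0, schema=schema)
        result = SegmentationResult.from_labelmap(deg)
        remove_large_anomalies(result, pp_cfg_128, schema)
        assert np.array_equal(result.prediction.labels, truth.labels)
        assert result.stage_log[0].components_removed == 1

    def test_all_background_is_identity(self, pp_cfg_128, schema):
        empty = LabelMap(np.zeros((64, 64), dtype=np.uint8))
        result = SegmentationResult.from_labelmap(empty)
        remove_large_anomalies(result, pp_cfg_128, schema)
        assert not result.prediction.labels.any()


class TestRemoveSmallAnomalies:
    def test_requires_large_stage_first(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        result = SegmentationResult.from_labelmap(truth)
        with pytest.raises(ValueError, match="remove_large"):
            remove_small_anomalies(result, pp_cfg_128, schema)

    def test_small_island_removed_exactly(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, [AddSmallIsland(4, 3)], seed=0, schema=schema)
        result = run_externals(deg, pp_cfg_128, schema)
        assert np.array_equal(result.prediction.labels, truth.labels)
        assert result.stage_log[1].pixels_changed == 3

    def test_component_at_threshold_retained(self, phantom_128, pp_cfg_128, schema):
        """Strict < rule: a component with area exactly eta_s survives."""
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, [AddSmallIsland(4, pp_cfg_128.eta_s)],
                                       seed=0, schema=schema)
        result = run_externals(deg, pp_cfg_128, schema)
        assert np.array_equal(result.prediction.labels, deg.labels)

    def test_untouched_truth_zero_changes(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        result = run_externals(truth, pp_cfg_128, schema)
        assert result.stage_log[1].pixels_changed == 0


class TestReconcile:
    def test_clean_phantom_has_expected_count_and_no_changes(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        result = run_externals(truth, pp_cfg_128, schema)
        reconcile_component_count(result, schema, pp_cfg_128)
        rec = result.stage_log[-1]
        assert rec.notes["K"] == 14 and rec.notes["action"] == "relabel"
        assert rec.pixels_changed == 0

    def test_surplus_island_removed_as_smallest_component(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        # 24 px: survives both external passes (>= eta_s, vanishes under the
        # coarse opening) yet is the smallest of the 15 structural components
        deg = make_degraded_prediction(truth, [AddSmallIsland(4, pp_cfg_128.eta_s + 4)],
                                       seed=0, schema=schema)
        result = run_externals(deg, pp_cfg_128, schema)
        reconcile_component_count(result, schema, pp_cfg_128)
        rec = result.stage_log[-1]
        assert rec.notes["K"] == 15 and rec.notes["action"] == "remove_extra"
        assert np.array_equal(result.prediction.labels, truth.labels)

    def test_adhesion_routed_to_split_branch(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, [MergeAdjacent(3, 10)], seed=0, schema=schema)
        result = run_externals(deg, pp_cfg_128, schema)
        reconcile_component_count(result, schema, pp_cfg_128)
        rec = result.stage_log[-1]
        assert rec.notes["K"] == 13 and rec.notes["action"] == "split_adhesions"
        assert structural_K(result.prediction.labels, schema) == 14


class TestSplitAdhesions:
    def test_merged_vertebra_disc_separated_and_uniform(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, [MergeAdjacent(3, 10)], seed=0, schema=schema)
        result = SegmentationResult.from_labelmap(deg)
        split_adhesions(result, schema, pp_cfg_128)
        labels = result.prediction.labels
        assert n_components(np.isin(labels, [3, 10])) == 2
        for cid in (3, 10):
            comp, n = ndimage.label(labels == cid, structure=EIGHT)
            assert n == 1  # internally uniform, single region per class
        assert np.array_equal(labels, truth.labels)

    def test_no_adhesion_is_identity(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        result = SegmentationResult.from_labelmap(truth)
        split_adhesions(result, schema, pp_cfg_128)
        assert np.array_equal(result.prediction.labels, truth.labels)

    def test_disc_sliver_below_eta_d_removed(self, phantom_128, pp_cfg_128, schema):
        """A sub-eta_d disc fragment inside the cord region is dropped."""
        _, truth = phantom_128
        labels = truth.labels.copy()
        cord = labels == schema.cord_id
        interior = ndimage.binary_erosion(cord, structure=EIGHT)
        rows, cols = np.nonzero(interior)
        sliver = (rows[:6], cols[:6])  # 6 px < eta_d = 10
        labels[sliver] = 8  # a disc class
        result = SegmentationResult.from_labelmap(LabelMap(labels))
        split_adhesions(result, schema, pp_cfg_128)
        assert not np.any(result.prediction.labels[sliver] == 8)


class TestFillCavities:
    def test_cord_hole_filled_exactly(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, [PunchHole(15, 10)], seed=0, schema=schema)
        result = SegmentationResult.from_labelmap(deg)
        fill_cavities(result, schema)
        assert np.array_equal(result.prediction.labels, truth.labels)
        assert result.stage_log[0].pixels_changed == 10

    def test_solid_regions_identity(self, phantom_128, schema):
        _, truth = phantom_128
        result = SegmentationResult.from_labelmap(truth)
        fill_cavities(result, schema)
        assert np.array_equal(result.prediction.labels, truth.labels)

    def test_background_only_identity(self, schema):
        empty = LabelMap(np.zeros((48, 48), dtype=np.uint8))
        result = SegmentationResult.from_labelmap(empty)
        fill_cavities(result, schema)
        assert not result.prediction.labels.any()

    def test_never_alters_foreground_pixels(self, phantom_128, schema):
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, [PunchHole(15, 10)], seed=0, schema=schema)
        result = SegmentationResult.from_labelmap(deg)
        fill_cavities(result, schema)
        fg_before = deg.labels != 0
        assert np.array_equal(result.prediction.labels[fg_before], deg.labels[fg_before])


class TestPostprocessAll:
    def test_clean_truth_is_fixed_point(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        result = postprocess_all(truth, schema, pp_cfg_128)
        assert np.array_equal(result.prediction.labels, truth.labels)
        assert all(rec.pixels_changed == 0 for rec in result.stage_log)

    def test_stage_log_has_four_entries_in_order(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        result = postprocess_all(truth, schema, pp_cfg_128)
        assert [r.stage for r in result.stage_log] == [
            "remove_large", "remove_small", "reconcile", "fill_cavities"
        ]

    def test_all_four_defects_recovered(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, ALL_DEFECTS, seed=0, schema=schema)
        result = postprocess_all(deg, schema, pp_cfg_128)
        assert np.array_equal(result.prediction.labels, truth.labels)

    def test_idempotent_on_own_output(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, ALL_DEFECTS, seed=1, schema=schema)
        once = postprocess_all(deg, schema, pp_cfg_128)
        twice = postprocess_all(once.prediction, schema, pp_cfg_128)
        assert np.array_equal(twice.prediction.labels, once.prediction.labels)

    @pytest.mark.parametrize("defects", [
        [AddLargeBlob(3, 75)],
        [AddSmallIsland(4, 3)],
        [MergeAdjacent(3, 10)],
        [PunchHole(15, 10)],
        ALL_DEFECTS,
    ], ids=["blob", "island", "merge", "hole", "all"])
    def test_monotone_cleanup_across_stages(self, phantom_128, pp_cfg_128, schema, defects):
        """Per-stage pixel error vs truth never increases."""
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, defects, seed=0, schema=schema)
        result = SegmentationResult.from_labelmap(deg)
        errors = [int((result.prediction.labels != truth.labels).sum())]
        remove_large_anomalies(result, pp_cfg_128, schema)
        errors.append(int((result.prediction.labels != truth.labels).sum()))
        remove_small_anomalies(result, pp_cfg_128, schema)
        errors.append(int((result.prediction.labels != truth.labels).sum()))
        reconcile_component_count(result, schema, pp_cfg_128)
        errors.append(int((result.prediction.labels != truth.labels).sum()))
        fill_cavities(result, schema)
        errors.append(int((result.prediction.labels != truth.labels).sum()))
        assert all(b <= a for a, b in zip(errors, errors[1:]))
        assert errors[-1] == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_fourteen_component_contract(self, phantom_128, pp_cfg_128, schema, seed):
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, ALL_DEFECTS, seed=seed, schema=schema)
        result = postprocess_all(deg, schema, pp_cfg_128)
        assert structural_K(result.prediction.labels, schema) == 14

    def test_external_stages_only_move_pixels_to_background(self, phantom_128, pp_cfg_128, schema):
        _, truth = phantom_128
        deg = make_degraded_prediction(truth, ALL_DEFECTS, seed=2, schema=schema)
        result = SegmentationResult.from_labelmap(deg)
        before = result.prediction.labels.copy()
        remove_large_anomalies(result, pp_cfg_128, schema)
        remove_small_anomalies(result, pp_cfg_128, schema)
        after = result.prediction.labels
        changed = before != after
        assert np.all(after[changed] == schema.background_id)
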