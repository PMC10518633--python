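import dataclasses

import numpy as np
import pytest

import gliaquant as gq
from gliaquant.colocalization import (
    ColocalizationParams,
    colocalized_record_volume,
    compute_stack_metrics,
)
from gliaquant.segmentation import label_components

VOX = (0.3, 0.18, 0.18)
PAPER_VOXEL_UM3 = 0.3 * 0.18 * 0.18  # 0.009720


def _pair_with_overlap(vol_a=100, vol_b=40, overlap=10):
    n = vol_a + vol_b - overlap + 2
    a = np.zeros((1, 1, n), bool)
    a[0, 0, :vol_a] = True
    b = np.zeros((1, 1, n), bool)
    b[0, 0, vol_a - overlap:vol_a - overlap + vol_b] = True
    return (label_components(a, voxel_size_zyx=VOX, channel="a"),
            label_components(b, voxel_size_zyx=VOX, channel="b"))


class TestColocalizePair:
    def test_quarter_of_smaller_object_is_colocalized(self):
        objs_a, objs_b = _pair_with_overlap(100, 40, 10)
        (rec,) = gq.colocalize_pair(objs_a, objs_b)
        assert rec.fraction_of_b == pytest.approx(0.25)
        assert rec.fraction_of_a == pytest.approx(0.10)
        assert rec.colocalized

    def test_just_below_quarter_is_not(self):
        objs_a, objs_b = _pair_with_overlap(100, 40, 9)
        (rec,) = gq.colocalize_pair(objs_a, objs_b)
        assert rec.fraction_of_b == pytest.approx(0.225)
        assert not rec.colocalized

    def test_identical_objects_fully_colocalized(self):
        mask = np.zeros((2, 6, 6), bool)
        mask[0, 1:4, 1:4] = True
        objs = label_components(mask, voxel_size_zyx=VOX)
        (rec,) = gq.colocalize_pair(objs, objs)
        assert rec.fraction_of_a == rec.fraction_of_b == 1.0
        assert rec.colocalized

    def test_anchor_object_rule_changes_verdict(self):
        objs_a, objs_b = _pair_with_overlap(100, 40, 10)
        (rec,) = gq.colocalize_pair(
            objs_a, objs_b, ColocalizationParams(denominator_rule="object_a"))
        assert not rec.colocalized  # 10/100 < 25% of the larger object

    def test_symmetry_under_min_object_rule(self, rng):
        la = label_components(rng.random((4, 12, 12)) < 0.3, voxel_size_zyx=VOX)
        lb = label_components(rng.random((4, 12, 12)) < 0.3, voxel_size_zyx=VOX)
        fwd = {(r.object_a_id, r.object_b_id): r.colocalized
               for r in gq.colocalize_pair(la, lb)}
        rev = {(r.object_b_id, r.object_a_id): r.colocalized
               for r in gq.colocalize_pair(lb, la)}
        assert fwd == rev

    def test_overlap_bounds_on_random_masks(self, rng):
        la = label_components(rng.random((4, 16, 16)) < 0.4, voxel_size_zyx=VOX)
        lb = label_components(rng.random((4, 16, 16)) < 0.4, voxel_size_zyx=VOX)
        vol_a, vol_b = la.voxel_counts, lb.voxel_counts
        recs = gq.colocalize_pair(la, lb)
        assert recs, "dense random masks should intersect"
        for r in recs:
            assert 0.0 <= r.fraction_of_a <= 1.0
            assert 0.0 <= r.fraction_of_b <= 1.0
            assert r.overlap_voxels <= min(vol_a[r.object_a_id], vol_b[r.object_b_id])

    def test_pair_overlaps_partition_voxel_intersection(self, rng):
        ma = rng.random((4, 16, 16)) < 0.4
        mb = rng.random((4, 16, 16)) < 0.4
        la = label_components(ma, voxel_size_zyx=VOX)
        lb = label_components(mb, voxel_size_zyx=VOX)
        recs = gq.colocalize_pair(la, lb)
        assert sum(r.overlap_voxels for r in recs) == int((ma & mb).sum())

    def test_mismatched_shapes_rejected(self):
        la = label_components(np.zeros((2, 4, 4), bool), voxel_size_zyx=VOX)
        lb = label_components(np.zeros((2, 4, 5), bool), voxel_size_zyx=VOX)
        with pytest.raises(ValueError, match="shape"):
            gq.colocalize_pair(la, lb)


class TestColocalizedVolume:
    def test_disjoint_masks_zero(self):
        a = np.zeros((2, 4, 4), bool)
        b = np.zeros((2, 4, 4), bool)
        a[0, 0, 0] = b[1, 1, 1] = True
        assert gq.colocalized_volume(a, b, VOX) == 0.0

    def test_punctum_inside_glia_at_confocal_voxel_size(self):
        # 20 shared voxels at 0.3 x 0.18 x 0.18 um -> 0.1944 um^3
        a = np.zeros((3, 5, 5), bool)
        a[:, :, :] = True
        b = np.zeros((3, 5, 5), bool)
        b[0, :4, :5] = True  # 20 voxels
        assert gq.colocalized_volume(a, b, VOX) == pytest.approx(20 * PAPER_VOXEL_UM3)
        assert 20 * PAPER_VOXEL_UM3 == pytest.approx(0.1944)

    def test_matches_and_count_oracle(self, rng):
        a = rng.random((4, 10, 10)) < 0.5
        b = rng.random((4, 10, 10)) < 0.5
        expected = sum(
            1 for z in range(4) for y in range(10) for x in range(10)
            if a[z, y, x] and b[z, y, x]) * np.prod(VOX)
        assert gq.colocalized_volume(a, b, VOX) == pytest.approx(expected)


class TestTripleColocalizedVolume:
    def test_any_empty_mask_zero(self, rng):
        a = rng.random((3, 8, 8)) < 0.5
        b = rng.random((3, 8, 8)) < 0.5
        empty = np.zeros((3, 8, 8), bool)
        assert gq.triple_colocalized_volume(a, b, empty, VOX) == 0.0

    def test_identical_masks_give_mask_volume(self, rng):
        a = rng.random((3, 8, 8)) < 0.4
        expected = a.sum() * np.prod(VOX)
        assert gq.triple_colocalized_volume(a, a, a, VOX) == pytest.approx(expected)

    def test_matches_triple_and_oracle(self, rng):
        a = rng.random((3, 8, 8)) < 0.6
        b = rng.random((3, 8, 8)) < 0.6
        c = rng.random((3, 8, 8)) < 0.6
        expected = int(np.logical_and(np.logical_and(a, b), c).sum()) * np.prod(VOX)
        assert gq.triple_colocalized_volume(a, b, c, VOX) == pytest.approx(expected)


class TestStackMetrics:
    def _stack_and_objects(self, glia_voxels):
        shape = (10, 10, 10)  # 1000 voxels
        glia = np.zeros(shape, bool)
        glia.ravel()[:glia_voxels] = True
        syn = np.zeros(shape, bool)
        syn.ravel()[:100] = True
        channels = {"Syn1": syn.astype(np.uint8) * 100,
                    "GFAP": glia.astype(np.uint8) * 100}
        stack = gq.ImageStack(channels=channels, voxel_size_zyx=(1.0, 1.0, 1.0),
                              stack_id="s", case_id="c")
        objs = {"Syn1": label_components(syn, voxel_size_zyx=(1, 1, 1), channel="Syn1"),
                "GFAP": label_components(glia, voxel_size_zyx=(1, 1, 1), channel="GFAP")}
        recs = {("Syn1", "GFAP"): gq.colocalize_pair(objs["Syn1"], objs["GFAP"])}
        return stack, objs, recs

    def test_glial_normalisation_worked_example(self):
        # colocalized 50 of glial 1000 -> 0.05; coloc 100 of 1000-voxel stack -> 0.1
        stack, objs, recs = self._stack_and_objects(glia_voxels=1000)
        m = compute_stack_metrics(stack, objs, recs)
        pm = m.pair_metrics[("Syn1", "GFAP")]
        assert pm["volume_um3"] == pytest.approx(100.0)  # syn fully inside glia
        assert pm["per_stack_volume"] == pytest.approx(0.1)
        assert pm["per_host_volume"] == pytest.approx(100.0 / 1000.0)

    def test_zero_glial_volume_flags_missing_normalisation(self):
        stack, objs, recs = self._stack_and_objects(glia_voxels=0)
        m = compute_stack_metrics(stack, objs, recs)
        pm = m.pair_metrics[("Syn1", "GFAP")]
        assert pm["per_host_volume"] is None
        assert pm["volume_um3"] == 0.0
        assert m.channel_volume_fraction["Syn1"] == pytest.approx(0.1)

    def test_near_far_volumes_sum_to_total(self, rng):
        stack, objs, recs = self._stack_and_objects(glia_voxels=500)
        plaque = np.zeros((10, 10, 10), bool)
        plaque[5, 5, 5] = True
        m = compute_stack_metrics(stack, objs, recs, plaque_mask=plaque,
                                  params=ColocalizationParams(plaque_distance_um=3.0))
        total = colocalized_record_volume(recs[("Syn1", "GFAP")])
        nf = m.near_far_volumes[("Syn1", "GFAP")]
        assert nf["near"] + nf["far"] == pytest.approx(total)
        assert m.plaque_free is False


class TestPlaqueStratify:
    def _objects(self):
        mask = np.zeros((8, 16, 16), bool)
        mask[0, 0, 0:2] = True    # near the plaque below
        mask[7, 14, 14] = True    # far corner
        return label_components(mask, voxel_size_zyx=(1.0, 1.0, 1.0))

    def test_overlapping_object_is_near(self):
        objs = self._objects()
        plaque = np.zeros((8, 16, 16), bool)
        plaque[0, 0, 0] = True
        labels, plaque_free = gq.plaque_stratify(objs, plaque, distance_um=1.0)
        assert not plaque_free
        near_ids = [o.object_id for o in objs.objects if o.bbox[0][0] == 0]
        assert all(labels[i] == "near" for i in near_ids)

    def test_distant_object_is_far(self):
        objs = self._objects()
        plaque = np.zeros((8, 16, 16), bool)
        plaque[0, 0, 0] = True
        labels, _ = gq.plaque_stratify(objs, plaque, distance_um=5.0)
        far_ids = [o.object_id for o in objs.objects if o.bbox[0][0] == 7]
        assert all(labels[i] == "far" for i in far_ids)

    def test_anisotropic_distance_respects_voxel_size(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[6, 0, 0] = True  # 6 z-steps from plaque at z=0
        objs = label_components(mask, voxel_size_zyx=(0.3, 0.18, 0.18))
        plaque = np.zeros((8, 8, 8), bool)
        plaque[0, 0, 0] = True
        # 6 * 0.3 = 1.8 um: near at 2.0 um, far at 1.5 um
        assert gq.plaque_stratify(objs, plaque, 2.0)[0][1] == "near"
        assert gq.plaque_stratify(objs, plaque, 1.5)[0][1] == "far"

    def test_empty_plaque_mask_flags_plaque_free(self):
        objs = self._objects()
        labels, plaque_free = gq.plaque_stratify(
            objs, np.zeros((8, 16, 16), bool), 10.0)
        assert plaque_free and labels == {}


class TestCohortMonotonicity:
    def test_colocalized_volume_tracks_planted_engulfment(self):
        """Across stacks, measured pair colocalization follows planted truth."""
        from scipy.stats import spearmanr

        pairs = []
        for i, ef in enumerate((0.05, 0.15, 0.3, 0.45)):
            params = gq.StackSimParams(shape_zyx=(24, 96, 96),
                                       engulfed_fraction=ef)
            stack, truth = gq.generate_stack(params, 30 + i)
            objs = gq.segment_stack(stack, channels=["Syn1", "GFAP"])
            recs = gq.colocalize_pair(objs["Syn1"], objs["GFAP"])
            pairs.append((truth.engulfed_volume_um3,
                          colocalized_record_volume(recs)))
        truth_v, seg_v = zip(*pairs)
        rho, _ = spearmanr(truth_v, seg_v)
        assert rho == 1.0  # strictly increasing recovery across these stacks
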