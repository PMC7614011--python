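import numpy as np
import pytest

import fetalrecon as fr
from fetalrecon import (GridMismatchError, NoUsableStacksError, RigidTransform,
                        StackMetrics, apply_inclusion, build_template,
                        compute_metrics, motion_score, ncc, select_reference,
                        similarity_score, volume_deviation)
from fetalrecon.core import ImageVolume, Stack, centered_affine
from tests.conftest import DESK_ACQ


def naive_ncc(a, b, region):
    """Brute-force two-pass Pearson correlation oracle."""
    xs, ys = [], []
    it = np.ndindex(a.shape)
    for idx in it:
        if region[idx]:
            xs.append(float(a[idx]))
            ys.append(float(b[idx]))
    if len(xs) < 2:
        return 0.0
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = sum((x - mx) ** 2 for x in xs) ** 0.5
    dy = sum((y - my) ** 2 for y in ys) ** 0.5
    if dx == 0 or dy == 0:
        return 0.0
    return num / (dx * dy)


class TestNcc:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=(8, 8, 8)) + 5
        assert ncc(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_positive_affine_intensity_invariance(self, rng):
        x = rng.normal(size=(8, 8, 8)) + 5
        assert ncc(x, 3.2 * x + 11.0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_loop(self, rng):
        for _ in range(3):
            a = rng.normal(size=(16, 16, 16)) + 2
            b = rng.normal(size=(16, 16, 16)) + 2
            a[rng.random(a.shape) < 0.2] = 0.0  # exercise nonzero-overlap rule
            region = (a != 0) & (b != 0)
            assert ncc(a, b) == pytest.approx(naive_ncc(a, b, region),
                                              abs=1e-12)

    def test_zero_variance_returns_zero(self):
        assert ncc(np.ones((4, 4, 4)), np.ones((4, 4, 4))) == 0.0

    def test_tiny_region_returns_zero(self):
        a = np.zeros((4, 4, 4))
        a[0, 0, 0] = 1.0
        assert ncc(a, a) == 0.0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(GridMismatchError):
            ncc(np.ones((4, 4, 4)), np.ones((5, 5, 5)))
        a = ImageVolume(np.random.rand(4, 4, 4), np.eye(4))
        b = ImageVolume(a.data, centered_affine((4, 4, 4), 2.0))
        with pytest.raises(GridMismatchError):
            ncc(a, b)


class TestMotionScore:
    def test_identical_slices_score_one(self, rng):
        sl = rng.normal(size=(12, 12)) + 3
        stack = np.repeat(sl[:, :, None], 8, axis=2)
        assert motion_score(stack) == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_pair_loop(self, rng):
        stack = rng.normal(size=(10, 10, 10)) + 2
        expected = np.mean([
            naive_ncc(stack[:, :, j], stack[:, :, j + 1],
                      (stack[:, :, j] != 0) & (stack[:, :, j + 1] != 0))
            for j in range(9)])
        assert motion_score(stack) == pytest.approx(expected, abs=1e-12)

    def test_slice_shuffling_lowers_score(self, desk_phantom, rng):
        _, img, glob, organs = desk_phantom
        st = fr.simulate_stack(img, RigidTransform.identity(), DESK_ACQ,
                               seed=21)
        base = motion_score(st)
        perm = rng.permutation(st.n_slices)
        assert motion_score(st.data[:, :, perm]) < base

    def test_requires_two_slices(self):
        with pytest.raises(ValueError):
            motion_score(np.zeros((4, 4, 1)))


class TestSimilarityScore:
    def test_identical_stacks_score_one(self, rng):
        x = rng.normal(size=(8, 8, 8)) + 4
        vols = [x.copy() for _ in range(4)]
        for i in range(4):
            assert similarity_score(i, vols) == pytest.approx(1.0, abs=1e-12)

    def test_single_stack_self_term_only(self, rng):
        x = rng.normal(size=(6, 6, 6)) + 1
        assert similarity_score(0, [x]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        vols = [rng.normal(size=(12, 12, 12)) + 2 for _ in range(4)]
        for i in range(4):
            expected = np.mean([
                naive_ncc(vols[i], v, (vols[i] != 0) & (v != 0))
                for v in vols])
            assert similarity_score(i, vols) == pytest.approx(expected,
                                                              abs=1e-12)


class TestVolumeDeviation:
    def test_equal_volumes_zero(self):
        assert volume_deviation([100, 100, 100]) == [0, 0, 0]

    def test_arithmetic(self):
        out = volume_deviation([80, 100, 120])
        assert out == pytest.approx([0.2, 0.0, 0.2], abs=1e-12)

    def test_small_volume_crosses_exclusion_line(self):
        out = volume_deviation([50, 100, 100, 100])
        assert out[0] == pytest.approx(0.5)
        m = [StackMetrics(f"s{i}", 0.9, 0.9, c) for i, c in enumerate(out)]
        flagged = apply_inclusion(m)
        assert not flagged[0].included
        assert all(x.included for x in flagged[1:])

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            volume_deviation([0.0, 0.0])


class TestInclusionRules:
    def test_low_motion_score_excluded(self):
        m = [StackMetrics("a", 0.9, 0.7, 0.0),
             StackMetrics("b", 0.9, 0.7, 0.0),
             StackMetrics("c", 0.3, 0.7, 0.0)]
        out = apply_inclusion(m)
        assert [x.included for x in out] == [True, True, False]
        assert "motion" in out[2].reason

    def test_strict_boundary_on_ccor(self):
        # exactly half of the maximum does NOT pass a strict inequality
        m = [StackMetrics("a", 0.8, 0.9, 0.0),
             StackMetrics("b", 0.4, 0.9, 0.0)]
        out = apply_inclusion(m)
        assert not out[1].included

    def test_strict_boundary_on_cvol(self):
        m = [StackMetrics("a", 0.9, 0.9, 0.40),
             StackMetrics("b", 0.9, 0.9, 0.39)]
        out = apply_inclusion(m)
        assert not out[0].included and out[1].included

    def test_low_similarity_excluded(self):
        m = [StackMetrics("a", 0.9, 0.9, 0.0),
             StackMetrics("b", 0.9, 0.44, 0.0)]
        out = apply_inclusion(m)
        assert not out[1].included and "dissimilar" in out[1].reason

    def test_single_stack_always_included(self):
        out = apply_inclusion([StackMetrics("only", 0.5, 0.5, 0.0)])
        assert out[0].included

    def test_all_excluded_is_explicit_failure(self):
        m = [StackMetrics("a", 0.9, 0.9, 0.9),
             StackMetrics("b", 0.9, 0.9, 0.8)]
        with pytest.raises(NoUsableStacksError) as err:
            apply_inclusion(m)
        assert "a" in str(err.value) and "b" in str(err.value)


class TestSelectReference:
    def test_tie_breaks_to_lowest_index(self):
        m = apply_inclusion([StackMetrics("a", 0.8, 0.9, 0.0),
                             StackMetrics("b", 0.9, 0.8, 0.0)])
        assert select_reference(m) == 0

    def test_highest_product_wins(self):
        m = apply_inclusion([StackMetrics("a", 0.5, 0.5, 0.0),
                             StackMetrics("b", 0.9, 0.9, 0.0)])
        assert select_reference(m) == 1

    def test_excluded_stacks_not_eligible(self):
        m = apply_inclusion([StackMetrics("a", 0.9, 0.9, 0.9),
                             StackMetrics("b", 0.6, 0.6, 0.0)])
        assert select_reference(m) == 1


class TestComputeMetricsProperties:
    def _stacks(self, desk_phantom, n=3, jitter=0.0):
        _, img, glob, organs = desk_phantom
        acq = fr.AcquisitionSpec(in_plane_mm=1.75, slice_thickness_mm=3.5,
                                 slice_spacing_mm=1.75, noise_sigma=1.0,
                                 jitter_rot_deg=jitter,
                                 jitter_trans_mm=jitter)
        out = []
        for i in range(n):
            st = fr.simulate_stack(img, RigidTransform.identity(), acq,
                                   seed=30 + i, labels=(glob, organs),
                                   name=f"s{i}")
            out.append(st)
        return out

    def test_intensity_scale_free_decisions(self, desk_phantom):
        stacks = self._stacks(desk_phantom)
        masks = [np.isin(s.truth_organs.data, [1, 3]) for s in stacks]
        T = [RigidTransform.identity()] * len(stacks)
        m1 = apply_inclusion(compute_metrics(stacks, T, masks))
        scaled = [s.with_data(s.data * 7.5) for s in stacks]
        m2 = apply_inclusion(compute_metrics(scaled, T, masks))
        assert [x.included for x in m1] == [x.included for x in m2]
        for a, b in zip(m1, m2):
            assert a.ccor == pytest.approx(b.ccor, abs=1e-9)
            assert a.csim == pytest.approx(b.csim, abs=1e-9)

    def test_jittered_duplicate_never_selected_or_disruptive(
            self, desk_phantom):
        stacks = self._stacks(desk_phantom, n=3)
        bad = self._stacks(desk_phantom, n=4, jitter=6.0)[3]
        masks = [np.isin(s.truth_organs.data, [1, 3]) for s in stacks]
        T = [RigidTransform.identity()] * 3
        base = apply_inclusion(compute_metrics(stacks, T, masks))
        with_bad = stacks + [bad]
        masks_b = masks + [np.isin(bad.truth_organs.data, [1, 3])]
        m = apply_inclusion(compute_metrics(with_bad, T + [
            RigidTransform.identity()], masks_b))
        assert [x.included for x in m[:3]] == [x.included for x in base]
        assert select_reference(m) != 3
        assert m[3].ccor < min(x.ccor for x in m[:3])


class TestBuildTemplate:
    def _aligned_stacks(self, rng, n=3):
        A = centered_affine((12, 12, 12), 2.0)
        base = rng.normal(size=(12, 12, 12)) + 10
        return [Stack(base.copy(), A, name=f"s{i}") for i in range(n)]

    def test_median_rejects_single_artifact(self, rng):
        stacks = self._aligned_stacks(rng)
        stacks[0].data[5, 5, 5] = 10.0
        stacks[1].data[5, 5, 5] = 11.0
        stacks[2].data[5, 5, 5] = 300.0
        T = [RigidTransform.identity()] * 3
        masks = [np.ones((12, 12, 12), bool)] * 3
        tmpl, _ = build_template(stacks, T, masks)
        vox = tmpl.world_to_voxel(stacks[0].voxel_to_world([5., 5., 5.]))
        val = tmpl.data[tuple(np.round(vox).astype(int))]
        assert val == pytest.approx(11.0, abs=1.0)

    def test_order_invariance(self, rng):
        stacks = self._aligned_stacks(rng)
        for i, s in enumerate(stacks):
            s.data += i * rng.normal(size=s.shape)
        T = [RigidTransform.identity()] * 3
        masks = [np.ones((12, 12, 12), bool)] * 3
        t1, m1 = build_template(stacks, T, masks)
        t2, m2 = build_template(stacks[::-1], T, masks)
        assert np.allclose(t1.data, t2.data, atol=1e-12)
        assert np.array_equal(m1.data, m2.data)

    def test_single_stack_template_is_resampled_stack(self, rng):
        stacks = self._aligned_stacks(rng, n=1)
        T = [RigidTransform.identity()]
        masks = [np.ones((12, 12, 12), bool)]
        tmpl, mask = build_template(stacks, T, masks)
        # compare on the template grid
        ref = stacks[0].resample_to(tmpl.affine, tmpl.shape)
        cov = ImageVolume(np.ones((12, 12, 12)),
                          stacks[0].affine).resample_to(
            tmpl.affine, tmpl.shape).data > 0.5
        assert np.allclose(tmpl.data[cov], ref.data[cov], atol=1e-9)
        assert mask.data[cov].any()

    def test_majority_vote_mask(self, rng):
        stacks = self._aligned_stacks(rng)
        masks = [np.zeros((12, 12, 12), bool) for _ in range(3)]
        masks[0][4:8, 4:8, 4:8] = True
        masks[1][4:8, 4:8, 4:8] = True
        masks[2][0:2, 0:2, 0:2] = True  # minority voxels
        T = [RigidTransform.identity()] * 3
        _, mask = build_template(stacks, T, masks)
        vox = mask.world_to_voxel(stacks[0].voxel_to_world([5., 5., 5.]))
        assert mask.data[tuple(np.round(vox).astype(int))] == 1
        vox0 = mask.world_to_voxel(stacks[0].voxel_to_world([1., 1., 1.]))
        assert mask.data[tuple(np.round(vox0).astype(int))] == 0
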