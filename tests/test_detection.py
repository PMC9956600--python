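"""Detection core: anchors, RoI-Align oracle, dynamic training rules, NMS."""

import numpy as np
import pytest

from snagdet import boxes as B
from snagdet.detector import (AnchorConfig, DynamicTrainState, ModelConfig,
                              SnagDetector, assign_training_labels,
                              generate_level_anchors, roi_align_batch,
                              roi_align_pool, smooth_l1, update_dynamic_state)
from snagdet.nn import Tensor


class TestBoxUtils:
    def test_encode_decode_roundtrip(self, rng):
        anchors = np.column_stack([rng.uniform(0, 50, 20), rng.uniform(0, 50, 20),
                                   rng.uniform(60, 100, 20), rng.uniform(60, 100, 20)])
        boxes = anchors + rng.uniform(-5, 5, anchors.shape)
        back = B.decode_boxes(B.encode_boxes(boxes, anchors), anchors)
        np.testing.assert_allclose(back, boxes, atol=1e-6)

    def test_zero_deltas_return_anchor(self):
        anchor = np.array([[10.0, 10.0, 30.0, 50.0]])
        np.testing.assert_allclose(B.decode_boxes(np.zeros((1, 4)), anchor), anchor)

    def test_nms_suppresses_duplicates(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], float)
        keep = B.nms(boxes, np.array([0.9, 0.8]), 0.7)
        assert list(keep) == [0]

    def test_nms_independent_of_input_order(self, rng):
        boxes = rng.uniform(0, 80, (15, 2))
        boxes = np.hstack([boxes, boxes + rng.uniform(5, 30, (15, 2))])
        scores = rng.permutation(15) / 15.0 + 0.01   # distinct scores
        keep = B.nms(boxes, scores, 0.5)
        perm = rng.permutation(15)
        keep_p = B.nms(boxes[perm], scores[perm], 0.5)
        assert sorted(perm[keep_p]) == sorted(keep)


class TestAnchors:
    def test_counts_on_two_level_toy(self):
        cfg = AnchorConfig()
        n = len(generate_level_anchors(2, 2, 4, cfg)) + \
            len(generate_level_anchors(1, 1, 8, cfg))
        assert n == 15  # (4 + 1) positions × 3 ratios

    def test_anchor_geometry(self):
        cfg = AnchorConfig(scale_factor=2.0, ratios=(1.0,))
        anc = generate_level_anchors(1, 1, 4, cfg)
        np.testing.assert_allclose(anc, [[-2.0, -2.0, 6.0, 6.0]])  # 8×8 at (2,2)

    def test_ratio_preserves_area(self):
        cfg = AnchorConfig(scale_factor=8.0)
        anc = generate_level_anchors(1, 1, 4, cfg)
        np.testing.assert_allclose(B.box_area(anc), 32.0 * 32.0, rtol=1e-9)


class TestRoIAlign:
    def test_constant_map_pools_to_constant(self):
        fm = Tensor(np.full((6, 6, 2), 3.0))
        out = roi_align_pool(fm, np.array([1.0, 1.0, 5.0, 5.0]), 2)
        np.testing.assert_allclose(out.numpy(), 3.0)

    def test_matches_brute_force_bilinear_sampler(self, rng):
        """4×4 ramp map, arbitrary box: brute-force loop over bins and
        sample points with the same half-pixel-center convention."""
        fm_arr = np.arange(16, dtype=float).reshape(4, 4, 1)
        box = np.array([0.5, 0.7, 3.2, 3.9])
        out_size, s = 2, 2
        got = roi_align_pool(Tensor(fm_arr), box, out_size, s).numpy()

        def sample(y, x):
            u, v = np.clip(y - 0.5, 0, 3), np.clip(x - 0.5, 0, 3)
            y0, x0 = int(np.floor(u)), int(np.floor(v))
            y1, x1 = min(y0 + 1, 3), min(x0 + 1, 3)
            fy, fx = u - y0, v - x0
            return (fm_arr[y0, x0, 0] * (1 - fy) * (1 - fx)
                    + fm_arr[y0, x1, 0] * (1 - fy) * fx
                    + fm_arr[y1, x0, 0] * fy * (1 - fx)
                    + fm_arr[y1, x1, 0] * fy * fx)

        want = np.zeros((out_size, out_size))
        bh = (box[3] - box[1]) / out_size
        bw = (box[2] - box[0]) / out_size
        for i in range(out_size):
            for j in range(out_size):
                acc = 0.0
                for p in range(s):
                    for q in range(s):
                        y = box[1] + (i + (p + 0.5) / s) * bh
                        x = box[0] + (j + (q + 0.5) / s) * bw
                        acc += sample(y, x)
                want[i, j] = acc / (s * s)
        np.testing.assert_allclose(got[:, :, 0], want, atol=1e-10)

    def test_full_map_box_recovers_map_at_matching_resolution(self):
        """Pooling the whole map with output = map size and dense sampling
        reproduces the map (interior bins sample pixel centers exactly)."""
        fm_arr = np.arange(16, dtype=float).reshape(4, 4, 1)
        out = roi_align_pool(Tensor(fm_arr), np.array([0.0, 0.0, 4.0, 4.0]),
                             4, 1).numpy()
        np.testing.assert_allclose(out[1:3, 1:3], fm_arr[1:3, 1:3])

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            roi_align_pool(Tensor(np.zeros((4, 4, 1))),
                           np.array([1.0, 1.0, 1.0, 3.0]), 2)

    def test_gradient_flows_through_pooling(self):
        from snagdet.nn import Parameter
        fm = Parameter(np.arange(16, dtype=float).reshape(4, 4, 1))
        out = roi_align_batch(fm, np.array([[0.5, 0.5, 3.5, 3.5]]), 2)
        out.sum().backward()
        assert fm.grad is not None and np.isfinite(fm.grad).all()
        np.testing.assert_allclose(fm.grad.sum(), 4.0)  # 2×2 bins of averages


class TestDynamicTraining:
    def test_defaults_before_first_boundary(self):
        state = DynamicTrainState()
        assert state.t_now == 0.5 and state.beta_now == 1.0

    def test_label_assignment_threshold_rules(self):
        gt = np.array([[0, 0, 10, 10]], float)
        state = DynamicTrainState(t_now=0.5)
        # IoU(b, gt) = 0.6 for this proposal
        prop = np.array([[0, 0, 10, 6]], float)
        assert B.compute_iou(prop[0], gt[0]) == pytest.approx(0.6)
        assert assign_training_labels(prop, gt, state)[0] == 1
        state.t_now = 0.7
        assert assign_training_labels(prop, gt, state)[0] == 0
        state.t_now = 0.6  # tie at the threshold is positive
        assert assign_training_labels(prop, gt, state)[0] == 1

    def test_no_ground_truth_gives_all_negative(self):
        labels = assign_training_labels(np.array([[0, 0, 5, 5]]),
                                        np.zeros((0, 4)), DynamicTrainState())
        assert labels.tolist() == [0]

    def test_threshold_update_is_mean_of_recorded_statistics(self):
        state = DynamicTrainState(update_interval=2)
        state.iou_record = [0.55, 0.65]
        state.error_record = [0.4, 0.2, 0.3]
        update_dynamic_state(state)
        assert state.t_now == pytest.approx(0.60)
        assert state.beta_now == pytest.approx(0.3)   # median
        assert state.iou_record == [] and state.error_record == []

    def test_update_with_empty_records_warns_and_keeps_state(self):
        state = DynamicTrainState()
        with pytest.warns(UserWarning):
            update_dynamic_state(state)
        assert state.t_now == 0.5 and state.beta_now == 1.0

    def test_threshold_clamped_to_bounds(self):
        state = DynamicTrainState()
        state.iou_record = [0.99]
        state.error_record = [10.0]
        update_dynamic_state(state)
        assert state.t_now == 0.9 and state.beta_now == 1.0

    def test_recorded_statistic_is_rank_selected(self):
        state = DynamicTrainState(k_i_quantile=0.75, k_beta=2)
        ious = np.array([0.1, 0.9, 0.5, 0.7])   # 75th pct rank → 0.9 (k=1)
        errs = np.array([0.3, 0.1, 0.2])        # 2nd smallest → 0.2
        state.record_iteration(ious, errs)
        assert state.iou_record == [0.9]
        assert state.error_record == [pytest.approx(0.2)]

    def test_scripted_stream_reproduces_update_sequence(self):
        """Spreadsheet-style oracle: feed two intervals of scripted
        statistics and check T_now/β_now after each boundary."""
        state = DynamicTrainState(update_interval=3, k_i_quantile=0.75, k_beta=1)
        script = [([0.4, 0.5], [0.30]), ([0.5, 0.6], [0.20]),
                  ([0.6, 0.7], [0.10])]
        for ious, errs in script:
            state.record_iteration(np.array(ious), np.array(errs))
            if state.at_boundary():
                update_dynamic_state(state)
        # per-iteration stats: max IoU (k=1 of 2 at 75th pct) = .5, .6, .7
        assert state.t_now == pytest.approx(np.mean([0.5, 0.6, 0.7]))
        assert state.beta_now == pytest.approx(np.median([0.3, 0.2, 0.1]))

    def test_t_now_nondecreasing_under_improving_curriculum(self):
        state = DynamicTrainState(update_interval=2, t_clamp=(0.0, 1.0))
        trace = [state.t_now]
        base = np.array([0.3, 0.4, 0.5, 0.6])
        for step in range(8):
            state.record_iteration(base + 0.05 * step, np.array([0.1]))
            if state.at_boundary():
                update_dynamic_state(state)
                trace.append(state.t_now)
        assert all(b >= a for a, b in zip(trace, trace[1:]))


class TestSmoothL1:
    @pytest.mark.parametrize("beta,x,want", [(1.0, 0.5, 0.125), (1.0, 2.0, 1.5),
                                             (0.5, 0.25, 0.0625)])
    def test_printed_values(self, beta, x, want):
        assert smooth_l1(x, beta) == pytest.approx(want)

    @pytest.mark.parametrize("beta", [0.1, 0.5, 1.0, 2.0])
    def test_continuous_at_transition(self, beta):
        eps = 1e-9
        below = smooth_l1(beta - eps, beta)
        above = smooth_l1(beta + eps, beta)
        assert abs(above - below) < 1e-7
        assert smooth_l1(beta, beta) == pytest.approx(0.5 * beta)

    def test_tensor_and_numpy_paths_agree(self, rng):
        x = rng.normal(size=(5, 4))
        np.testing.assert_allclose(smooth_l1(Tensor(x), 0.7).numpy(),
                                   smooth_l1(x, 0.7))

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            smooth_l1(1.0, 0.0)


class TestDetectorContracts:
    def test_random_model_outputs_valid_scores_and_boxes(self, tiny_model, rng):
        img = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
        dets = tiny_model.detect(img)
        for d in dets:
            assert 0.0 <= d.score <= 1.0
            x1, y1, x2, y2 = d.box
            assert 0 <= x1 < x2 <= 64 and 0 <= y1 < y2 <= 64

    def test_proposals_clipped_and_scored(self, tiny_model, rng):
        img = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
        P = tiny_model.pyramid(img)
        props = tiny_model.generate_proposals(P, (64, 64))
        assert len(props) > 0
        for p in props[:20]:
            assert 0.0 <= p.objectness <= 1.0
            assert p.level in {"P1", "P2", "P3", "P4"}

    def test_smoke_training_iterations_produce_finite_losses(self, rng):
        model = SnagDetector(ModelConfig.tiny_test(seed=1))
        state = DynamicTrainState()
        gen = np.random.default_rng(0)
        for _ in range(2):
            img = (gen.random((64, 64, 3)) * 255).astype(np.uint8)
            gt = np.array([[8, 8, 30, 30], [40, 35, 60, 58]], float)
            losses = model.training_losses(img, gt, state, gen)
            total = sum(float(v.numpy()) for v in losses.values())
            assert np.isfinite(total)
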