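"""Network architecture: shape contract, comparison-layer oracle, counting."""

from dataclasses import replace

import numpy as np
import pytest

from orbinet.nn import (INPUT_SHAPES, HalfComparison, Model, ModelConfig,
                        build_ablation, build_model, describe, forward,
                        half_depthwise_forward, load_checkpoint, planeset_batch,
                        save_checkpoint)
from orbinet.nn.model import SPLIT_MODES
from orbinet.preprocessing import PlaneSet


def _random_planeset(rng) -> PlaneSet:
    return PlaneSet(axial=rng.random((128, 128, 32)),
                    sagittal=rng.random((128, 128, 32)),
                    coronal=rng.random((64, 128, 32)))


def _batch(rng, planes=("axial", "coronal", "sagittal"), n=2):
    out = {}
    for p in planes:
        h, w, s = INPUT_SHAPES[p]
        out[p] = rng.random((n, s, h, w), dtype=np.float32)
    return out


class TestShapeContract:
    @pytest.mark.parametrize("stage", ["stage1", "stage2", "stage3", "proposed"])
    def test_post_layer2_maps_match_reduced_sizes(self, stage, rng):
        """Reduced sizes: axial 32x32x16, coronal 16x32x16, sagittal 32x32x32."""
        model = build_model(ModelConfig(stage=stage, n_classes=2))
        batch = _batch(rng)
        expected = {"axial": (32, 32, 16), "coronal": (16, 32, 16),
                    "sagittal": (32, 32, 32)}
        for plane, (h, w, c) in expected.items():
            feat = model.plane_embedding(batch, plane, upto="pool2")
            assert feat.shape == (2, c, h, w)
            # comparison output: 16 filters per orbit -> 16 x 2 = 32 flat
            cmp_out = model.plane_embedding(batch, plane, upto="compare")
            assert cmp_out.shape == (2, 32)
            fc_out = model.plane_embedding(batch, plane, upto="fc")
            assert fc_out.shape == (2, 4)

    @pytest.mark.parametrize("planes,width", [
        (("axial",), 4), (("axial", "coronal"), 8),
        (("axial", "coronal", "sagittal"), 12)])
    def test_head_input_width_scales_with_plane_count(self, planes, width, rng):
        model = build_model(ModelConfig(planes=planes, n_classes=2))
        assert model.head.w.value.shape == (1, width)
        logits = model.forward_batch(_batch(rng, planes))
        assert logits.shape == (2, 1)

    def test_three_class_head_softmax(self, rng):
        model = build_model(ModelConfig(n_classes=3))
        assert model.head.w.value.shape == (3, 12)
        proba = model.predict_proba(_batch(rng))
        assert proba.shape == (2, 3)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_binary_output_in_unit_interval(self, rng):
        model = build_model(ModelConfig(n_classes=2))
        ps = _random_planeset(rng)
        score = forward(model, ps)
        assert 0.0 < score < 1.0

    def test_zero_weight_head_gives_chance_scores(self, rng):
        for n_classes, expected in ((2, 0.5), (3, 1 / 3)):
            model = build_model(ModelConfig(n_classes=n_classes))
            model.head.w.value[...] = 0.0
            model.head.b.value[...] = 0.0
            proba = model.predict_proba(_batch(rng))
            assert np.allclose(proba, expected, atol=1e-7)

    def test_all_stages_same_output_shapes(self, rng):
        batch = _batch(rng)
        outs = [build_model(ModelConfig(stage=s, n_classes=2)).forward_batch(batch).shape
                for s in ("stage1", "stage2", "stage3", "proposed")]
        assert len(set(outs)) == 1

    def test_config_validation(self):
        with pytest.raises(ValueError, match="non-empty"):
            ModelConfig(planes=())
        with pytest.raises(ValueError, match="n_classes"):
            ModelConfig(n_classes=4)
        with pytest.raises(ValueError, match="orbit"):
            ModelConfig(conv1_out_channels={"axial": 32, "coronal": 16,
                                            "sagittal": 32})
        with pytest.raises(ValueError, match="stage"):
            build_ablation(ModelConfig(), "stage4")

    def test_shape_mismatch_names_plane(self, rng):
        model = build_model(ModelConfig(n_classes=2))
        batch = _batch(rng)
        batch["coronal"] = batch["coronal"][:, :, :32, :]
        with pytest.raises(ValueError, match="coronal"):
            model.forward_batch(batch)


class TestHalfDepthwise:
    def test_zero_weights_output_equals_bias(self, rng):
        feat = rng.standard_normal((16, 32, 32)).astype(np.float32)
        w = np.zeros((16, 32, 16))
        b = np.arange(16.0)
        out = half_depthwise_forward(feat, w, w, "width", b, b)
        assert out.shape == (16, 2)
        assert np.allclose(out, b[:, None])

    def test_delta_filter_picks_single_value(self, rng):
        feat = rng.standard_normal((16, 32, 32)).astype(np.float32)
        wl = np.zeros((16, 32, 16))
        c, i, j = 5, 7, 3
        wl[c, i, j] = 1.0
        out = half_depthwise_forward(feat, wl, np.zeros_like(wl), "width")
        left_half = feat[:, :, 16:]  # high width indices = patient left
        assert out[c, 0] == pytest.approx(left_half[c, i, j], rel=1e-6)

    @pytest.mark.parametrize("lr_axis,shape", [("width", (16, 32, 32)),
                                               ("slice", (32, 32, 32))])
    def test_matches_brute_force_sum(self, lr_axis, shape, rng):
        """Each output equals an explicit multiply-and-sum over its half."""
        for _ in range(20):
            feat = rng.standard_normal(shape).astype(np.float32)
            n = 16
            half_shape = ((n, shape[1], shape[2] // 2) if lr_axis == "width"
                          else (n, shape[1], shape[2]))
            wl = rng.standard_normal(half_shape)
            wr = rng.standard_normal(half_shape)
            bl, br = rng.standard_normal(n), rng.standard_normal(n)
            out = half_depthwise_forward(feat, wl, wr, lr_axis, bl, br)
            if lr_axis == "width":
                right, left = feat[:, :, :16], feat[:, :, 16:]
            else:
                right, left = feat[:16], feat[16:]
            for c in range(n):
                exp_l = float((left[c] * wl[c]).sum()) + bl[c]
                exp_r = float((right[c] * wr[c]).sum()) + br[c]
                assert out[c, 0] == pytest.approx(exp_l, rel=1e-5, abs=1e-4)
                assert out[c, 1] == pytest.approx(exp_r, rel=1e-5, abs=1e-4)

    def test_odd_split_dimension_is_error(self, rng):
        feat = rng.standard_normal((1, 16, 8, 7)).astype(np.float32)
        layer = HalfComparison("spatial", 16, (8, 3), "proposed",
                               np.random.default_rng(0))
        with pytest.raises(ValueError, match="odd"):
            layer.forward(feat)


class TestEquivariance:
    def test_lr_mirror_with_mirrored_swapped_weights_swaps_blocks(self, rng):
        """Flipping the patient along left-right and exchanging (and spatially
        mirroring) the per-side filters exchanges the left/right outputs."""
        layer = HalfComparison("spatial", 16, (32, 16), "proposed",
                               np.random.default_rng(0))
        feat = rng.standard_normal((3, 16, 32, 32)).astype(np.float32)
        out = layer.forward(feat)
        wl, wr = layer.w_left.value.copy(), layer.w_right.value.copy()
        bl, br = layer.b_left.value.copy(), layer.b_right.value.copy()
        layer.w_left.value[...] = wr[:, :, ::-1]
        layer.w_right.value[...] = wl[:, :, ::-1]
        layer.b_left.value[...] = br
        layer.b_right.value[...] = bl
        out_m = layer.forward(feat[:, :, :, ::-1])
        assert np.allclose(out[:, :16], out_m[:, 16:], atol=1e-5)
        assert np.allclose(out[:, 16:], out_m[:, :16], atol=1e-5)

    def test_mirror_right_tied_layer_is_symmetric_under_lr_flip(self, rng):
        """With mirror_right=True and tied filters, an lr flip of the input
        only swaps the two output blocks."""
        layer = HalfComparison("spatial", 16, (32, 16), "stage3",
                               np.random.default_rng(0), mirror_right=True)
        feat = rng.standard_normal((2, 16, 32, 32)).astype(np.float32)
        out = layer.forward(feat)
        out_m = layer.forward(feat[:, :, :, ::-1])
        assert np.allclose(out[:, :16], out_m[:, 16:], atol=1e-5)
        assert np.allclose(out[:, 16:], out_m[:, :16], atol=1e-5)


class TestParameterAccounting:
    def test_head_count_closed_form(self):
        model = build_model(ModelConfig(n_classes=2))
        assert model.parameter_breakdown()["head"] == 12 + 1

    def test_proposed_axial_comparison_count(self):
        model = build_model(ModelConfig(stage="proposed", n_classes=2))
        # 2 sides x 16 channels x (32x16 weights + 1 bias)
        assert model.parameter_breakdown()["axial.compare"] == 16416

    def test_stage3_axial_is_half_proposed_weights_plus_shared_biases(self):
        prop = build_model(ModelConfig(stage="proposed", n_classes=2))
        st3 = build_model(ModelConfig(stage="stage3", n_classes=2))
        prop_w = 2 * 16 * (32 * 16)
        assert st3.parameter_breakdown()["axial.compare"] == prop_w // 2 + 16
        assert prop.parameter_breakdown()["axial.compare"] == prop_w + 32

    def test_count_strictly_decreases_stage1_to_stage2(self):
        counts = {s: build_model(ModelConfig(stage=s, n_classes=2)).parameter_count()
                  for s in ("stage1", "stage2", "stage3", "proposed")}
        assert counts["stage1"] > counts["stage2"]
        assert counts["stage2"] > counts["stage3"]
        assert counts["proposed"] > counts["stage3"]

    def test_proposed_equals_stage3_plus_one_extra_side_per_plane(self):
        cfg = ModelConfig(n_classes=2)
        st3 = build_model(replace(cfg, stage="stage3")).parameter_count()
        prop = build_model(replace(cfg, stage="proposed")).parameter_count()
        extra = 0
        for plane in cfg.planes:
            fh, fw, c = cfg.feature_shape(plane)
            hh, hw = ((fh, fw // 2) if SPLIT_MODES[plane] == "spatial"
                      else (fh, fw))
            extra += 16 * (hh * hw) + 16  # one per-side filter tensor + biases
        assert prop == st3 + extra

    def test_breakdown_sums_to_total(self):
        model = build_model(ModelConfig(stage="stage1", n_classes=3))
        assert sum(model.parameter_breakdown().values()) == model.parameter_count()


class TestDeterminismAndSerialization:
    def test_same_seed_same_weights_and_outputs(self, rng):
        batch = _batch(rng)
        a = build_model(ModelConfig(n_classes=2, seed=7))
        b = build_model(ModelConfig(n_classes=2, seed=7))
        assert all(np.array_equal(x, y) for x, y in
                   zip(a.state_dict(), b.state_dict()))
        assert np.array_equal(a.forward_batch(batch), b.forward_batch(batch))
        c = build_model(ModelConfig(n_classes=2, seed=8))
        assert not all(np.array_equal(x, y) for x, y in
                       zip(a.state_dict(), c.state_dict()))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_model(ModelConfig(n_classes=3, stage="stage2", seed=5))
        save_checkpoint(model, tmp_path / "m.npz")
        loaded = load_checkpoint(tmp_path / "m.npz")
        assert loaded.config == model.config
        batch = _batch(rng)
        assert np.array_equal(model.forward_batch(batch),
                              loaded.forward_batch(batch))

    def test_describe_mentions_all_planes(self):
        text = describe(build_model(ModelConfig(n_classes=2)))
        for plane in ("axial", "coronal", "sagittal"):
            assert plane in text
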