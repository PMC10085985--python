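"""Spot detection, confidence scoring, the trainable surrogate, attribution."""

import dataclasses

import numpy as np
import pytest

from tearfilm import classify as cl
from tearfilm import simulate as sim
from tearfilm.preprocess import detect_corneal_roi, standardize

from conftest import brute_force_spots, make_config


def render_standardized(config, state):
    """Render a scene and push it through ROI detection + standardization."""
    frame = sim.render_frame(config, state)
    roi = detect_corneal_roi(frame)
    return standardize(frame, roi)


@pytest.fixture(scope="module")
def spot_scene():
    """Noiseless scene helpers: frames with zero, one, or two spots."""
    config = make_config((2.0, 3.0, 2.5), seed=520, artifact_rate=0.0, noise_sd=0.0)
    gt = sim.ground_truth(config)
    start, _ = gt.segments[0]
    i_open = int(round((start + 0.5) * config.fps))  # before breakup at +2.0
    i_spot = int(round((start + 3.0) * config.fps))  # 1 s after breakup
    clean = render_standardized(config, sim.scene_state(config, i_open, gt))
    spotted_state = sim.scene_state(config, i_spot, gt)
    spotted = render_standardized(config, spotted_state)
    return config, gt, clean, spotted, spotted_state


class TestDetectSpots:
    def test_uniform_disc_has_no_spots(self, spot_scene):
        clean = spot_scene[2]
        assert cl.detect_spots(clean) == []

    def test_single_spot_area_matches_truth(self, spot_scene):
        config, gt, _, spotted, state = spot_scene
        spots = cl.detect_spots(spotted)
        assert len(spots) == 1
        (sx, sy, sr) = state.spots[0]
        # expected area in standardized coordinates
        scale = 384.0 / (2.0 * gt.disc_radius_px * 1.1)
        expected = np.pi * (sr * scale) ** 2
        assert abs(spots[0].area_px - expected) / expected <= 0.2

    def test_two_separated_spots_found(self, spot_scene):
        config, gt, *_ = spot_scene
        cx, cy = gt.disc_center_xy
        r = gt.disc_radius_px
        state = sim.FrameState(
            frame_index=0, timestamp_s=0.0, eye_open=True,
            spots=[(cx - 0.4 * r, cy, 10.0), (cx + 0.4 * r, cy, 8.0)],
            artifact=None, label="positive",
        )
        frame = render_standardized(config, state)
        spots = cl.detect_spots(frame)
        assert len(spots) == 2
        assert spots[0].area_px > spots[1].area_px

    def test_agrees_with_brute_force_oracle(self, noiseless_recording):
        """detect_spots == independent threshold + flood-fill scan, exactly."""
        _, _, gt, records = noiseless_recording
        params = cl.SpotDetectionParams()
        mask = cl.standard_corneal_mask(384, params.margin_frac, params.mask_erosion)
        checked = 0
        for r in records[::4]:
            if not r.quality.passed:
                continue
            green = r.image[..., 1].astype(np.float64)
            bg = float(np.median(green[mask]))
            oracle = brute_force_spots(green, mask, params.depth_frac * bg, params.min_area)
            ours = sorted(s.area_px for s in cl.detect_spots(r.image, params))
            assert ours == oracle
            checked += 1
        assert checked >= 10

    def test_rejects_unstandardized_shape(self):
        with pytest.raises(ValueError, match="standardized"):
            cl.detect_spots(np.zeros((100, 100, 3)))


class TestClassifyFrame:
    def test_spotless_frame_is_negative(self, spot_scene):
        label, conf = cl.classify_frame(spot_scene[2], cl.RuleBasedClassifier())
        assert label == "negative"
        assert conf < 0.5

    def test_large_deep_spot_saturates(self, spot_scene):
        config, gt, *_ = spot_scene
        cx, cy = gt.disc_center_xy
        state = sim.FrameState(
            frame_index=0, timestamp_s=0.0, eye_open=True,
            spots=[(cx, cy, 0.5 * gt.disc_radius_px)], artifact=None, label="positive",
        )
        frame = render_standardized(config, state)
        label, conf = cl.classify_frame(frame, cl.RuleBasedClassifier())
        assert label == "positive"
        assert conf > 0.99

    def test_noiseless_video_reproduces_truth_exactly(self, noiseless_recording):
        _, _, gt, records = noiseless_recording
        model = cl.RuleBasedClassifier()
        n = 0
        for r in records:
            truth = gt.per_frame_labels[r.source_index]
            if r.quality.passed and truth in ("positive", "negative"):
                label, _ = cl.classify_frame(r.image, model)
                assert label == truth
                n += 1
        assert n >= 50

    def test_confidence_monotone_in_spot_evidence(self, spot_scene):
        config, gt, *_ = spot_scene
        cx, cy = gt.disc_center_xy
        model = cl.RuleBasedClassifier()

        def conf_for(spots, depth=None):
            c = config if depth is None else dataclasses.replace(config, spot_depth=depth)
            state = sim.FrameState(
                frame_index=0, timestamp_s=0.0, eye_open=True,
                spots=spots, artifact=None, label="positive",
            )
            return model.predict_confidence(render_standardized(c, state))

        one = conf_for([(cx - 20, cy, 10.0)])
        deeper = conf_for([(cx - 20, cy, 10.0)], depth=0.9)
        two = conf_for([(cx - 20, cy, 10.0), (cx + 30, cy, 8.0)])
        assert deeper >= one
        assert two >= one

    def test_label_flips_exactly_at_threshold(self, spot_scene):
        _, conf = cl.classify_frame(spot_scene[3], cl.RuleBasedClassifier())
        model = cl.RuleBasedClassifier()
        lab_hi, _ = cl.classify_frame(spot_scene[3], model, decision_threshold=conf)
        lab_lo, _ = cl.classify_frame(
            spot_scene[3], model, decision_threshold=np.nextafter(conf, 2.0)
        )
        assert lab_hi == "positive"
        assert lab_lo == "negative"


class TestTrainClassifier:
    def test_validation_accuracy_on_synthetic_set(self, trained_model):
        assert trained_model.training_metadata["validation_accuracy"] >= 0.95

    def test_training_is_deterministic(self, training_set):
        frames, labels, groups = training_set
        sub = slice(0, 160)
        a = cl.train_classifier(frames[sub], labels[sub], seed=3, groups=groups[sub])
        b = cl.train_classifier(frames[sub], labels[sub], seed=3, groups=groups[sub])
        assert np.array_equal(a.coef, b.coef)
        assert a.intercept == b.intercept

    def test_permuted_labels_give_chance_accuracy(self, training_set):
        frames, labels, groups = training_set
        rng = np.random.default_rng(0)
        permuted = list(rng.permutation(labels))
        model = cl.train_classifier(frames, permuted, seed=42, groups=groups)
        acc = model.training_metadata["validation_accuracy"]
        prior = max(np.mean([l == "negative" for l in permuted]),
                    np.mean([l == "positive" for l in permuted]))
        assert acc <= prior + 0.1  # no signal beyond the class prior

    def test_single_class_rejected(self, training_set):
        frames, labels, _ = training_set
        neg = [f for f, l in zip(frames, labels) if l == "negative"][:20]
        with pytest.raises(ValueError, match="both classes"):
            cl.train_classifier(neg, ["negative"] * len(neg), seed=0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cl.train_classifier([], [], seed=0)

    def test_surrogate_confidence_in_unit_interval(self, trained_model, training_set):
        frames, _, _ = training_set
        for f in frames[:10]:
            c = trained_model.predict_confidence(f)
            assert 0.0 <= c <= 1.0

    def test_serialization_round_trip(self, trained_model, training_set, tmp_path):
        frames, _, _ = training_set
        path = cl.save_model(trained_model, tmp_path / "model.json")
        loaded = cl.load_model(path)
        for f in frames[:5]:
            assert loaded.predict_confidence(f) == pytest.approx(
                trained_model.predict_confidence(f), abs=1e-12
            )


class TestAttribution:
    def _spot_mask(self, frame, params=None):
        params = params or cl.SpotDetectionParams()
        mask = cl.standard_corneal_mask(384, params.margin_frac, params.mask_erosion)
        green = frame[..., 1].astype(np.float64)
        bg = float(np.median(green[mask]))
        return mask & (green < params.depth_frac * bg)

    def test_rule_based_peak_inside_spot(self, spot_scene):
        frame = spot_scene[3]
        heat = cl.attribution_map(frame, cl.RuleBasedClassifier())
        y, x = np.unravel_index(np.argmax(heat), heat.shape)
        assert self._spot_mask(frame)[y, x]

    def test_rule_based_negative_frame_is_cold(self, spot_scene):
        heat = cl.attribution_map(spot_scene[2], cl.RuleBasedClassifier())
        assert heat.max() < 0.2

    def test_uniform_frame_gives_flat_map(self):
        uniform = np.full((384, 384, 3), 0.5)
        heat = cl.attribution_map(uniform, cl.RuleBasedClassifier())
        assert np.ptp(heat) == 0.0

    def test_occlusion_peak_inside_spot(self, spot_scene, trained_model):
        frame = spot_scene[3]
        heat = cl.attribution_map(frame, trained_model)
        y, x = np.unravel_index(np.argmax(heat), heat.shape)
        spots = cl.detect_spots(frame)
        sx, sy = spots[0].centroid_xy
        r = np.sqrt(spots[0].area_px / np.pi)
        assert np.hypot(x - sx, y - sy) <= 1.5 * r

    def test_occlusion_negative_frame_is_cold(self, spot_scene, trained_model):
        heat = cl.attribution_map(spot_scene[2], trained_model)
        assert heat.max() < 0.2
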