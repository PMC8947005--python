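"""Detector: schedule, determinism, oracle double, prediction contracts."""

import math

import numpy as np
import pytest

import mlshift as m
from mlshift.detector import learning_rate
from mlshift.detector.model import KeypointDetector
from mlshift.detector.train import samples_from_scans


class TestSchedule:
    def test_single_step_drop(self):
        cfg = m.DetectorConfig()
        trace = [learning_rate(cfg, e) for e in range(cfg.epochs)]
        assert trace[0] == 1e-4
        assert trace[cfg.lr_drop_epoch] == pytest.approx(1e-4 / 10)
        assert trace[-1] == pytest.approx(1e-5)
        drops = sum(1 for a, b in zip(trace, trace[1:]) if b < a)
        assert drops == 1

    def test_config_guards(self):
        with pytest.raises(ValueError):
            m.DetectorConfig(n_keypoints=5)
        with pytest.raises(ValueError):
            m.DetectorConfig(lr_initial=0)
        with pytest.raises(ValueError):
            m.DetectorConfig(backbone_depth="resnet101")


class TestOracleDetector:
    def test_noise_free_oracle_reproduces_ground_truth(self, phantom_scan):
        res = m.run_pipeline(phantom_scan.volume,
                             m.OracleDetector(phantom_scan.annotations))
        assert res.defined
        assert res.source == "prediction"
        assert res.scan_mls_mm == pytest.approx(7.5, abs=1e-9)

    def test_zero_shift_oracle(self, flat_scan):
        res = m.run_pipeline(flat_scan.volume,
                             m.OracleDetector(flat_scan.annotations))
        assert res.scan_mls_mm == pytest.approx(0.0, abs=1e-12)

    def test_full_dropout_yields_undefined(self, phantom_scan):
        # dropout approaching 1 with a generator that drops everything
        det = m.OracleDetector(phantom_scan.annotations, dropout_rate=0.999,
                               rng=np.random.default_rng(0))
        res = m.run_pipeline(phantom_scan.volume, det)
        assert not res.defined
        assert math.isnan(res.scan_mls_mm)

    def test_noise_is_deterministic_under_rng(self, phantom_scan):
        out = []
        for _ in range(2):
            det = m.oracle_detector(phantom_scan.annotations, sigma_px=2.0,
                                    rng=np.random.default_rng(3))
            out.append({i: d.keypoints.as_array() for i, d in det.items()
                        if d is not None})
        for i in out[0]:
            assert np.array_equal(out[0][i], out[1][i])

    def test_invalid_parameters_rejected(self, phantom_scan):
        with pytest.raises(ValueError):
            m.oracle_detector(phantom_scan.annotations, sigma_px=-1)
        with pytest.raises(ValueError):
            m.oracle_detector(phantom_scan.annotations, dropout_rate=1.0)


class TestTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            m.train_detector([], [], m.DetectorConfig(epochs=1))

    def test_epoch_zero_loss_deterministic(self, small_cohort):
        samples = samples_from_scans(small_cohort["train"][:3])
        cfg = m.DetectorConfig(epochs=1, seed=5)
        losses = []
        for _ in range(2):
            _, log = m.train_detector(samples, [], cfg)
            losses.append(log[0]["loss_total"])
        assert losses[0] == losses[1]

    def test_training_log_fields(self, trained_tiny_model):
        _, log, cfg = trained_tiny_model
        assert len(log) == cfg.epochs
        for entry in log:
            for key in ("loss_rpn_obj", "loss_cls", "loss_box", "loss_kp",
                        "lr", "val_kp_error_mm"):
                assert key in entry
        assert log[0]["lr"] == cfg.lr_initial

    def test_training_reduces_validation_error(self, small_cohort,
                                               trained_tiny_model):
        """A briefly trained model localizes landmarks better than an
        untrained one on held-out phantoms."""
        model, log, cfg = trained_tiny_model
        valid = samples_from_scans(small_cohort["valid"] + small_cohort["test"])
        untrained = KeypointDetector(m.DetectorConfig(seed=123))
        untrained.cfg.score_threshold = 0.0  # force detections from raw net

        def kp_error(net):
            errs = []
            for s in valid:
                if s.keypoints is None:
                    continue
                det = m.predict_keypoints(net, [s.model_input])
                d = det[s.model_input.center_slice_index]
                if d is None:
                    errs.append(256.0)  # missed positive: worst-case error
                    continue
                errs.append(float(np.linalg.norm(
                    d.keypoints.as_array() - s.keypoints.as_array(), axis=1).mean()))
            return np.mean(errs)

        assert kp_error(model) < kp_error(untrained)


class TestPrediction:
    def test_score_threshold_above_one_blanks_everything(self, trained_tiny_model,
                                                         phantom_scan):
        model, _, _ = trained_tiny_model
        inputs = m.preprocess_volume(phantom_scan.volume)
        dets = m.predict_keypoints(model, inputs, score_threshold=1.01)
        assert all(d is None for d in dets.values())
        res = m.run_pipeline(phantom_scan.volume, model, score_threshold=1.01)
        assert not res.defined  # no detections exits without error

    def test_keypoints_inside_dilated_box(self, trained_tiny_model, phantom_scan):
        model, _, _ = trained_tiny_model
        inputs = m.preprocess_volume(phantom_scan.volume)
        dets = m.predict_keypoints(model, inputs, score_threshold=0.5)
        found = 0
        for d in dets.values():
            if d is None:
                continue
            found += 1
            mx = 0.1 * d.box.width
            my = 0.1 * d.box.height
            for x, y in d.keypoints.as_array():
                assert d.box.x_min - mx <= x <= d.box.x_max + mx
                assert d.box.y_min - my <= y <= d.box.y_max + my
            assert 0.0 <= d.score <= 1.0
        assert found > 0  # the trained model detects the septum band

    def test_all_air_volume_yields_no_detection(self, trained_tiny_model):
        model, _, _ = trained_tiny_model
        vol = m.CTVolume(np.full((6, 256, 256), -1000.0), (5.0, 0.9, 0.9), "air")
        res = m.run_pipeline(vol, model, score_threshold=0.5)
        assert not res.defined

    def test_native_space_round_trip(self, trained_tiny_model, phantom_scan):
        model, _, _ = trained_tiny_model
        inputs = m.preprocess_volume(phantom_scan.volume)
        native = m.predict_keypoints(model, inputs, native_size=(256, 256))
        resized = m.predict_keypoints(model, inputs)
        for i in native:
            if native[i] is None:
                assert resized[i] is None
                continue
            assert np.allclose(native[i].keypoints.as_array() * 2,
                               resized[i].keypoints.as_array(), atol=1e-6)


class TestPersistence:
    def test_save_load_round_trip(self, trained_tiny_model, phantom_scan, tmp_path):
        model, _, _ = trained_tiny_model
        path = tmp_path / "model.npz"
        model.save(path)
        back = KeypointDetector.load(path)
        inputs = m.preprocess_volume(phantom_scan.volume)[:3]
        a = m.predict_keypoints(model, inputs)
        b = m.predict_keypoints(back, inputs)
        for i in a:
            if a[i] is None:
                assert b[i] is None
            else:
                assert np.allclose(a[i].keypoints.as_array(),
                                   b[i].keypoints.as_array())


class TestFPNVariant:
    def test_fpn_backbone_forward_shapes(self):
        cfg = m.DetectorConfig(backbone_depth="fpn50", image_size=64)
        model = KeypointDetector(cfg)
        x = np.random.default_rng(0).uniform(0, 1, (1, 3, 64, 64)).astype(np.float32)
        feat = model.backbone.forward(x)
        assert feat.shape == (1, 64, 16, 16)
        dets = model.detect(x)
        assert len(dets) == 1
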