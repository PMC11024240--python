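"""Backbone/head construction, preprocessing, Cox training, complexity."""

import numpy as np
import pytest
from PIL import Image

from iuasurv._architectures import Tape
from iuasurv.imaging_model import (
    BackboneSpec,
    SurvivalHeadSpec,
    TrainConfig,
    build_model,
    complexity_report,
    count_flops,
    count_parameters,
    measure_inference_time,
    predict_patient,
    preprocess_image,
    train,
)
from iuasurv.survival_core import (
    CohortTable,
    SurvivalRecord,
    cox_loss_and_score_gradient,
    deepsurv_loss,
    fit_linear_cox,
)
from iuasurv.evaluation import harrell_cindex
from conftest import simulate_ph_cohort


def make_image_cohort(n, seed, size=32):
    """Tiny random-image cohort for plumbing tests (no visual signal)."""
    rng = np.random.default_rng(seed)
    recs, images = [], {}
    for i in range(n):
        pid = f"p{i}"
        recs.append(SurvivalRecord(pid, float(rng.uniform(1, 40)), int(rng.uniform() < 0.7)))
        images[pid] = [rng.uniform(-1, 1, (size, size, 3))]
    return CohortTable(records=recs), images


class TestPreprocessing:
    def test_target_size_and_range(self):
        spec = BackboneSpec(name="tiny_test", input_size=64)
        arr = (np.random.default_rng(0).uniform(0, 255, (300, 400, 3))).astype(np.uint8)
        x = preprocess_image(arr, spec)
        assert x.shape == (64, 64, 3)
        assert x.min() >= -1.0 and x.max() <= 1.0

    def test_undersized_image_rejected_for_clinical_backbones(self):
        spec = BackboneSpec(name="inception_v3")
        arr = np.zeros((299, 400, 3), np.uint8)
        with pytest.raises(ValueError, match="below-min-resolution"):
            preprocess_image(arr, spec)

    def test_deterministic(self, tmp_path):
        arr = (np.random.default_rng(1).uniform(0, 255, (310, 310, 3))).astype(np.uint8)
        p = tmp_path / "img.png"
        Image.fromarray(arr).save(p)
        spec = BackboneSpec(name="inception_v3")
        a = preprocess_image(str(p), spec)
        b = preprocess_image(str(p), spec)
        assert np.array_equal(a, b)

    def test_non_rgb_converted_with_warning(self):
        img = Image.new("L", (336, 336), 128)
        with pytest.warns(UserWarning, match="converted to RGB"):
            x = preprocess_image(img, BackboneSpec(name="tiny_test", input_size=336))
        assert x.shape == (336, 336, 3)


class TestModelConstruction:
    def test_head_parameter_hand_count(self):
        """Dense(16->8)+BN + Dense(8->8)+BN + Dense(8->1), BN = 4/feature."""
        model = build_model(
            BackboneSpec(name="tabular", feature_dim=16),
            SurvivalHeadSpec(),
            seed=0,
        )
        expected = (16 * 8 + 8) + 4 * 8 + (8 * 8 + 8) + 4 * 8 + (8 * 1 + 1)
        assert model.n_parameters() == expected

    def test_output_shape_is_one_per_image(self):
        model = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=0)
        x = np.random.default_rng(0).normal(size=(5, 32, 32, 3))
        assert model.forward_scores(x).shape == (5,)

    def test_seeded_initialization_is_reproducible(self):
        m1 = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=11)
        m2 = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=11)
        m3 = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=12)
        for a, b in zip(m1.net.get_weights(), m2.net.get_weights()):
            assert np.array_equal(a, b)
        assert any(
            not np.array_equal(a, c)
            for a, c in zip(m1.net.get_weights(), m3.net.get_weights())
        )

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            BackboneSpec(name="alexnet")


class TestTraining:
    def test_batch_loss_matches_full_cohort_loss(self):
        """The minibatch objective at batch >= n is the cohort deepsurv loss."""
        rng = np.random.default_rng(0)
        s = rng.normal(size=40)
        t = rng.uniform(1, 30, 40)
        e = (rng.uniform(size=40) < 0.7).astype(int)
        loss, grad = cox_loss_and_score_gradient(s, t, e)
        assert loss == pytest.approx(deepsurv_loss(s, t, e), abs=1e-12)
        # gradient against central finite differences
        eps = 1e-6
        for k in (0, 7, 23):
            sp, sm = s.copy(), s.copy()
            sp[k] += eps
            sm[k] -= eps
            fd = (deepsurv_loss(sp, t, e) - deepsurv_loss(sm, t, e)) / (2 * eps)
            assert grad[k] == pytest.approx(fd, abs=1e-7)

    def test_loss_descends_on_learnable_cohort(self):
        cohort, images = make_image_cohort(40, seed=0)
        model = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=0)
        tc = TrainConfig(learning_rate=0.01, epochs=4, seed=0, weight_decay=0.0)
        hist = train(model, cohort, images, tc)
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert hist["epochs"] == 4

    def test_strong_regularization_shrinks_weights(self):
        cohort, images = make_image_cohort(30, seed=1)

        def weight_norm(lam):
            model = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=3)
            tc = TrainConfig(learning_rate=0.01, epochs=3, seed=3, weight_decay=lam)
            train(model, cohort, images, tc)
            return model.net.weight_sq_norm()

        assert weight_norm(1e3) < weight_norm(0.0)

    def test_training_is_reproducible_given_seed(self):
        cohort, images = make_image_cohort(25, seed=2)
        scores = []
        for _ in range(2):
            model = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=5)
            tc = TrainConfig(learning_rate=0.01, epochs=2, seed=5, weight_decay=1e-4)
            train(model, cohort, images, tc)
            x = np.stack([images[p][0] for p in cohort.patient_ids])
            scores.append(model.forward_scores(x))
        assert np.array_equal(scores[0], scores[1])

    def test_linear_head_recovers_linear_cox_oracle(self, ph_data_500):
        """A no-hidden-layer head on covariates converges to the Newton fit."""
        X, t, e = ph_data_500
        recs = [
            SurvivalRecord(f"p{i}", t[i], int(e[i]), covariates=X[i])
            for i in range(len(t))
        ]
        cohort = CohortTable(records=recs)
        model = build_model(
            BackboneSpec(name="tabular", feature_dim=2),
            SurvivalHeadSpec(
                hidden_layers=0, dropout=0.0, batch_norm=False, activation="linear"
            ),
            seed=0,
            dropout_transfer=0.0,
        )
        tc = TrainConfig(
            learning_rate=0.05, epochs=400, seed=0, weight_decay=0.0,
            batch_size=len(t), gradient_clip=100.0,
        )
        train(model, cohort, None, tc, covariates=True)
        oracle = fit_linear_cox(X, t, e)
        s_net = model.forward_scores(X)
        s_or = X @ oracle.beta
        c_net = harrell_cindex(s_net, t, e, n_bootstrap=0).c_index
        c_or = harrell_cindex(s_or, t, e, n_bootstrap=0).c_index
        assert abs(c_net - c_or) < 0.02
        # pairwise score differences agree (scores are shift-equivalent)
        d = (s_net - s_net.mean()) - (s_or - s_or.mean())
        assert np.abs(d).max() < 0.05

    def test_too_few_events_rejected(self):
        recs = [SurvivalRecord("a", 1.0, 1), SurvivalRecord("b", 2.0, 0)]
        cohort = CohortTable(records=recs)
        model = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=0)
        with pytest.raises(ValueError, match="events"):
            train(model, cohort, {}, TrainConfig(epochs=1))


class TestPrediction:
    def test_aggregation_contracts(self):
        model = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=0)
        rng = np.random.default_rng(4)
        img = rng.normal(size=(32, 32, 3))
        single = predict_patient(model, [img], "mean", "p").log_hazard
        doubled = predict_patient(model, [img, img], "mean", "p").log_hazard
        assert doubled == pytest.approx(single, abs=1e-12)
        img2 = rng.normal(size=(32, 32, 3))
        s1 = model.forward_scores(img[None])[0]
        s2 = model.forward_scores(img2[None])[0]
        mean = predict_patient(model, [img, img2], "mean", "p").log_hazard
        mx = predict_patient(model, [img, img2], "max", "p").log_hazard
        assert mean == pytest.approx((s1 + s2) / 2)
        assert mx == pytest.approx(max(s1, s2))
        assert mx >= mean

    def test_empty_image_list_rejected(self):
        model = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=0)
        with pytest.raises(ValueError, match="no images"):
            predict_patient(model, [], "mean", "p007")


class TestComplexityAccounting:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("inception_resnet_v2", 54_336_736),
            ("resnet50", 23_587_712),
            ("inception_v3", 21_802_784),
            ("vgg19", 20_024_384),
        ],
    )
    def test_published_backbone_parameter_counts(self, name, expected):
        assert count_parameters(name) == expected

    def test_tiny_backbone_hand_count(self):
        spec = BackboneSpec(name="tiny_test", input_size=32, channels=(8, 16, 32))
        # conv 3x3x3->8 (+bias) + BN(4*8), conv 8->16 + BN, conv 16->32 + BN
        expected = (
            (27 * 8 + 8) + 32 + (72 * 16 + 16) + 64 + (144 * 32 + 32) + 128
        )
        assert count_parameters(spec) == expected

    def test_single_conv_flop_hand_count(self):
        # 3x3 conv, 1->1 channel, 10x10 valid output, bias, MAC = 2 FLOPs
        t = Tape(12, 12, 1)
        t.conv(1, 3, pad="valid", bias=True)
        assert t.flops == 2 * 9 * 100 + 100

    def test_flops_quadruple_when_input_side_doubles(self):
        spec = BackboneSpec(name="tiny_test", input_size=32)
        f1 = count_flops(spec, input_size=32)
        f2 = count_flops(spec, input_size=64)
        assert f2 == pytest.approx(4 * f1, rel=1e-12)

    def test_inference_time_positive_and_recorded(self):
        model = build_model(BackboneSpec(name="tiny_test", input_size=32), seed=0)
        assert measure_inference_time(model, n_images=2, repeats=2) > 0
        rep = complexity_report(model, measure_time=True)
        assert rep.avg_inference_seconds > 0
        assert rep.param_count == model.n_parameters()
        assert "2 FLOPs" in rep.flop_convention

    def test_scores_track_severity_after_training(self, trained_run):
        """Image scores learned from adhesion burden track latent severity."""
        from scipy.stats import spearmanr

        truth = trained_run["truth"].set_index("patient_id")
        test_ids = trained_run["splits"]["test"]
        sev = truth.loc[test_ids, "severity"].values
        rho = spearmanr(trained_run["test_scores"], -sev).statistic
        assert rho > 0.6
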