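import numpy as np
import pytest

from microexpr.datasets_io import DOMAIN_MACRO, DOMAIN_MICRO, Sample
from microexpr.errors import DataError
from microexpr.model import build_model, forward
from microexpr.train import (LossBatch, TrainConfig, domain_loss,
                             emotion_loss, fit, reduce_macro_sample,
                             total_loss)
from tests.test_model import tiny_spec


class TestEmotionLoss:
    def test_perfect_prediction_is_zero(self):
        assert emotion_loss(np.array([1.0, 0, 0]),
                            np.array([1.0, 0, 0])) == 0.0

    @pytest.mark.parametrize("y,true_class,expected", [
        ((0.5, 0.25, 0.25), 0, 0.69315),
        ((1 / 3, 1 / 3, 1 / 3), 0, 1.09861),
        ((1 / 3, 1 / 3, 1 / 3), 2, 1.09861),
        ((0.25, 0.5, 0.25), 1, 0.69315),
    ])
    def test_cross_entropy_values(self, y, true_class, expected):
        onehot = np.zeros(3)
        onehot[true_class] = 1.0
        assert emotion_loss(np.array(y), onehot) == pytest.approx(
            expected, abs=1e-5)

    def test_zero_probability_clamped(self):
        onehot = np.array([1.0, 0, 0])
        loss = emotion_loss(np.array([0.0, 0.5, 0.5]), onehot)
        assert np.isfinite(loss)
        assert loss == pytest.approx(-np.log(1e-12))


class TestDomainLoss:
    def test_confident_correct_is_near_zero(self):
        assert domain_loss(1 - 1e-12, 1) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d,d_true,expected", [
        (0.5, 0, 0.69315),
        (0.5, 1, 0.69315),
        (0.25, 0, 0.28768),
        (0.25, 1, 1.38629),
    ])
    def test_binary_cross_entropy_values(self, d, d_true, expected):
        assert domain_loss(d, d_true) == pytest.approx(expected, abs=1e-5)

    def test_extremes_clamped(self):
        assert np.isfinite(domain_loss(0.0, 1))
        assert np.isfinite(domain_loss(1.0, 0))


class TestTotalLoss:
    def test_perfect_emotion_with_uncertain_domain(self):
        batch = LossBatch([np.array([0, 1.0, 0])], [np.array([0, 1.0, 0])],
                          [0.5], [1])
        assert total_loss(batch, 15.0) == pytest.approx(-15 * np.log(2))

    def test_decomposition_on_random_batches(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 9))
            probs = rng.dirichlet(np.ones(3), size=n)
            onehot = np.eye(3)[rng.integers(0, 3, size=n)]
            d = rng.uniform(0.01, 0.99, size=n)
            d_true = rng.integers(0, 2, size=n)
            lam = float(rng.uniform(0, 20))
            batch = LossBatch(list(probs), list(onehot), list(d),
                              list(d_true))
            ly = np.mean([emotion_loss(p, o) for p, o in zip(probs, onehot)])
            ld = np.mean([domain_loss(x, t) for x, t in zip(d, d_true)])
            assert total_loss(batch, lam) == pytest.approx(ly - lam * ld)

    def test_lambda_zero_is_mean_emotion_loss(self):
        batch = LossBatch([np.array([0.5, 0.25, 0.25])],
                          [np.array([1.0, 0, 0])], [0.9], [0])
        assert total_loss(batch, 0.0) == pytest.approx(-np.log(0.5))


class TestMacroReduction:
    def _macro(self, n_frames):
        return Sample(clip_id="m", subject_id="s", dataset="ck-like",
                      emotion=1, domain=DOMAIN_MACRO, fps=24.0,
                      frames=np.zeros((n_frames, 8, 8)))

    @pytest.mark.parametrize("n,expected_apex", [(11, 5), (10, 4), (30, 14),
                                                 (1, 0), (18, 8)])
    def test_middle_frame_becomes_apex(self, n, expected_apex):
        assert reduce_macro_sample(self._macro(n)).apex_index == expected_apex

    def test_window_composes_with_selection(self):
        # 30 frames -> apex floor(29/2) = 14 -> centred window [5, 22]
        from microexpr.preprocess import select_frame_window
        reduced = reduce_macro_sample(self._macro(30))
        window = select_frame_window(30, reduced.apex_index)
        assert window == list(range(14 - 9, 14 + 9))

    def test_micro_sample_rejected(self):
        s = Sample(clip_id="x", subject_id="s", dataset="samm-like",
                   emotion=0, domain=DOMAIN_MICRO, fps=24.0,
                   frames=np.zeros((10, 8, 8)))
        with pytest.raises(DataError):
            reduce_macro_sample(s)


def _toy_prepared(spec, n, seed=0, separable=True):
    """Tiny prepared samples whose flow input encodes the class sign."""
    from microexpr.train import PreparedSample
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n):
        cls = i % 3
        video = rng.random(spec.video_input)
        flow = 0.1 * rng.standard_normal(spec.flow_input)
        if separable:
            flow += (cls - 1) * 0.8
        items.append(PreparedSample(
            clip_id=f"c{i}", subject_id=f"s{i % 4}", emotion=cls,
            domain=i % 2, video=video, flow=flow))
    return items


class TestFit:
    def test_one_epoch_runs_and_history_length(self):
        spec = tiny_spec(dropout=0.5)
        model = build_model(spec, False, seed=0)
        items = _toy_prepared(spec, 8)
        res = fit(model, items, TrainConfig(lambda_da=0.0, epochs=1,
                                            batch_size=8, seed=0))
        assert len(res.loss_history) == 1

    def test_single_batch_step_equals_manual_sgd(self):
        # one optimizer step: params change by -lr * mean(batch gradients)
        spec = tiny_spec(dropout=0.0)
        items = _toy_prepared(spec, 4)
        cfg = TrainConfig(lambda_da=0.0, epochs=1, batch_size=4,
                          learning_rate=0.5, seed=3)
        model = build_model(spec, False, seed=1, dtype=np.float64)
        before = {k: v.copy() for k, v in model.params.items()}
        fit(model, items, cfg)
        from microexpr.model import backward as bw
        manual = {k: np.zeros_like(v) for k, v in before.items()}
        ref = build_model(spec, False, seed=1, dtype=np.float64)
        for item in items:
            r = forward(ref, item.video, item.flow)
            for k, g in bw(ref, r, item.emotion).items():
                manual[k] += g
        for k in before:
            expected = before[k] - 0.5 * manual[k] / 4
            assert np.allclose(model.params[k], expected, atol=1e-6), k

    def test_seeded_determinism(self):
        spec = tiny_spec(dropout=0.5)
        items = _toy_prepared(spec, 9)
        cfg = TrainConfig(lambda_da=1.0, epochs=2, batch_size=4, seed=7)
        histories = []
        for _ in range(2):
            model = build_model(spec, True, seed=2)
            histories.append(fit(model, items, cfg).loss_history)
        assert histories[0] == histories[1]

    def test_empty_training_set_errors(self):
        model = build_model(tiny_spec(), False, seed=0)
        with pytest.raises(DataError):
            fit(model, [], TrainConfig(epochs=1))

    def test_lambda_zero_leaves_discriminator_out_of_feature_updates(self):
        # with lambda=0 the feature/head trajectory matches a plain model
        spec = tiny_spec(dropout=0.0)
        items = _toy_prepared(spec, 6)
        cfg = TrainConfig(lambda_da=0.0, epochs=2, batch_size=3, seed=5)
        plain = build_model(spec, False, seed=2, dtype=np.float64)
        adv = build_model(spec, True, seed=2, dtype=np.float64)
        for k in plain.params:
            adv.params[k] = plain.params[k].copy()
        fit(plain, items, cfg)
        fit(adv, items, cfg)
        for k in plain.params:
            assert np.allclose(plain.params[k], adv.params[k],
                               atol=1e-10), k

    def test_learns_separable_toy_data(self):
        spec = tiny_spec(dropout=0.5)
        items = _toy_prepared(spec, 12)
        model = build_model(spec, False, seed=1)
        res = fit(model, items, TrainConfig(lambda_da=0.0, epochs=30,
                                            batch_size=4,
                                            learning_rate=0.05, seed=0))
        from microexpr.evaluate import confusion, uar
        from microexpr.train import predict
        preds = [int(np.argmax(predict(model, it))) for it in items]
        cm = confusion([it.emotion for it in items], preds)
        assert uar(cm) > 0.8
        assert res.loss_history[-1] < res.loss_history[0]


class TestGradientRoutingEquivalence:
    def test_grl_step_matches_two_player_finite_difference_update(self):
        """One SGD step through the GRL must equal the explicit two-player
        update of the adaptation objective: theta_f descends
        L_y - lam * L_d (adversarial to the domain term), theta_y descends
        L_y, and theta_d descends its own L_d.  The two-player partials
        are measured independently by central finite differences."""
        spec = tiny_spec(dropout=0.0)
        item = _toy_prepared(spec, 1)[0]
        lam, lr = 3.0, 0.1
        cfg = TrainConfig(lambda_da=lam, epochs=1, batch_size=1,
                          learning_rate=lr, seed=9)
        model = build_model(spec, True, seed=6, dtype=np.float64)
        start = {k: v.copy() for k, v in model.params.items()}
        fit(model, [item], cfg)

        probe = build_model(spec, True, seed=6, dtype=np.float64)

        def losses():
            res = forward(probe, item.video, item.flow)
            onehot = np.zeros(3)
            onehot[item.emotion] = 1.0
            return (emotion_loss(res.emotion_probs, onehot),
                    domain_loss(res.domain_prob, item.domain))

        rng = np.random.default_rng(0)
        eps = 1e-6
        group_of = {k: ("theta_d" if k.startswith("disc")
                        else "theta_y" if k.startswith("head")
                        else "theta_f") for k in start}
        for key, group in group_of.items():
            p = probe.params[key]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                ly_up, ld_up = losses()
                p[idx] = orig - eps
                ly_dn, ld_dn = losses()
                p[idx] = orig
                dly = (ly_up - ly_dn) / (2 * eps)
                dld = (ld_up - ld_dn) / (2 * eps)
                if group == "theta_f":
                    expected_grad = dly - lam * dld
                elif group == "theta_y":
                    expected_grad = dly
                else:
                    expected_grad = dld
                taken = (start[key][idx] - model.params[key][idx]) / lr
                assert abs(taken - expected_grad) < 1e-5, (key, idx)
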