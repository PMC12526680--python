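import math

import numpy as np
import pytest

from cropstack.data_prep import split_train_test
from cropstack.exceptions import ValidationError
from cropstack.knowledge_base import CropPhysicsEntry, PhysicsKnowledgeBase
from cropstack.pinn import (
    FittedPinn,
    NetworkConfig,
    data_loss,
    fit_network,
    forward,
    init_network,
    physics_loss,
    total_loss,
    train,
)
from cropstack.synthetic import SyntheticConfig, generate, make_default_knowledge_base


@pytest.fixture
def single_crop_kb():
    return PhysicsKnowledgeBase(
        [CropPhysicsEntry("rice", mu_temp=25.0, sigma_temp=2.0, mu_ph=6.0, sigma_ph=0.5)]
    )


class TestInitAndForward:
    def test_layer_shapes(self):
        cfg = NetworkConfig(n_features=7, n_classes=22, hidden_sizes=(64, 64))
        state = init_network(cfg)
        assert [w.shape for w in state.weights] == [(7, 64), (64, 64), (64, 22)]
        assert [b.shape for b in state.biases] == [(64,), (64,), (22,)]

    def test_deterministic_init(self):
        cfg = NetworkConfig(seed=3)
        a, b = init_network(cfg), init_network(cfg)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_zero_hidden_rejected(self):
        with pytest.raises(ValidationError):
            NetworkConfig(hidden_sizes=(0, 64))

    def test_rows_sum_to_one(self, rng):
        state = init_network(NetworkConfig(n_features=7, n_classes=5))
        probs = forward(state, rng.uniform(size=(10, 7)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_zero_final_layer_gives_uniform(self, rng):
        state = init_network(NetworkConfig(n_features=7, n_classes=4))
        state.weights[2][:] = 0.0
        state.biases[2][:] = 0.0
        probs = forward(state, rng.uniform(size=(3, 7)))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_order_preserving(self, rng):
        state = init_network(NetworkConfig(n_features=7, n_classes=3))
        x = rng.uniform(size=(6, 7))
        probs = forward(state, x)
        np.testing.assert_allclose(probs[::-1], forward(state, x[::-1]), atol=1e-12)

    def test_width_mismatch(self):
        state = init_network(NetworkConfig(n_features=7, n_classes=3))
        with pytest.raises(ValidationError):
            forward(state, np.zeros((2, 5)))


class TestDataLoss:
    def test_perfect_predictions(self):
        y = np.eye(3)
        assert data_loss(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_over_22(self):
        n, c = 10, 22
        probs = np.full((n, c), 1 / c)
        y = np.zeros((n, c))
        y[:, 0] = 1
        assert data_loss(probs, y) == pytest.approx(math.log(22), abs=1e-10)
        assert data_loss(probs, y) == pytest.approx(3.0910424534, abs=1e-9)

    def test_half_probability(self):
        probs = np.array([[0.5, 0.5], [0.5, 0.5]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert data_loss(probs, y) == pytest.approx(math.log(2), abs=1e-12)

    def test_batch_mismatch(self):
        with pytest.raises(ValidationError):
            data_loss(np.ones((2, 3)) / 3, np.eye(3))

    def test_nonnegative_and_clipped(self):
        probs = np.array([[1.0, 0.0]])
        y = np.array([[0.0, 1.0]])
        loss = data_loss(probs, y)
        assert 0 <= loss <= -math.log(1e-12) + 1e-9


class TestPhysicsLoss:
    def test_perfect_at_optimum(self, single_crop_kb):
        probs = np.array([[1.0]])
        loss = physics_loss(probs, [25.0], [6.0], single_crop_kb)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_zero_probability_max_penalty(self, single_crop_kb):
        probs = np.array([[0.0]])
        loss = physics_loss(probs, [25.0], [6.0], single_crop_kb)
        assert loss == pytest.approx(1.0, abs=1e-12)

    def test_one_sigma_both(self, single_crop_kb):
        probs = np.array([[1.0]])
        loss = physics_loss(probs, [27.0], [6.5], single_crop_kb)
        assert loss == pytest.approx(1 - math.exp(-1), abs=1e-10)
        assert loss == pytest.approx(0.6321205588, abs=1e-9)

    def test_bounded(self, two_crop_kb, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(2), size=5)
            loss = physics_loss(p, rng.uniform(0, 45, 5), rng.uniform(0, 14, 5), two_crop_kb)
            assert 0.0 <= loss <= 1.0

    def test_oracle_double_loop(self, two_crop_kb, rng):
        # batched implementation vs naive per-sample, per-crop loop
        for _ in range(20):
            n = 6
            p = rng.dirichlet(np.ones(2), size=n)
            temp = rng.uniform(10, 40, n)
            ph = rng.uniform(4, 9, n)
            expected = 0.0
            for i in range(n):
                for c, lbl in enumerate(two_crop_kb.class_order):
                    e = two_crop_kb.entry(lbl)
                    ts = math.exp(-((temp[i] - e.mu_temp) ** 2) / (2 * e.sigma_temp**2))
                    ps = math.exp(-((ph[i] - e.mu_ph) ** 2) / (2 * e.sigma_ph**2))
                    expected += 1 - p[i, c] * ts * ps
            expected /= n * 2
            got = physics_loss(p, temp, ph, two_crop_kb)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_true_class_mode(self, two_crop_kb):
        rice = two_crop_kb.class_order.index("rice")
        probs = np.zeros((1, 2))
        probs[0, rice] = 0.9
        probs[0, 1 - rice] = 0.1
        loss_all = physics_loss(probs, [25.0], [6.0], two_crop_kb, mode="all_crops")
        loss_true = physics_loss(
            probs, [25.0], [6.0], two_crop_kb,
            labels_idx=np.array([rice]), mode="true_class",
        )
        assert loss_true == pytest.approx(1 - 0.9, abs=1e-12)  # rice at its optimum
        assert loss_all != loss_true

    def test_gradient_pull_toward_suitable_crops(self, two_crop_kb):
        # finite differences of the penalty wrt each probability: steeper
        # descent for the crop whose optima are nearer the sample
        temp, ph = [24.9], [6.05]  # close to rice optimum
        base = np.array([[0.5, 0.5]])
        eps = 1e-6
        grads = []
        for c in range(2):
            bumped = base.copy()
            bumped[0, c] += eps
            grads.append(
                (physics_loss(bumped, temp, ph, two_crop_kb)
                 - physics_loss(base, temp, ph, two_crop_kb)) / eps
            )
        scores = two_crop_kb.score_matrix(np.array(temp), np.array(ph))[0]
        np.testing.assert_allclose(grads, -scores / 2, atol=1e-5)
        rice = two_crop_kb.class_order.index("rice")
        assert grads[rice] < grads[1 - rice]  # raising p(rice) reduces penalty fastest


class TestTotalLoss:
    @pytest.mark.parametrize(
        "d,p,lam,expected",
        [(1.0, 0.5, 0.0, 1.0), (1.0, 0.5, 2.0, 2.0), (0.0, 0.0, 5.0, 0.0)],
    )
    def test_arithmetic(self, d, p, lam, expected):
        lb = total_loss(d, p, lam)
        assert lb.total_loss == pytest.approx(expected, abs=1e-12)
        assert lb.total_loss == pytest.approx(
            lb.data_loss + lb.lambda_physics * lb.physics_loss, abs=1e-10
        )

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValidationError):
            total_loss(1.0, 1.0, -0.5)


@pytest.fixture(scope="module")
def sep3():
    kb = make_default_knowledge_base(3, seed=4)
    cfg = SyntheticConfig(n_classes=3, samples_per_class=40, separation=5.0, seed=4)
    return generate(cfg, kb), kb


class TestTraining:
    def test_training_accuracy_on_separable_data(self, sep3):
        data, kb = sep3
        model = train(data, kb, NetworkConfig(n_classes=3, epochs=80, seed=0))
        acc = (model.predict(data) == data.labels).mean()
        assert acc >= 0.99

    def test_loss_identity_every_epoch(self, sep3):
        data, kb = sep3
        model = train(data, kb, NetworkConfig(n_classes=3, epochs=10, seed=0))
        for lb in model.history:
            assert lb.total_loss == pytest.approx(
                lb.data_loss + lb.lambda_physics * lb.physics_loss, abs=1e-10
            )
            assert np.isfinite(lb.total_loss)

    def test_lambda_zero_equals_plain_network(self, sep3):
        data, kb = sep3
        cfg = NetworkConfig(n_classes=3, epochs=15, lambda_physics=0.0, seed=1)
        with_kb = train(data, kb, cfg)
        without_kb = train(data, None, cfg)
        for a, b in zip(with_kb.history, without_kb.history):
            assert abs(a.data_loss - b.data_loss) < 1e-8
        x = with_kb.scaler.transform(data.features)
        np.testing.assert_allclose(
            with_kb.predict_proba(x), without_kb.predict_proba(x), atol=1e-12
        )

    def test_deterministic_training(self, sep3):
        data, kb = sep3
        cfg = NetworkConfig(n_classes=3, epochs=5, seed=2)
        a, b = train(data, kb, cfg), train(data, kb, cfg)
        for wa, wb in zip(a.state.weights, b.state.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_lambda_positive_requires_kb(self, sep3):
        data, _ = sep3
        with pytest.raises(ValidationError):
            train(data, None, NetworkConfig(n_classes=3, epochs=1, lambda_physics=0.1))

    def test_predict_proba_contract(self, sep3, rng):
        data, kb = sep3
        model = train(data, kb, NetworkConfig(n_classes=3, epochs=5, seed=0))
        x = rng.uniform(size=(4, 7))
        p1, p2 = model.predict_proba(x), model.predict_proba(x)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)

    def test_serialization_roundtrip(self, sep3, tmp_path, rng):
        data, kb = sep3
        model = train(data, kb, NetworkConfig(n_classes=3, epochs=5, seed=0))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = FittedPinn.load(path)
        x = rng.uniform(size=(5, 7))
        np.testing.assert_allclose(model.predict_proba(x), loaded.predict_proba(x), atol=1e-12)
        assert loaded.class_order == model.class_order
        assert loaded.kb_hash == kb.sha256()
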