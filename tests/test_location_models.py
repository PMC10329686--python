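import numpy as np
import pytest

import spotloc as sl
from spotloc._nn import Tensor
from spotloc.location_models import (CoordScaler, LocationModelConfig,
                                     _loss_tensor)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# loss oracles
# ---------------------------------------------------------------------------

class TestCoordLoss:
    def test_perfect_zero(self):
        y = np.array([[0.2, 0.3], [0.7, 0.9]])
        assert sl.coord_loss(y, y) == 0.0

    def test_hand_example(self):
        assert sl.coord_loss(np.array([[0.5, 0.8]]),
                             np.array([[0.2, 0.4]])) == pytest.approx(0.25)

    def test_matches_loop_oracle(self, rng):
        pred = rng.uniform(size=(20, 2))
        true = rng.uniform(size=(20, 2))
        naive = sum((true[i, 0] - pred[i, 0]) ** 2 + (true[i, 1] - pred[i, 1]) ** 2
                    for i in range(20))
        assert sl.coord_loss(pred, true) == pytest.approx(naive, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sl.coord_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestEllipseLoss:
    def test_boundary_zero(self):
        pred = np.array([[0.5, 0.5, 0.1, 0.2]])
        assert sl.ellipse_loss(pred, np.array([[0.6, 0.5]]), 0.9) \
            == pytest.approx(0.0, abs=1e-12)

    def test_center_contribution(self):
        pred = np.array([[0.5, 0.5, 0.1, 0.2]])
        assert sl.ellipse_loss(pred, np.array([[0.5, 0.5]]), 0.9) \
            == pytest.approx(0.1)

    def test_outside_contribution(self):
        pred = np.array([[0.5, 0.5, 0.1, 0.2]])
        assert sl.ellipse_loss(pred, np.array([[0.7, 0.5]]), 0.9) \
            == pytest.approx(2.7)

    def test_matches_loop_oracle(self, rng):
        n, alpha = 15, 0.85
        pred = np.column_stack([rng.uniform(size=(n, 2)),
                                rng.uniform(0.05, 0.5, size=(n, 2))])
        true = rng.uniform(size=(n, 2))
        naive = 0.0
        for i in range(n):
            c1, c2, r1, r2 = pred[i]
            q = ((true[i, 0] - c1) / r1) ** 2 + ((true[i, 1] - c2) / r2) ** 2
            s = 1.0 if q <= 1 else 0.0
            naive += (alpha * (1 - s) + (1 - alpha) * s) * abs(q - 1)
        assert sl.ellipse_loss(pred, true, alpha) == pytest.approx(naive, abs=1e-10)

    def test_nonpositive_axis_rejected(self):
        pred = np.array([[0.5, 0.5, 0.0, 0.2]])
        with pytest.raises(ValueError, match="positive"):
            sl.ellipse_loss(pred, np.array([[0.5, 0.5]]), 0.9)

    def test_continuity_at_boundary(self):
        # bracket r around the value putting the point exactly on the boundary
        y = np.array([[0.6, 0.5]])
        base = np.array([0.5, 0.5, 0.1, 0.2])
        eps = 1e-8
        lo = sl.ellipse_loss(np.array([base - [0, 0, eps, 0]]), y, 0.9)
        hi = sl.ellipse_loss(np.array([base + [0, 0, eps, 0]]), y, 0.9)
        assert abs(lo - hi) < 1e-6


class TestDomainLoss:
    def test_confident_limit_zero(self):
        scores = np.array([[50.0, -50.0]])
        assert sl.domain_loss(scores, np.array([1]), 2) == pytest.approx(0.0, abs=1e-12)

    def test_zero_scores_hand_value(self):
        assert sl.domain_loss(np.zeros((1, 2)), np.array([1]), 2) \
            == pytest.approx(2 * np.log(2))

    def test_matches_loop_oracle(self, rng):
        n, C = 12, 4
        scores = rng.normal(size=(n, C))
        labels = rng.integers(1, C + 1, size=n)
        naive = 0.0
        for i in range(n):
            for c in range(1, C + 1):
                p = sigmoid(scores[i, c - 1])
                naive -= np.log(p) if labels[i] == c else np.log(1 - p)
        assert sl.domain_loss(scores, labels, C) == pytest.approx(naive, abs=1e-10)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            sl.domain_loss(np.zeros((1, 2)), np.array([3]), 2)


class TestOrdinalLoss:
    def test_hand_value_l2(self):
        assert sl.ordinal_loss(np.array([0.0]), np.array([0.0]),
                               np.array([2]), 2) == pytest.approx(np.log(2))

    def test_hand_value_l3(self):
        expected = -(np.log(sigmoid(1.0)) + np.log(sigmoid(-1.0)))
        assert sl.ordinal_loss(np.array([0.0]), np.array([1.0, -1.0]),
                               np.array([3]), 3) == pytest.approx(expected)
        assert expected == pytest.approx(1.6265, abs=5e-4)

    def test_confident_limit_zero(self):
        assert sl.ordinal_loss(np.array([80.0]), np.array([1.0, -1.0]),
                               np.array([3]), 3) == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        n, L = 10, 5
        a = rng.normal(size=n)
        b = np.sort(rng.normal(size=L - 1))[::-1]
        labels = rng.integers(1, L + 1, size=n)
        naive = 0.0
        for i in range(n):
            for l in range(1, L):
                p = sigmoid(a[i] + b[l - 1])
                naive -= np.log(p) if labels[i] > l else np.log(1 - p)
        assert sl.ordinal_loss(a, b, labels, L) == pytest.approx(naive, abs=1e-10)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            sl.ordinal_loss(np.array([0.0]), np.array([0.0]), np.array([5]), 2)


class TestOrdinalProbabilities:
    def test_sum_to_one_random(self, rng):
        for _ in range(20):
            a = rng.normal(size=6)
            b = np.sort(rng.normal(size=4))[::-1]
            probs = sl.ordinal_probabilities(a, b, 5)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
            assert (probs >= -1e-12).all()

    def test_l2_symmetric(self):
        probs = sl.ordinal_probabilities(np.array([0.0]), np.array([0.0]), 2)
        np.testing.assert_allclose(probs, [[0.5, 0.5]])

    def test_low_score_concentrates_on_first_layer(self):
        probs = sl.ordinal_probabilities(np.array([-60.0]),
                                         np.array([1.0, -1.0]), 3)
        assert probs[0, 0] > 0.999999

    def test_cumulative_monotone(self, rng):
        a = rng.normal(size=8)
        b = np.sort(rng.normal(size=5))[::-1]
        cum = sigmoid(a[:, None] + b[None, :])
        assert (np.diff(cum, axis=1) <= 1e-12).all()

    def test_unordered_b_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            sl.ordinal_probabilities(np.array([0.0]), np.array([-1.0, 1.0]), 3)


class TestScaler:
    def test_min_max_map(self):
        coords = np.array([[0.0, 10.0], [4.0, 20.0], [2.0, 15.0]])
        scaler = CoordScaler.fit(coords)
        s = sl.scale_coords(coords, scaler)
        np.testing.assert_allclose(s[0], [0.0, 0.0])
        np.testing.assert_allclose(s[1], [1.0, 1.0])
        np.testing.assert_allclose(s[2], [0.5, 0.5])

    def test_roundtrip_inverse(self, rng):
        coords = rng.uniform(-5, 30, size=(40, 2))
        scaler = CoordScaler.fit(coords)
        back = sl.unscale_coords(sl.scale_coords(coords, scaler), scaler)
        np.testing.assert_allclose(back, coords, atol=1e-12)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            CoordScaler.fit(np.array([[1.0, 2.0], [1.0, 3.0]]))


# ---------------------------------------------------------------------------
# autograd training losses mirror the numpy reference forms
# ---------------------------------------------------------------------------

class TestTrainingLossParity:
    def _model(self, task, n_features, n_classes=None, alpha=0.9):
        cfg = LocationModelConfig(task=task, hidden_sizes=(8, 4),
                                  n_classes=n_classes, alpha=alpha, seed=0)
        return sl.LocationModel(cfg, [f"g{i}" for i in range(n_features)],
                                None, None)

    def test_coord2d_parity(self, rng):
        model = self._model("coord2d", 6)
        X = rng.normal(size=(10, 6))
        y = rng.uniform(size=(10, 2))
        out = model.forward(Tensor(X))
        assert float(_loss_tensor(model, out, y, 0.9).data) == pytest.approx(
            sl.coord_loss(out.data, y), abs=1e-10)

    def test_ellipse_parity(self, rng):
        model = self._model("ellipse", 6)
        X = rng.normal(size=(10, 6))
        y = rng.uniform(size=(10, 2))
        out = model.forward(Tensor(X))
        assert float(_loss_tensor(model, out, y, 0.9).data) == pytest.approx(
            sl.ellipse_loss(out.data, y, 0.9), abs=1e-10)

    def test_domain_parity(self, rng):
        model = self._model("domain", 6, n_classes=3)
        X = rng.normal(size=(10, 6))
        y = rng.integers(1, 4, size=10)
        out = model.forward(Tensor(X))
        assert float(_loss_tensor(model, out, y, 0.9).data) == pytest.approx(
            sl.domain_loss(out.data, y, 3), abs=1e-10)

    def test_ordinal_parity(self, rng):
        model = self._model("ordinal", 6, n_classes=4)
        X = rng.normal(size=(10, 6))
        y = rng.integers(1, 5, size=10)
        out = model.forward(Tensor(X))
        b = model.cut_points().data
        assert (np.diff(b) < 0).all()
        assert float(_loss_tensor(model, out, y, 0.9).data) == pytest.approx(
            sl.ordinal_loss(out.data, b, y, 4), abs=1e-10)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TestTraining:
    def test_default_hidden_sizes(self):
        assert LocationModelConfig().hidden_sizes == (50, 10, 5)

    def test_coord2d_loss_drops_below_ten_percent(self, gradient_reference):
        cfg = LocationModelConfig(task="coord2d", epochs=300, lr=3e-3, seed=1)
        model = sl.train_location_model(gradient_reference, config=cfg)
        assert model.training_log[-1][1] < 0.1 * model.training_log[0][1]

    def test_seed_determinism(self, gradient_reference, gradient_spec):
        cfg = LocationModelConfig(task="coord2d", epochs=50, seed=5)
        probe = sl.make_query(gradient_spec, 20, seed=1)
        _, probe_h = sl.harmonize_genes(gradient_reference, probe)
        a = sl.predict(sl.train_location_model(gradient_reference, config=cfg),
                       probe_h)
        b = sl.predict(sl.train_location_model(gradient_reference, config=cfg),
                       probe_h)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_coord_predictions_in_unit_square(self, gradient_reference):
        cfg = LocationModelConfig(task="coord2d", epochs=30, seed=2)
        model = sl.train_location_model(gradient_reference, config=cfg)
        out = model.forward(Tensor(gradient_reference.matrix)).data
        assert (out >= 0).all() and (out <= 1).all()

    def test_task_label_mismatch_rejected(self, gradient_reference):
        bare = sl.SpotExpression(
            gradient_reference.matrix, gradient_reference.gene_ids,
            gradient_reference.spot_ids, gradient_reference.spatial_coords,
            normalized=True)
        cfg = LocationModelConfig(task="ordinal", n_classes=4, epochs=5)
        with pytest.raises(Exception, match="label"):
            sl.train_location_model(bare, config=cfg)

    def test_replicates_extend_training_rows(self, gradient_reference):
        from spotloc.augmentation import ReplicateSet
        reps = ReplicateSet([gradient_reference.matrix.copy()], "fp", 0)
        cfg = LocationModelConfig(task="coord2d", epochs=5, seed=0)
        model = sl.train_location_model(gradient_reference, replicates=reps,
                                        config=cfg)
        assert model.training_log  # trained without error on doubled rows

    def test_checkpoint_roundtrip(self, gradient_reference, tmp_path):
        cfg = LocationModelConfig(task="coord2d", epochs=20, seed=3)
        model = sl.train_location_model(gradient_reference, config=cfg)
        sl.save_location_model(model, tmp_path / "ckpt")
        back = sl.load_location_model(tmp_path / "ckpt")
        X = gradient_reference.matrix[:5]
        np.testing.assert_allclose(back.forward(Tensor(X)).data,
                                   model.forward(Tensor(X)).data)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LocationModelConfig(task="nope")
        with pytest.raises(ValueError):
            LocationModelConfig(alpha=1.5)
        with pytest.raises(ValueError):
            LocationModelConfig(task="domain", n_classes=1)
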