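"""Masked classifier: activations, loss, mask conservation, gradients, training."""

import numpy as np
import pytest

from scsignet.network import (
    NetworkConfig,
    cross_entropy,
    forward,
    encode,
    init_network,
    one_hot,
    relu,
    signaling_activity,
    softmax,
    train,
    _loss_and_grads,
)
from scsignet.pathways import IndicatorMatrix


def indicator(mask):
    mask = np.asarray(mask)
    return IndicatorMatrix(
        genes=[f"g{i}" for i in range(mask.shape[0])],
        circuits=[f"c{j}" for j in range(mask.shape[1])],
        values=mask,
    )


def tiny_net(mask, n_classes=2, seed=0, **kw):
    mask = np.asarray(mask)
    cfg = NetworkConfig(
        n_genes=mask.shape[0],
        n_circuits=mask.shape[1],
        n_classes=n_classes,
        encoding_dim=kw.pop("encoding_dim", 5),
        seed=seed,
        **kw,
    )
    return init_network(cfg, indicator(mask), seed=seed)


class TestPrimitives:
    def test_relu_clamps_negatives(self):
        assert relu(-2) == 0 and relu(3) == 3
        z = np.random.default_rng(0).normal(size=50)
        assert (relu(z) >= 0).all()

    def test_softmax_uniform_on_constant_rows(self):
        assert np.allclose(softmax([0.0, 0.0]), [0.5, 0.5])
        assert np.allclose(softmax([3.0, 3.0, 3.0]), 1 / 3)

    def test_softmax_shift_invariant_and_overflow_safe(self):
        z = np.random.default_rng(1).normal(size=(4, 6))
        assert np.allclose(softmax(z), softmax(z + 1000.0))
        assert np.isfinite(softmax(np.array([1e4, -1e4]))).all()

    def test_cross_entropy_reference_values(self):
        assert cross_entropy([[1, 0]], [[1, 0]]) == 0.0
        assert np.isclose(cross_entropy([[1, 0]], [[0.5, 0.5]]), np.log(2))
        with pytest.raises(ValueError, match="shape mismatch"):
            cross_entropy([[1, 0]], [[1, 0, 0]])

    def test_cross_entropy_nonnegative_and_floored(self):
        rng = np.random.default_rng(2)
        p = softmax(rng.normal(size=(10, 3)))
        y = one_hot(rng.integers(0, 3, size=10), [0, 1, 2])
        assert cross_entropy(y, p) >= 0
        assert np.isfinite(cross_entropy([[1.0, 0.0]], [[0.0, 1.0]]))  # floor at eps


class TestInit:
    def test_mask_zeros_exactly_where_indicator_is_zero(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((20, 7)) < 0.3).astype(np.uint8)
        mask[:, 0] = 0  # a fully masked circuit column
        net = tiny_net(mask)
        W = net.params["W1"]
        assert (W[mask == 0] == 0).all()
        assert np.count_nonzero(W) <= mask.sum()
        assert (W[:, 0] == 0).all()

    def test_biases_start_at_zero(self):
        net = tiny_net(np.ones((4, 3), dtype=np.uint8))
        for name in ("b1", "b2", "b3"):
            assert (net.params[name] == 0).all()

    def test_same_seed_bitwise_identical(self):
        mask = np.ones((6, 4), dtype=np.uint8)
        a, b = tiny_net(mask, seed=9), tiny_net(mask, seed=9)
        for k in a.params:
            assert (a.params[k] == b.params[k]).all()
        c = tiny_net(mask, seed=10)
        assert not (a.params["W1"] == c.params["W1"]).all()

    def test_dimension_mismatch_rejected(self):
        cfg = NetworkConfig(n_genes=5, n_circuits=3, n_classes=2)
        with pytest.raises(ValueError, match="indicator shape"):
            init_network(cfg, indicator(np.ones((4, 3), dtype=np.uint8)))


class TestForward:
    def test_zero_input_zero_biases_gives_zero_signaling_layer(self):
        net = tiny_net(np.ones((4, 3), dtype=np.uint8))
        a1, enc, probs = forward(net, np.zeros((2, 4)))
        assert (a1 == 0).all()
        assert np.allclose(probs.sum(axis=1), 1)

    def test_probability_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        net = tiny_net((rng.random((10, 5)) < 0.5).astype(np.uint8), n_classes=3)
        probs = forward(net, rng.uniform(-1, 1, size=(8, 10)))[2]
        assert np.allclose(probs.sum(axis=1), 1, atol=1e-6)

    def test_encode_matches_forward_middle_output(self):
        rng = np.random.default_rng(5)
        net = tiny_net(np.ones((6, 2), dtype=np.uint8))
        X = rng.uniform(-1, 1, size=(3, 6))
        assert (encode(net, X) == forward(net, X)[1]).all()
        assert encode(net, X).shape[1] == net.config.encoding_dim
        assert (signaling_activity(net, X) == forward(net, X)[0]).all()

    def test_identical_cells_get_identical_encodings(self):
        net = tiny_net(np.ones((4, 3), dtype=np.uint8))
        X = np.tile(np.array([0.2, -0.5, 0.9, 0.0]), (2, 1))
        enc = encode(net, X)
        assert (enc[0] == enc[1]).all()

    def test_out_of_circuit_gene_never_moves_circuit_node(self):
        # finite-difference probe: perturbing a masked-out gene leaves a1[:, j] fixed
        rng = np.random.default_rng(6)
        for trial in range(5):
            mask = (rng.random((12, 4)) < 0.4).astype(np.uint8)
            mask[0, :] = 1  # keep circuits nonempty
            net = tiny_net(mask, seed=trial)
            X = rng.uniform(-1, 1, size=(3, 12))
            base = signaling_activity(net, X)
            for j in range(4):
                outside = np.flatnonzero(mask[:, j] == 0)
                if outside.size == 0:
                    continue
                Xp = X.copy()
                Xp[:, outside] += rng.uniform(0.5, 2.0, size=(3, outside.size))
                assert (signaling_activity(net, Xp)[:, j] == base[:, j]).all()

    def test_non_finite_input_rejected(self):
        net = tiny_net(np.ones((2, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="non-finite"):
            forward(net, np.array([[np.nan, 0.0]]))


class TestGradients:
    def test_analytic_gradients_match_central_differences(self):
        rng = np.random.default_rng(7)
        mask = (rng.random((6, 4)) < 0.6).astype(np.uint8)
        mask[0, :] = 1
        net = tiny_net(mask, n_classes=3, encoding_dim=4, seed=1, dtype="float64")
        X = rng.uniform(-1, 1, size=(5, 6))
        y = one_hot(rng.integers(0, 3, size=5), [0, 1, 2])
        _, grads = _loss_and_grads(net, X, y)
        h = 1e-6
        for k, g in grads.items():
            theta = net.params[k]
            flat_idx = rng.choice(theta.size, size=min(theta.size, 10), replace=False)
            for fi in flat_idx:
                ij = np.unravel_index(fi, theta.shape)
                if k == "W1" and net.mask[ij] == 0:
                    assert g[ij] == 0  # masked entries have exactly zero gradient
                    continue
                orig = theta[ij]
                theta[ij] = orig + h
                up = cross_entropy(y, forward(net, X)[2])
                theta[ij] = orig - h
                down = cross_entropy(y, forward(net, X)[2])
                theta[ij] = orig
                numeric = (up - down) / (2 * h)
                denom = max(abs(numeric), abs(g[ij]), 1e-8)
                assert abs(numeric - g[ij]) / denom < 1e-4, (k, ij)


def separable_problem(n_per_class=200, seed=0):
    """Two clearly separated classes over 10 genes, 3 circuits."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((10, 3), dtype=np.uint8)
    mask[0:4, 0] = 1
    mask[4:8, 1] = 1
    mask[8:10, 2] = 1
    X0 = rng.normal(-0.5, 0.2, size=(n_per_class, 10))
    X1 = rng.normal(-0.5, 0.2, size=(n_per_class, 10))
    X0[:, 0:4] += 1.0  # class 0 activates circuit 0 genes
    X1[:, 4:8] += 1.0  # class 1 activates circuit 1 genes
    X = np.clip(np.vstack([X0, X1]), -1, 1)
    y = one_hot([0] * n_per_class + [1] * n_per_class, [0, 1])
    order = rng.permutation(len(X))
    return mask, X[order], y[order]


@pytest.fixture(scope="module")
def trained():
    mask, X, y = separable_problem()
    n = len(X)
    cut = int(0.7 * n)
    net = tiny_net(mask, n_classes=2, encoding_dim=8, seed=3, epochs=40)
    net, history = train(net, (X[:cut], y[:cut]), (X[cut:], y[cut:]))
    return net, history, (X[cut:], y[cut:])


class TestTraining:

    def test_validation_accuracy_on_separable_data(self, trained):
        net, _, (Xv, yv) = trained
        pred = forward(net, Xv)[2].argmax(axis=1)
        assert (pred == yv.argmax(axis=1)).mean() >= 0.95

    def test_masked_entries_exactly_zero_after_training(self, trained):
        net, _, _ = trained
        assert np.abs(net.params["W1"][net.mask == 0]).max() == 0

    def test_loss_mostly_decreases(self, trained):
        _, history, _ = trained
        losses = history["learn_loss"]
        drops = sum(b <= a for a, b in zip(losses, losses[1:]))
        assert drops / (len(losses) - 1) >= 0.8

    def test_early_stopping_restores_best_validation_weights(self, trained):
        net, history, (Xv, yv) = trained
        restored = cross_entropy(yv, forward(net, Xv)[2])
        assert np.isclose(restored, history["best_valid_loss"], rtol=1e-5)

    def test_seeded_training_is_bitwise_reproducible(self):
        mask, X, y = separable_problem(n_per_class=40, seed=5)
        runs = []
        for _ in range(2):
            net = tiny_net(mask, n_classes=2, encoding_dim=4, seed=2, epochs=5)
            net, _ = train(net, (X[:60], y[:60]), (X[60:], y[60:]))
            runs.append(net.copy_params())
        for k in runs[0]:
            assert (runs[0][k] == runs[1][k]).all()

    def test_missing_class_rejected(self):
        mask, X, y = separable_problem(n_per_class=20, seed=6)
        net = tiny_net(mask, n_classes=2, epochs=2)
        only0 = y[:, 0] == 1
        with pytest.raises(ValueError, match="missing from learning set"):
            train(net, (X[only0], y[only0]), (X, y))
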