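"""Regression heads: predictions, exact gradients, Adam, FLOP accounting."""

import numpy as np
import pytest

import fedgap as fg
from fedgap.heads import ShapeError, load_head, save_head


def _flatten(arrs):
    return np.concatenate([a.ravel() for a in arrs])


def _fd_gradient(head, X, y, eps=1e-6):
    """Central finite differences on the flattened parameter vector."""
    params = head.parameters()
    flat = _flatten(params)
    shapes = [p.shape for p in params]
    sizes = [p.size for p in params]

    def rebuild(vec):
        out, pos = [], 0
        for shp, sz in zip(shapes, sizes):
            out.append(vec[pos : pos + sz].reshape(shp))
            pos += sz
        return fg.HeadModel.from_parameters(head.kind, out)

    grad = np.empty_like(flat)
    for i in range(flat.size):
        up, dn = flat.copy(), flat.copy()
        up[i] += eps
        dn[i] -= eps
        lu, _ = fg.l2_loss_and_grad(rebuild(up), X, y)
        ld, _ = fg.l2_loss_and_grad(rebuild(dn), X, y)
        grad[i] = (lu - ld) / (2 * eps)
    return grad


class TestPredict:
    def test_constant_model(self):
        head = fg.HeadModel.linear(8, bias_init=52.0)
        assert fg.predict(head, np.ones(8)) == 52.0

    def test_coordinate_readout(self):
        head = fg.HeadModel.linear(8)
        w = head.weights[0].copy()
        w[0, 0] = 1.0
        head = fg.HeadModel("linear", (w,), head.biases)
        x = np.zeros(8)
        x[0] = 40.0
        assert fg.predict(head, x) == 40.0

    def test_dimension_mismatch(self):
        with pytest.raises(ShapeError):
            fg.predict(fg.HeadModel.linear(8), np.ones(9))


class TestLossAndGrad:
    def test_perfect_predictions(self):
        head = fg.HeadModel.linear(4, bias_init=50.0)
        loss, grads = fg.l2_loss_and_grad(head, np.zeros((3, 4)), np.full(3, 50.0))
        assert loss == 0.0
        assert all(np.all(g == 0) for g in grads)

    def test_single_sample_bias_gradient(self):
        """residual 2 -> loss 4, d/db mean (wx+b-y)^2 = 2*residual = 4."""
        head = fg.HeadModel.linear(4, bias_init=2.0)
        loss, grads = fg.l2_loss_and_grad(head, np.zeros((1, 4)), np.zeros(1))
        assert loss == 4.0
        assert grads[1][0] == 4.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            fg.l2_loss_and_grad(fg.HeadModel.linear(4), np.empty((0, 4)), np.empty(0))

    @pytest.mark.parametrize(
        "maker",
        [
            lambda rng: fg.HeadModel.linear(12, bias_init=rng.normal()),
            lambda rng: fg.HeadModel.mlp(12, n_layers=2, hidden_units=7, seed=1),
            lambda rng: fg.HeadModel.mlp(12, n_layers=4, hidden_units=5, seed=2),
        ],
        ids=["linear", "mlp2", "mlp4"],
    )
    def test_gradient_matches_finite_differences(self, maker):
        rng = np.random.default_rng(3)
        head = maker(rng)
        # perturb weights so ReLU kinks are not exactly at 0
        head = fg.HeadModel.from_parameters(
            head.kind, [p + 0.01 * rng.normal(size=p.shape) for p in head.parameters()]
        )
        X = rng.normal(size=(5, 12))
        y = rng.normal(50, 8, size=5)
        _, grads = fg.l2_loss_and_grad(head, X, y)
        fd = _fd_gradient(head, X, y)
        an = _flatten(grads)
        denom = np.maximum(np.abs(fd), 1e-3)
        assert np.max(np.abs(an - fd) / denom) < 1e-4


class TestAdam:
    def test_zero_gradient_no_decay_leaves_parameters(self):
        head = fg.HeadModel.linear(4, bias_init=1.0)
        state = fg.AdamState.init(head, weight_decay=0.0)
        grads = [np.zeros_like(p) for p in head.parameters()]
        new, _ = fg.adam_step(head, grads, state)
        assert all(np.array_equal(a, b) for a, b in zip(new.parameters(), head.parameters()))

    def test_first_step_hand_computation(self):
        """w=1, g=2, lr=0.1, wd=0: m_hat=2, v_hat=4 -> w' = 1 - 0.1*2/(2+eps)."""
        head = fg.HeadModel("linear", (np.array([[1.0]]),), (np.array([0.0]),))
        state = fg.AdamState.init(head, lr=0.1, weight_decay=0.0)
        grads = [np.array([[2.0]]), np.array([0.0])]
        new, st = fg.adam_step(head, grads, state)
        assert new.weights[0][0, 0] == pytest.approx(0.9, abs=1e-7)
        assert st.step == 1

    def test_lr_zero_freezes(self):
        rng = np.random.default_rng(0)
        head = fg.HeadModel.mlp(6, 2, hidden_units=3, seed=0)
        state = fg.AdamState.init(head, lr=0.0)
        grads = [rng.normal(size=p.shape) for p in head.parameters()]
        new, _ = fg.adam_step(head, grads, state)
        assert all(np.array_equal(a, b) for a, b in zip(new.parameters(), head.parameters()))

    def test_weight_decay_shrinks_norms_at_zero_gradient(self):
        head = fg.HeadModel("linear", (np.ones((4, 1)),), (np.array([2.0]),))
        state = fg.AdamState.init(head, weight_decay=1e-2)
        grads = [np.zeros_like(p) for p in head.parameters()]
        new, _ = fg.adam_step(head, grads, state)
        for old_p, new_p in zip(head.parameters(), new.parameters()):
            assert np.linalg.norm(new_p) < np.linalg.norm(old_p)

    def test_trajectory_matches_independent_reference(self):
        """1000 steps against a separately written scalar-loop Adam."""
        rng = np.random.default_rng(42)
        d = 5
        head = fg.HeadModel("linear", (rng.normal(size=(d, 1)),), (rng.normal(size=1),))
        state = fg.AdamState.init(head, lr=5e-3, weight_decay=1e-4)

        # reference: plain python floats, textbook update
        lr, wd, b1, b2, eps = 5e-3, 1e-4, 0.9, 0.999, 1e-8
        ref = [float(v) for v in head.weights[0][:, 0]] + [float(head.biases[0][0])]
        ref_m = [0.0] * (d + 1)
        ref_v = [0.0] * (d + 1)

        for t in range(1, 1001):
            g = rng.normal(size=d + 1)
            grads = [g[:d].reshape(d, 1), g[d:]]
            head, state = fg.adam_step(head, grads, state)
            for i in range(d + 1):
                gi = g[i] + wd * ref[i]
                ref_m[i] = b1 * ref_m[i] + (1 - b1) * gi
                ref_v[i] = b2 * ref_v[i] + (1 - b2) * gi * gi
                mh = ref_m[i] / (1 - b1**t)
                vh = ref_v[i] / (1 - b2**t)
                ref[i] = ref[i] - lr * mh / (vh**0.5 + eps)
            cur = list(head.weights[0][:, 0]) + [head.biases[0][0]]
            assert max(abs(a - b) for a, b in zip(cur, ref)) <= 1e-10


class TestAccounting:
    def test_linear_head_parameter_count(self):
        assert fg.head_param_count(fg.HeadModel.linear(1024)) == 1025

    def test_mlp_parameter_counts_match_enumeration(self):
        for n_layers in (2, 3, 4):
            head = fg.HeadModel.mlp(1024, n_layers)
            sizes = [1024] + [100] * (n_layers - 1) + [1]
            expected = sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
            assert fg.head_param_count(head) == expected
            assert head.layer_sizes == sizes

    def test_linear_inference_flops(self):
        """2 FLOPs/MAC plus the bias add: 2*1024 + 1 = 2049 (~2.0 kFLOPs)."""
        assert fg.head_flops(fg.HeadModel.linear(1024), "inference") == 2049

    def test_linear_train_step_flops(self):
        """forward 2049 + backward 4098 + Adam 9*1025 = 15372 (~15.3 kFLOPs)."""
        assert fg.head_flops(fg.HeadModel.linear(1024), "train_step") == 15_372

    def test_mlp_flop_ladder_has_equal_increments(self):
        inf = [fg.head_flops(fg.HeadModel.mlp(1024, n), "inference") for n in (2, 3, 4)]
        assert inf[0] == 2 * (1024 * 100 + 100) + 101
        assert inf[1] - inf[0] == inf[2] - inf[1]  # each extra 100x100 layer


def test_checkpoint_round_trip(tmp_path):
    head = fg.HeadModel.mlp(16, 3, hidden_units=5, seed=4)
    path = tmp_path / "head.json"
    save_head(head, path)
    back = load_head(path)
    assert back.kind == head.kind
    assert all(np.array_equal(a, b) for a, b in zip(back.weights, head.weights))
    assert all(np.array_equal(a, b) for a, b in zip(back.biases, head.biases))
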