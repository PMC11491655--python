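"""Training engines: composition, determinism, learnability, cost ledger."""

import numpy as np
import pytest

import fedgap as fg
from fedgap.training import ProtocolError, RoleError, pool_clients


@pytest.fixture(scope="module")
def noiseless_split(noiseless_cohort):
    clients = fg.build_network(noiseless_cohort)
    plan = fg.SplitPlan(n_train=300, n_val=60, seed=3)
    return fg.monte_carlo_split(clients, plan, 0)


class TestLocalUpdate:
    def test_composition_equals_single_adam_step(self, small_split):
        client = small_split.train[0]
        protocol = fg.TrainingProtocol(strategy="fl")
        head = fg.HeadModel.linear(client.X.shape[1], bias_init=50.0)
        new_head, _, flops = fg.local_update(head, client, protocol)
        _, grads = fg.l2_loss_and_grad(head, client.X, client.y)
        ref, _ = fg.adam_step(head, grads, fg.AdamState.init(head, lr=protocol.lr,
                                                            weight_decay=protocol.weight_decay))
        assert all(np.array_equal(a, b) for a, b in zip(new_head.parameters(), ref.parameters()))
        assert flops == fg.head_flops(head, "train_step")

    def test_zero_residual_only_weight_decay_moves(self, small_split):
        client = small_split.train[0]
        protocol = fg.TrainingProtocol(strategy="fl")
        # constant head predicting this client's exact age: gradients vanish
        head = fg.HeadModel.linear(client.X.shape[1], bias_init=client.age)
        new_head, _, _ = fg.local_update(head, client, protocol)
        assert np.array_equal(new_head.weights[0], head.weights[0])  # zero weights stay
        assert abs(new_head.biases[0][0] - head.biases[0][0]) <= protocol.lr  # decay shrink only

    def test_disease_client_rejected(self, tiny_cohort):
        disease = [c for c in fg.build_network(tiny_cohort) if c.group == "disease"][0]
        head = fg.HeadModel.linear(tiny_cohort.feature_dim)
        with pytest.raises(RoleError):
            fg.local_update(head, disease, fg.TrainingProtocol())


class TestFedAvg:
    def test_identity_and_midpoint(self):
        a = [np.array([0.0])]
        b = [np.array([2.0])]
        assert fg.fedavg([a, a])[0] == np.array([0.0])
        assert fg.fedavg([a, b])[0] == np.array([1.0])

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(8)
        sets = [[rng.normal(size=(3, 2)), rng.normal(size=2)] for _ in range(7)]
        avg = fg.fedavg(sets)
        for i in range(2):
            acc = np.zeros_like(sets[0][i])
            for ps in sets:
                acc = acc + ps[i]
            assert np.allclose(avg[i], acc / 7, atol=1e-15)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            fg.fedavg([[np.zeros(2)], [np.zeros(3)]])


class TestEvaluate:
    def test_exact_values(self):
        head = fg.HeadModel.linear(2, bias_init=0.0)
        X = np.zeros((2, 2))
        assert fg.evaluate(head, X, np.zeros(2)) == 0.0
        # predictions [50, 60] vs ages [52, 57] -> mean(|-2|, |3|) = 2.5
        w = np.array([[1.0], [0.0]])
        head = fg.HeadModel("linear", (w,), (np.array([0.0]),))
        X = np.array([[50.0, 0.0], [60.0, 0.0]])
        assert fg.evaluate(head, X, np.array([52.0, 57.0])) == 2.5

    def test_matches_brute_force_loop(self, small_split):
        head = fg.HeadModel.linear(small_split.train[0].X.shape[1], bias_init=47.0)
        got = fg.evaluate(head, small_split.validation)
        total, count = 0.0, 0
        for c in small_split.validation:
            for row, age in zip(c.X, c.y):
                total += abs(fg.predict(head, row) - age)
                count += 1
        assert got == pytest.approx(total / count, rel=1e-12)


class TestFederated:
    def test_noiseless_learnability(self, noiseless_split):
        """FedAvg reaches sub-half-year validation MAE on the noiseless cohort."""
        res = fg.train_federated(
            noiseless_split.train, noiseless_split.validation,
            fg.TrainingProtocol(strategy="fl", seed=1, max_rounds=600, patience=50),
        )
        assert res.best_val_mae < 0.5

    def test_single_client_round_equals_sequential_training(self, small_split):
        """With 1 client/round and a 1-client pool, FL degenerates to repeated
        local training of that client."""
        client = small_split.train[:1]
        protocol = fg.TrainingProtocol(
            strategy="fl", fl_clients_per_round=1, max_rounds=5, patience=5, seed=0
        )
        res = fg.train_federated(client, small_split.validation, protocol)
        head = fg.HeadModel.linear(client[0].X.shape[1], bias_init=client[0].age)
        for _ in range(5):
            head, _, _ = fg.local_update(head, client[0], protocol)
        # compare against the last-round head via its validation MAE trace
        assert res.history[-1] == pytest.approx(
            fg.evaluate(head, small_split.validation), rel=1e-12
        )

    def test_seeded_run_reproducible(self, small_split):
        protocol = fg.TrainingProtocol(strategy="fl", max_rounds=15, seed=11)
        a = fg.train_federated(small_split.train, small_split.validation, protocol)
        b = fg.train_federated(small_split.train, small_split.validation, protocol)
        assert a.history == b.history
        assert a.ledger.train_flops == b.ledger.train_flops
        assert a.ledger.model_transfers == b.ledger.model_transfers

    def test_capacity_check(self, small_split):
        protocol = fg.TrainingProtocol(strategy="fl", fl_clients_per_round=10_000)
        with pytest.raises(ProtocolError):
            fg.train_federated(small_split.train, small_split.validation, protocol)


class TestTraveling:
    def test_single_client_equals_repeated_local_training(self, small_split):
        client = small_split.train[:1]
        protocol = fg.TrainingProtocol(strategy="tm", max_rounds=4, patience=4, seed=0)
        res = fg.train_traveling(client, small_split.validation, protocol)
        head = fg.HeadModel.linear(client[0].X.shape[1], bias_init=client[0].age)
        for _ in range(4):
            head, _, _ = fg.local_update(head, client[0], protocol)
        assert res.history[-1] == pytest.approx(
            fg.evaluate(head, small_split.validation), rel=1e-12
        )

    def test_visit_orders_differ_between_cycles_but_reproduce(self, small_split):
        rng_a = np.random.default_rng(5)
        rng_b = np.random.default_rng(5)
        n = len(small_split.train)
        cycle1_a, cycle2_a = rng_a.permutation(n), rng_a.permutation(n)
        cycle1_b = rng_b.permutation(n)
        assert not np.array_equal(cycle1_a, cycle2_a)  # fresh order each cycle
        assert np.array_equal(cycle1_a, cycle1_b)  # reproducible across runs
        protocol = fg.TrainingProtocol(strategy="tm", max_rounds=3, patience=3, seed=5)
        a = fg.train_traveling(small_split.train, small_split.validation, protocol)
        b = fg.train_traveling(small_split.train, small_split.validation, protocol)
        assert a.history == b.history

    def test_noiseless_learnability(self, noiseless_split):
        res = fg.train_traveling(
            noiseless_split.train, noiseless_split.validation,
            fg.TrainingProtocol(strategy="tm", seed=2),
        )
        assert res.best_val_mae < 0.5


class TestCentralized:
    def test_noiseless_recovery(self, noiseless_split):
        res = fg.train_centralized(
            noiseless_split.train, noiseless_split.validation,
            fg.TrainingProtocol(strategy="central", seed=3),
        )
        train_mae = fg.evaluate(res.head, noiseless_split.train)
        assert train_mae < 0.1

    def test_full_batch_epoch_is_one_adam_step(self, small_split):
        clients = small_split.train[:20]
        X, y = pool_clients(clients)
        protocol = fg.TrainingProtocol(
            strategy="central", batch_size_central=len(y), max_rounds=1, seed=0
        )
        res = fg.train_centralized(clients, small_split.validation, protocol)
        head = fg.HeadModel.linear(X.shape[1], bias_init=float(np.mean([c.age for c in clients])))
        _, grads = fg.l2_loss_and_grad(head, X, y)
        ref, _ = fg.adam_step(head, grads, fg.AdamState.init(head, lr=protocol.lr,
                                                            weight_decay=protocol.weight_decay))
        assert res.ledger.local_updates == 1
        assert res.history[0] == pytest.approx(fg.evaluate(ref, small_split.validation), rel=1e-12)

    def test_reproducible(self, small_split):
        protocol = fg.TrainingProtocol(strategy="central", max_rounds=5, seed=21)
        a = fg.train_centralized(small_split.train, small_split.validation, protocol)
        b = fg.train_centralized(small_split.train, small_split.validation, protocol)
        assert a.history == b.history


class TestResultContract:
    def test_early_stopping_returns_argmin_snapshot(self, small_split):
        for maker, strat in (
            (fg.train_federated, "fl"),
            (fg.train_traveling, "tm"),
            (fg.train_centralized, "central"),
        ):
            res = maker(
                small_split.train, small_split.validation,
                fg.TrainingProtocol(strategy=strat, max_rounds=30, seed=4),
            )
            returned = fg.evaluate(res.head, small_split.validation)
            assert returned == pytest.approx(min(res.history), rel=1e-12)
            assert res.best_round == int(np.argmin(res.history))

    def test_ledger_byte_conservation(self, small_split):
        res = fg.train_federated(
            small_split.train, small_split.validation,
            fg.TrainingProtocol(strategy="fl", max_rounds=8, seed=4),
        )
        led = res.ledger
        assert led.bytes_transferred == 4 * led.param_count * led.model_transfers
        # 2 transfers per participating client per round
        assert led.model_transfers == 2 * 32 * len(res.history)
        assert led.local_updates == 32 * len(res.history)
        assert led.train_flops == led.local_updates * fg.head_flops(res.head, "train_step")

    def test_model_results_surface(self, small_split):
        model = fg.RetinalAgeModel.from_split(
            small_split, protocol=fg.TrainingProtocol(strategy="central", max_rounds=5, seed=1)
        )
        res = model.fit()
        assert res.params.shape == (small_split.train[0].X.shape[1] + 1,)
        text = res.summary()
        assert "central" in text and "validation MAE" in text
        assert res.mae(small_split.validation) == pytest.approx(res.val_mae, rel=1e-12)
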