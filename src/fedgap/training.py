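"""Centralized, federated (FedAvg) and traveling-model training engines.

All three strategies optimize the same head with the same Adam hyperparameters
on the same Monte-Carlo split, so within-iteration comparisons are paired:

* **central** — clients' records pooled, minibatch Adam with a persistent
  optimizer state, one validation check per epoch;
* **fl** — each round a fresh sample of ``fl_clients_per_round`` clients takes
  one local Adam step (fresh optimizer state, only parameters travel) from the
  current global head; the returned parameter sets are averaged (FedAvg);
* **tm** — the head travels through *all* training clients in a freshly
  randomized order each cycle, updated in place client-to-client.

Early stopping watches pooled validation MAE with a patience and returns the
best-validation snapshot. A :class:`CostLedger` counts local updates, training
FLOPs and parameter transfers (validation broadcasts tracked separately).

The public surface is statsmodels-flavoured: build a :class:`RetinalAgeModel`
from a split, call :meth:`~RetinalAgeModel.fit`, inspect the returned
:class:`RetinalAgeResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accounting import DEFAULT_HEAD_CONVENTION, FlopConvention
from .cohort import Cohort
from .heads import AdamState, HeadModel, adam_step, head_flops, head_param_count, l2_loss_and_grad, predict
from .network import Client

__all__ = [
    "TrainingProtocol",
    "CostLedger",
    "TrainResult",
    "RetinalAgeModel",
    "RetinalAgeResults",
    "local_update",
    "fedavg",
    "train_federated",
    "train_traveling",
    "train_centralized",
    "evaluate",
    "pool_clients",
]

STRATEGIES = ("central", "fl", "tm")


class ProtocolError(ValueError):
    pass


class RoleError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingProtocol:
    """Knobs of one training run (defaults follow the simulated-network setup)."""

    strategy: str = "central"
    max_rounds: int = 200
    patience: int = 10
    fl_clients_per_round: int = 32
    local_epochs: int = 1
    batch_size_central: int = 64
    lr: float = 5e-3
    weight_decay: float = 1e-4
    tm_carry_adam: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ProtocolError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if self.max_rounds < 1:
            raise ProtocolError("max_rounds must be >= 1")
        if self.patience < 1:
            raise ProtocolError("patience must be >= 1")
        if self.fl_clients_per_round < 1:
            raise ProtocolError("fl_clients_per_round must be >= 1")
        if self.local_epochs < 1:
            raise ProtocolError("local_epochs must be >= 1")


@dataclass
class CostLedger:
    """Monotone counters of the compute and communication a run consumed.

    ``bytes_transferred`` covers *training* parameter transfers only
    (payload = 4 bytes per parameter — heads travel at 32-bit precision);
    validation broadcasts are counted separately so either reading of "times
    parameters were shared" can be reconstructed.
    """

    param_count: int = 0
    local_updates: int = 0
    train_flops: int = 0
    model_transfers: int = 0
    validation_broadcasts: int = 0
    per_client_updates: dict[str, int] = field(default_factory=dict)

    @property
    def payload_bytes(self) -> int:
        return 4 * self.param_count

    @property
    def bytes_transferred(self) -> int:
        return self.model_transfers * self.payload_bytes

    def record_update(self, client_id: str, flops: int) -> None:
        self.local_updates += 1
        self.train_flops += flops
        self.per_client_updates[client_id] = self.per_client_updates.get(client_id, 0) + 1


@dataclass
class TrainResult:
    """Best-validation snapshot plus the full run trace."""

    head: HeadModel
    best_round: int
    history: list[float]  # validation MAE per round/cycle/epoch
    cum_updates: list[float]  # cumulative local updates after each round
    ledger: CostLedger
    n_train_clients: int

    @property
    def updates_per_client_at_best(self) -> float:
        """Mean local updates each training client ran up to convergence."""
        return self.cum_updates[self.best_round] / self.n_train_clients

    @property
    def best_val_mae(self) -> float:
        return self.history[self.best_round]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def pool_clients(clients: list[Client]) -> tuple[np.ndarray, np.ndarray]:
    """Stack all clients' records into pooled (X, y) arrays."""
    if not clients:
        raise ValueError("no clients to pool")
    X = np.concatenate([c.X for c in clients], axis=0)
    y = np.concatenate([c.y for c in clients])
    return X, y


def evaluate(head: HeadModel, data, y: np.ndarray | None = None) -> float:
    """Pooled mean absolute error (years); both eyes count separately."""
    if y is not None:
        X = np.asarray(data, dtype=float)
    elif isinstance(data, Cohort):
        X, y = data.features, data.meta["age"].to_numpy()
    else:
        X, y = pool_clients(list(data))
    if len(y) == 0:
        raise ValueError("nothing to evaluate")
    return float(np.mean(np.abs(predict(head, X) - y)))


def local_update(
    head: HeadModel,
    client: Client,
    protocol: TrainingProtocol,
    state: AdamState | None = None,
    conv: FlopConvention = DEFAULT_HEAD_CONVENTION,
) -> tuple[HeadModel, AdamState, int]:
    """``local_epochs`` Adam steps on the client's two records as one batch.

    ``state=None`` starts from a fresh optimizer state — the default protocol:
    only model parameters travel between server and clients. Each local update
    is billed at one ``train_step`` FLOP unit (forward + backward + Adam).
    """
    if client.group != "healthy":
        raise RoleError(f"client {client.client_id} is not a training-eligible healthy client")
    if state is None:
        state = AdamState.init(head, lr=protocol.lr, weight_decay=protocol.weight_decay)
    step_flops = head_flops(head, "train_step", conv)
    spent = 0
    for _ in range(protocol.local_epochs):
        _, grads = l2_loss_and_grad(head, client.X, client.y)
        head, state = adam_step(head, grads, state)
        spent += step_flops
    return head, state, spent


def fedavg(param_sets: list) -> list[np.ndarray] | HeadModel:
    """Unweighted elementwise mean of parameter sets (every client holds the
    same two records, so uniform weights are exact FedAvg)."""
    if not param_sets:
        raise ValueError("fedavg needs at least one parameter set")
    if isinstance(param_sets[0], HeadModel):
        kind = param_sets[0].kind
        lists = [h.parameters() for h in param_sets]
        return HeadModel.from_parameters(kind, fedavg(lists))
    first = param_sets[0]
    for ps in param_sets[1:]:
        if len(ps) != len(first) or any(a.shape != b.shape for a, b in zip(ps, first)):
            raise ValueError("parameter sets have mismatched shapes")
    return [np.mean([ps[i] for ps in param_sets], axis=0) for i in range(len(first))]


def _init_head(train_clients: list[Client]) -> HeadModel:
    """Zero weights, bias at the training-set mean age (the constant-mean
    predictor), so every strategy starts from the same sensible baseline."""
    X0 = train_clients[0].X
    mean_age = float(np.mean([c.age for c in train_clients]))
    return HeadModel.linear(X0.shape[1], bias_init=mean_age)


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

def _run_rounds(step_fn, head, val_X, val_y, protocol, ledger, n_train):
    """Shared round loop with patience-based early stopping on validation MAE."""
    history: list[float] = []
    cum_updates: list[float] = []
    best_mae = np.inf
    best_head = head
    best_round = 0
    n_val_clients = len(val_y) // 2
    for rnd in range(protocol.max_rounds):
        head = step_fn(head, rnd)
        mae = float(np.mean(np.abs(predict(head, val_X) - val_y)))
        ledger.validation_broadcasts += n_val_clients
        history.append(mae)
        cum_updates.append(float(ledger.local_updates))
        if mae < best_mae:
            best_mae, best_head, best_round = mae, head, rnd
        if rnd - best_round >= protocol.patience:
            break
    return TrainResult(best_head, best_round, history, cum_updates, ledger, n_train)


def train_federated(
    train_clients: list[Client],
    val_clients: list[Client],
    protocol: TrainingProtocol,
    conv: FlopConvention = DEFAULT_HEAD_CONVENTION,
) -> TrainResult:
    """FedAvg: per round, a fresh without-replacement sample of clients each
    takes one local update from the global head; updates are averaged."""
    if protocol.fl_clients_per_round > len(train_clients):
        raise ProtocolError(
            f"fl_clients_per_round={protocol.fl_clients_per_round} exceeds "
            f"{len(train_clients)} training clients"
        )
    if not val_clients:
        raise ProtocolError("federated training needs validation clients")
    rng = np.random.default_rng(protocol.seed)
    val_X, val_y = pool_clients(val_clients)
    head0 = _init_head(train_clients)
    ledger = CostLedger(param_count=head_param_count(head0))

    def step(head: HeadModel, rnd: int) -> HeadModel:
        idx = rng.choice(len(train_clients), size=protocol.fl_clients_per_round, replace=False)
        updated = []
        for i in idx:
            client = train_clients[i]
            new_head, _, flops = local_update(head, client, protocol, conv=conv)
            ledger.record_update(client.client_id, flops)
            ledger.model_transfers += 2  # send + return
            updated.append(new_head)
        return fedavg(updated)

    return _run_rounds(step, head0, val_X, val_y, protocol, ledger, len(train_clients))


def train_traveling(
    train_clients: list[Client],
    val_clients: list[Client],
    protocol: TrainingProtocol,
    conv: FlopConvention = DEFAULT_HEAD_CONVENTION,
) -> TrainResult:
    """Traveling model: the head visits every client once per cycle, in a
    freshly randomized order, updated sequentially in place."""
    if not train_clients:
        raise ProtocolError("traveling-model training needs at least one client")
    if not val_clients:
        raise ProtocolError("traveling-model training needs validation clients")
    rng = np.random.default_rng(protocol.seed)
    val_X, val_y = pool_clients(val_clients)
    head0 = _init_head(train_clients)
    ledger = CostLedger(param_count=head_param_count(head0))
    carried_state: list[AdamState | None] = [None]

    def step(head: HeadModel, rnd: int) -> HeadModel:
        order = rng.permutation(len(train_clients))
        for i in order:
            client = train_clients[i]
            state = carried_state[0] if protocol.tm_carry_adam else None
            head, state, flops = local_update(head, client, protocol, state=state, conv=conv)
            if protocol.tm_carry_adam:
                carried_state[0] = state
            ledger.record_update(client.client_id, flops)
            ledger.model_transfers += 2  # arrive + leave
        return head

    return _run_rounds(step, head0, val_X, val_y, protocol, ledger, len(train_clients))


def train_centralized(
    train_clients: list[Client],
    val_clients: list[Client],
    protocol: TrainingProtocol,
    conv: FlopConvention = DEFAULT_HEAD_CONVENTION,
) -> TrainResult:
    """Pooled minibatch Adam (persistent state, reshuffled each epoch)."""
    if not train_clients:
        raise ValueError("empty training pool")
    if not val_clients:
        raise ProtocolError("centralized training needs validation data")
    rng = np.random.default_rng(protocol.seed)
    X, y = pool_clients(train_clients)
    val_X, val_y = pool_clients(val_clients)
    head0 = _init_head(train_clients)
    ledger = CostLedger(param_count=head_param_count(head0))
    state = AdamState.init(head0, lr=protocol.lr, weight_decay=protocol.weight_decay)
    state_box = [state]
    bs = protocol.batch_size_central
    # centralized FLOPs itemized per record (forward + backward) plus one
    # optimizer update per minibatch
    fwd = head_flops(head0, "inference", conv)
    adam_flops = head_flops(head0, "train_step", conv) - 3 * fwd

    def step(head: HeadModel, rnd: int) -> HeadModel:
        order = rng.permutation(len(y))
        st = state_box[0]
        for start in range(0, len(y), bs):
            sel = order[start : start + bs]
            _, grads = l2_loss_and_grad(head, X[sel], y[sel])
            head, st = adam_step(head, grads, st)
            ledger.local_updates += 1
            ledger.train_flops += 3 * fwd * len(sel) + adam_flops
        state_box[0] = st
        return head

    return _run_rounds(step, head0, val_X, val_y, protocol, ledger, len(train_clients))


_ENGINES = {"central": train_centralized, "fl": train_federated, "tm": train_traveling}


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class RetinalAgeModel:
    """Age-regression head bound to one Monte-Carlo split and a strategy.

    Parameters
    ----------
    train_clients, val_clients : lists of :class:`~fedgap.network.Client`
    protocol : :class:`TrainingProtocol`, optional
        ``protocol.strategy`` picks the engine.
    conv : :class:`~fedgap.accounting.FlopConvention`, optional
        FLOP convention used by the cost ledger.
    """

    def __init__(
        self,
        train_clients: list[Client],
        val_clients: list[Client],
        protocol: TrainingProtocol | None = None,
        conv: FlopConvention = DEFAULT_HEAD_CONVENTION,
    ):
        self.train_clients = list(train_clients)
        self.val_clients = list(val_clients)
        self.protocol = protocol or TrainingProtocol()
        self.conv = conv

    @classmethod
    def from_split(cls, split, protocol: TrainingProtocol | None = None, **kw) -> "RetinalAgeModel":
        return cls(split.train, split.validation, protocol=protocol, **kw)

    def fit(self) -> "RetinalAgeResults":
        engine = _ENGINES[self.protocol.strategy]
        result = engine(self.train_clients, self.val_clients, self.protocol, conv=self.conv)
        return RetinalAgeResults(self, result)


class RetinalAgeResults:
    """Fitted head plus run diagnostics (history, ledger, convergence round)."""

    def __init__(self, model: RetinalAgeModel, result: TrainResult):
        self.model = model
        self._result = result
        self.head = result.head
        self.history = result.history
        self.best_round = result.best_round
        self.ledger = result.ledger

    @property
    def params(self) -> np.ndarray:
        """Flat parameter vector (weights then bias)."""
        return np.concatenate([p.ravel() for p in self.head.parameters()])

    @property
    def val_mae(self) -> float:
        return self._result.best_val_mae

    @property
    def updates_per_client(self) -> float:
        return self._result.updates_per_client_at_best

    def predict(self, X: np.ndarray) -> np.ndarray | float:
        return predict(self.head, X)

    def mae(self, data, y: np.ndarray | None = None) -> float:
        return evaluate(self.head, data, y)

    def summary(self) -> str:
        p = self.model.protocol
        led = self.ledger
        lines = [
            "Retinal age regression results",
            "=" * 46,
            f"strategy:              {p.strategy}",
            f"training clients:      {len(self.model.train_clients)}",
            f"validation clients:    {len(self.model.val_clients)}",
            f"head parameters:       {led.param_count}",
            f"rounds run:            {len(self.history)} (max {p.max_rounds}, patience {p.patience})",
            f"best round:            {self.best_round}",
            f"best validation MAE:   {self.val_mae:.3f} years",
            f"local updates:         {led.local_updates}",
            f"updates per client:    {self.updates_per_client:.2f}",
            f"training FLOPs:        {led.train_flops:,}",
            f"parameter transfers:   {led.model_transfers} "
            f"({led.bytes_transferred:,} bytes at 32-bit)",
            f"validation broadcasts: {led.validation_broadcasts}",
        ]
        return "\n".join(lines)
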