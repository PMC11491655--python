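"""Regression heads trained on frozen embeddings.

The trainable model is deliberately tiny: a linear regression head (LRH) with
``D`` weights plus one bias (1025 parameters for D=1024), or an MLP with
100-unit ReLU hidden layers. Forward pass, L2 loss, analytic gradients and the
Adam update are written out explicitly — the exact per-step arithmetic *is*
the contract here, since the distributed cost ledger counts these operations.

An ``n``-layer MLP means ``n`` weight matrices: ``D -> 100 -> ... -> 100 -> 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .accounting import DEFAULT_HEAD_CONVENTION, FlopConvention

__all__ = [
    "HeadModel",
    "AdamState",
    "predict",
    "l2_loss_and_grad",
    "adam_step",
    "head_param_count",
    "head_flops",
    "save_head",
    "load_head",
]

ADAM_FLOPS_PER_PARAM = 9  # documented per-parameter cost of one Adam update


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class HeadModel:
    """A stack of affine layers with ReLU between (none for ``linear``)."""

    kind: str  # "linear" | "mlp"
    weights: tuple[np.ndarray, ...]  # each (n_in, n_out)
    biases: tuple[np.ndarray, ...]  # each (n_out,)

    @classmethod
    def linear(cls, input_dim: int = 1024, bias_init: float = 0.0) -> "HeadModel":
        return cls(
            kind="linear",
            weights=(np.zeros((input_dim, 1)),),
            biases=(np.array([float(bias_init)]),),
        )

    @classmethod
    def mlp(
        cls,
        input_dim: int = 1024,
        n_layers: int = 2,
        hidden_units: int = 100,
        seed: int = 0,
        bias_init: float = 0.0,
    ) -> "HeadModel":
        """``n_layers`` weight matrices, every hidden layer ``hidden_units`` wide."""
        if n_layers < 2:
            raise ShapeError("an MLP head needs >= 2 layers (use linear() otherwise)")
        rng = np.random.default_rng(seed)
        sizes = [input_dim] + [hidden_units] * (n_layers - 1) + [1]
        weights, biases = [], []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            weights.append(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
            biases.append(np.zeros(n_out))
        biases[-1] = np.array([float(bias_init)])
        return cls(kind="mlp", weights=tuple(weights), biases=tuple(biases))

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def parameters(self) -> list[np.ndarray]:
        """Flat parameter list in the canonical order W0, b0, W1, b1, ..."""
        out: list[np.ndarray] = []
        for w, b in zip(self.weights, self.biases):
            out.extend([w, b])
        return out

    @classmethod
    def from_parameters(cls, kind: str, params: list[np.ndarray]) -> "HeadModel":
        return cls(kind=kind, weights=tuple(params[0::2]), biases=tuple(params[1::2]))

    def predict(self, x: np.ndarray) -> np.ndarray | float:
        return predict(self, x)


def _forward(head: HeadModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; ReLU between layers, linear output."""
    acts = [X]
    h = X
    last = len(head.weights) - 1
    for i, (w, b) in enumerate(zip(head.weights, head.biases)):
        h = h @ w + b
        if i < last:
            h = np.maximum(h, 0.0)
        acts.append(h)
    return acts


def predict(head: HeadModel, x: np.ndarray) -> np.ndarray | float:
    """Predicted age(s); scalar for a single vector, 1-D array for a batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != head.input_dim:
        raise ShapeError(f"expected {head.input_dim} features, got {X.shape[1]}")
    out = _forward(head, X)[-1][:, 0]
    return float(out[0]) if single else out


def l2_loss_and_grad(
    head: HeadModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    """Mean squared error over the batch and its exact gradients.

    Gradients are returned in the canonical parameter order (see
    :meth:`HeadModel.parameters`).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
        y = np.atleast_1d(y)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    if X.shape[1] != head.input_dim:
        raise ShapeError(f"expected {head.input_dim} features, got {X.shape[1]}")
    n = X.shape[0]
    acts = _forward(head, X)
    resid = acts[-1][:, 0] - y
    loss = float(np.mean(resid**2))

    grads: list[np.ndarray] = []
    delta = (2.0 / n) * resid[:, None]  # dL/d(output)
    last = len(head.weights) - 1
    layer_grads: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(last, -1, -1):
        layer_grads.append((acts[i].T @ delta, delta.sum(axis=0)))
        if i > 0:
            delta = (delta @ head.weights[i].T) * (acts[i] > 0)
    for gw, gb in reversed(layer_grads):
        grads.extend([gw, gb])
    return loss, grads


@dataclass(frozen=True)
class AdamState:
    """Adam optimizer state (coupled L2 weight decay, added to the gradient)."""

    step: int
    m: tuple[np.ndarray, ...]
    v: tuple[np.ndarray, ...]
    lr: float = 5e-3
    weight_decay: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def init(cls, head: HeadModel, lr: float = 5e-3, weight_decay: float = 1e-4,
             beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> "AdamState":
        params = head.parameters()
        return cls(
            step=0,
            m=tuple(np.zeros_like(p) for p in params),
            v=tuple(np.zeros_like(p) for p in params),
            lr=lr, weight_decay=weight_decay, beta1=beta1, beta2=beta2, eps=eps,
        )


def adam_step(
    head: HeadModel, grads: list[np.ndarray], state: AdamState
) -> tuple[HeadModel, AdamState]:
    """One Adam update; returns the new head and state (inputs untouched)."""
    params = head.parameters()
    if len(grads) != len(params):
        raise ShapeError(f"expected {len(params)} gradient arrays, got {len(grads)}")
    t = state.step + 1
    bc1 = 1.0 - state.beta1**t
    bc2 = 1.0 - state.beta2**t
    new_params, new_m, new_v = [], [], []
    for p, g, m, v in zip(params, grads, state.m, state.v):
        if g.shape != p.shape:
            raise ShapeError(f"gradient shape {g.shape} != parameter shape {p.shape}")
        g = g + state.weight_decay * p
        m = state.beta1 * m + (1.0 - state.beta1) * g
        v = state.beta2 * v + (1.0 - state.beta2) * g**2
        m_hat = m / bc1
        v_hat = v / bc2
        new_params.append(p - state.lr * m_hat / (np.sqrt(v_hat) + state.eps))
        new_m.append(m)
        new_v.append(v)
    new_head = HeadModel.from_parameters(head.kind, new_params)
    new_state = AdamState(
        step=t, m=tuple(new_m), v=tuple(new_v),
        lr=state.lr, weight_decay=state.weight_decay,
        beta1=state.beta1, beta2=state.beta2, eps=state.eps,
    )
    return new_head, new_state


def head_param_count(head: HeadModel) -> int:
    return int(sum(p.size for p in head.parameters()))


def head_flops(
    head: HeadModel,
    phase: str = "inference",
    conv: FlopConvention = DEFAULT_HEAD_CONVENTION,
) -> int:
    """FLOPs of one forward pass or one full training update on one sample.

    ``train_step`` = forward + backward (counted as 2x forward) + Adam
    (:data:`ADAM_FLOPS_PER_PARAM` per parameter).
    """
    macs = sum(w.size for w in head.weights)
    fwd = conv.flops_per_mac * macs
    if conv.count_bias_adds:
        fwd += sum(b.size for b in head.biases)
    if conv.count_norms_activations:
        fwd += sum(b.size for b in head.biases[:-1])  # one ReLU per hidden unit
    if phase == "inference":
        return int(fwd)
    if phase == "train_step":
        return int(3 * fwd + ADAM_FLOPS_PER_PARAM * head_param_count(head))
    raise ValueError(f"phase must be 'inference' or 'train_step', got {phase!r}")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_head(head: HeadModel, path) -> None:
    payload = {
        "schema": "fedgap-head-v1",
        "kind": head.kind,
        "layer_sizes": head.layer_sizes,
        "weights": [w.tolist() for w in head.weights],
        "biases": [b.tolist() for b in head.biases],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_head(path) -> HeadModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema") != "fedgap-head-v1":
        raise ValueError(f"not a head checkpoint: {path}")
    return HeadModel(
        kind=payload["kind"],
        weights=tuple(np.asarray(w, dtype=float) for w in payload["weights"]),
        biases=tuple(np.asarray(b, dtype=float) for b in payload["biases"]),
    )
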