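"""Feed-forward surrogate of removal efficiency: a dense ReLU network.

The surrogate maps the seven normalized process features to the removal
percentage.  Hidden layers use ReLU, the single output is linear, and the
loss is mean squared error plus an L1 penalty (rate 0.01) on the kernel
weights.  Training is full-batch adaptive-moment gradient descent (Adam,
learning rate 0.05 by default) with an internal validation split of 0.2
for early stopping.  Everything is plain numpy so training is fast, fully
deterministic under a seed, and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from petsorb.records import normalize_rows, one_hot

MAX_HIDDEN_LAYERS = 5
MAX_NEURONS = 20
N_INPUTS = 7


@dataclass(frozen=True)
class NetworkTopology:
    """Architecture of the dense surrogate: 1-5 hidden layers of 1-20 neurons."""

    hidden_layers: tuple[int, ...]
    l1_rate: float = 0.01
    n_inputs: int = N_INPUTS
    n_outputs: int = 1

    def __post_init__(self) -> None:
        if not 1 <= len(self.hidden_layers) <= MAX_HIDDEN_LAYERS:
            raise ValueError(
                f"hidden layer count must be in [1, {MAX_HIDDEN_LAYERS}], "
                f"got {len(self.hidden_layers)}"
            )
        for w in self.hidden_layers:
            if not 1 <= w <= MAX_NEURONS:
                raise ValueError(f"layer width {w} outside [1, {MAX_NEURONS}]")


def _init_weights(topology: NetworkTopology, rng: np.random.Generator):
    sizes = [topology.n_inputs, *topology.hidden_layers, topology.n_outputs]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(X, weights, biases):
    """Returns (prediction, per-layer activations) for backprop."""
    acts = [X]
    a = X
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = a @ W + b
        a = z if i == len(weights) - 1 else np.maximum(z, 0.0)
        acts.append(a)
    return a[:, 0], acts


def _loss_and_grads(X, y, weights, biases, l1_rate):
    n = X.shape[0]
    pred, acts = _forward(X, weights, biases)
    err = pred - y
    mse = float(np.mean(err**2))
    loss = mse + l1_rate * sum(float(np.abs(W).sum()) for W in weights)

    gW = [None] * len(weights)
    gb = [None] * len(weights)
    delta = (2.0 / n) * err[:, None]  # dL/dz at the linear output
    for i in reversed(range(len(weights))):
        a_prev = acts[i]
        gW[i] = a_prev.T @ delta + l1_rate * np.sign(weights[i])
        gb[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ weights[i].T) * (acts[i] > 0)
    return loss, mse, gW, gb


@dataclass
class TrainedSurrogate:
    """Decoded and trained network with its normalization contract.

    ``predict`` consumes already-normalized 7-feature rows; ``predict_raw``
    consumes raw-unit conditions plus an antibiotic label and applies the
    stored min-max bounds first.
    """

    topology: NetworkTopology
    weights: list
    biases: list
    bounds: np.ndarray | None = None  # (2, 7) min/max used at training time
    loss_history: list = field(default_factory=list)
    val_loss_history: list = field(default_factory=list)
    final_loss: float = float("nan")
    final_mse: float = float("nan")
    seed: int | None = None

    def predict(self, X_normalized) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X_normalized, dtype=float))
        pred, _ = _forward(X, self.weights, self.biases)
        return pred

    def predict_raw(self, conditions, antibiotic: str) -> np.ndarray:
        """Predict removal % from raw-unit rows (pH, dose, time, c0, temperature).

        The output is the network's raw regression value; callers that
        report a removal percentage should clip it to the physical [0, 100]
        range (the optimizer does so when reporting its optimum).
        """
        if self.bounds is None:
            raise ValueError("surrogate has no stored normalization bounds")
        cond = np.atleast_2d(np.asarray(conditions, dtype=float))
        hot = np.tile(one_hot(antibiotic), (cond.shape[0], 1))
        raw = np.hstack([cond, hot])
        return self.predict(normalize_rows(raw, self.bounds))


def train_network(
    topology: NetworkTopology,
    train_features: np.ndarray,
    train_targets: np.ndarray,
    lr: float = 0.05,
    validation_split: float = 0.2,
    max_epochs: int = 200,
    patience: int = 20,
    seed: int = 0,
    bounds: np.ndarray | None = None,
) -> TrainedSurrogate:
    """Train the surrogate by full-batch Adam on MSE + L1.

    A fraction ``validation_split`` of the rows (seeded shuffle) is held out
    for early stopping: training stops once the validation loss has not
    improved for ``patience`` epochs, and the best-validation weights are
    restored.  Deterministic under a fixed seed.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_targets, dtype=float)
    rng = np.random.default_rng(seed)
    weights, biases = _init_weights(topology, rng)

    n = X.shape[0]
    if validation_split > 0 and n >= 5:
        perm = rng.permutation(n)
        n_val = max(1, int(round(n * validation_split)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_tr, y_tr, X_val, y_val = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
    else:
        X_tr, y_tr, X_val, y_val = X, y, None, None

    # Adam state
    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8

    history, val_history = [], []
    best_val = np.inf
    best_state = None
    stall = 0
    for epoch in range(1, max_epochs + 1):
        loss, _, gW, gb = _loss_and_grads(X_tr, y_tr, weights, biases, topology.l1_rate)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch} "
                f"(topology={topology.hidden_layers}, lr={lr})"
            )
        history.append(loss)
        for i in range(len(weights)):
            for g, m, v, p in ((gW[i], mW[i], vW[i], weights[i]), (gb[i], mb[i], vb[i], biases[i])):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g**2
                mhat = m / (1 - b1**epoch)
                vhat = v / (1 - b2**epoch)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

        if X_val is not None:
            val_pred, _ = _forward(X_val, weights, biases)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
            val_history.append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = ([W.copy() for W in weights], [b.copy() for b in biases])
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break

    if best_state is not None:
        weights, biases = best_state

    # final penalized loss on the full training set with the kept weights
    final_loss, final_mse, _, _ = _loss_and_grads(X, y, weights, biases, topology.l1_rate)
    return TrainedSurrogate(
        topology=topology,
        weights=weights,
        biases=biases,
        bounds=None if bounds is None else np.asarray(bounds, dtype=float),
        loss_history=history,
        val_loss_history=val_history,
        final_loss=final_loss,
        final_mse=final_mse,
        seed=seed,
    )


def save_surrogate(model: TrainedSurrogate, path) -> None:
    """Serialize the surrogate (topology, weights, bounds) to portable JSON."""
    import json

    payload = {
        "hidden_layers": list(model.topology.hidden_layers),
        "l1_rate": model.topology.l1_rate,
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "bounds": None if model.bounds is None else model.bounds.tolist(),
        "seed": model.seed,
        "final_loss": model.final_loss,
        "final_mse": model.final_mse,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_surrogate(path) -> TrainedSurrogate:
    """Inverse of :func:`save_surrogate`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    topo = NetworkTopology(
        hidden_layers=tuple(payload["hidden_layers"]), l1_rate=payload["l1_rate"]
    )
    return TrainedSurrogate(
        topology=topo,
        weights=[np.array(W) for W in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        bounds=None if payload["bounds"] is None else np.array(payload["bounds"]),
        final_loss=payload["final_loss"],
        final_mse=payload["final_mse"],
        seed=payload["seed"],
    )


def performance(model: TrainedSurrogate, X_normalized, y) -> dict[str, float]:
    """R2, MAE, MSE and fractional MAPE of the surrogate on a data subset."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty dataset")
    pred = model.predict(X_normalized)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed removal has zero variance; R2 undefined")
    err = pred - y
    nz = y != 0
    return {
        "R2": 1.0 - float(np.sum(err**2)) / sst,
        "MAE": float(np.mean(np.abs(err))),
        "MSE": float(np.mean(err**2)),
        "MAPE": float(np.mean(np.abs(err[nz] / y[nz]))),
    }
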