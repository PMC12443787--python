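"""Bidirectional-GRU multi-label classifier, implemented in NumPy.

Architecture (defaults reproduce the 5,601-parameter configuration):

* encoder: affine 88 -> 32 + ReLU + 10% dropout, applied at every month —
  compresses the largely sparse drug grid;
* bidirectional GRU with hidden size h (default 8) over the 18 months, one
  bias vector per gate per direction; the two final hidden states are
  concatenated with the 4 static covariates (sex, normalized age, BD, SZD);
* head: affine (2h+4) -> 24 + ReLU + dropout, affine 24 -> 8 + ReLU,
  affine 8 -> 9 + sigmoid — one probability per adverse event.

Gates follow the standard GRU update

    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)
    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)
    n_t = tanh(W_n x_t + U_n (r_t * h_{t-1}) + b_n)
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

Forward, parameter gradients, and input gradients are all hand-written and
verified against finite differences in the test suite; the input gradients
are what the expected-gradients attribution consumes. Training uses Adam
with a weighted binary cross entropy and validation-loss early stopping.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

N_OUTPUTS = 9


@dataclass(frozen=True)
class ModelConfig:
    n_features_t: int = 88
    n_months: int = 18
    encoder_dim: int = 32
    hidden_size: int = 8
    dense_dims: tuple = (24, 8)
    n_outputs: int = N_OUTPUTS
    dropout: float = 0.10

    def __post_init__(self) -> None:
        if self.encoder_dim >= self.n_features_t:
            raise ValueError("encoder must reduce dimensionality")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    batch_size: int = 128
    patience: int = 15
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


REFERENCE_PARAM_COUNT = 5601


def count_parameters(config: ModelConfig = ModelConfig()) -> int:
    """Closed-form trainable-parameter count for a configuration.

    encoder: F*E + E; per GRU direction: 3*(E*h + h^2 + h) (single bias per
    gate); head: (2h+4)*d1 + d1, d1*d2 + d2, d2*9 + 9.
    """
    f, e, h = config.n_features_t, config.encoder_dim, config.hidden_size
    d1, d2 = config.dense_dims
    enc = f * e + e
    gru = 2 * 3 * (e * h + h * h + h)
    n_static = 4
    head = (2 * h + n_static) * d1 + d1 + d1 * d2 + d2 + d2 * config.n_outputs + config.n_outputs
    return enc + gru + head


def init_params(config: ModelConfig, seed: int) -> dict:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization, seeded."""
    rng = np.random.default_rng(seed)

    def mat(fan_in, shape):
        s = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-s, s, size=shape)

    e, h = config.encoder_dim, config.hidden_size
    d1, d2 = config.dense_dims
    p = {
        "Wenc": mat(config.n_features_t, (config.n_features_t, e)),
        "benc": np.zeros(e),
    }
    for direction in ("f", "b"):
        for gate in ("z", "r", "n"):
            p[f"W{gate}_{direction}"] = mat(e, (e, h))
            p[f"U{gate}_{direction}"] = mat(h, (h, h))
            p[f"b{gate}_{direction}"] = np.zeros(h)
    p["W1"] = mat(2 * h + 4, (2 * h + 4, d1))
    p["b1"] = np.zeros(d1)
    p["W2"] = mat(d1, (d1, d2))
    p["b2"] = np.zeros(d2)
    p["W3"] = mat(d2, (d2, config.n_outputs))
    p["b3"] = np.zeros(config.n_outputs)
    return p


def n_params(params: dict) -> int:
    """Actual parameter count of a built model (oracle for the formula)."""
    return int(sum(v.size for v in params.values()))


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> "Model":
    """Instantiate the network; warns if defaults drift from the reference
    5,601-parameter configuration (non-default configs are fine for CV)."""
    expected = count_parameters(config)
    if config == ModelConfig() and expected != REFERENCE_PARAM_COUNT:
        warnings.warn(
            f"default configuration has {expected} parameters, "
            f"expected {REFERENCE_PARAM_COUNT}"
        )
    return Model(config=config, params=init_params(config, seed))


# ---------------------------------------------------------------------------
# forward / backward


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _gru_direction(params, E, direction, reverse):
    """Run one GRU direction over E (n, T, e); returns final h and caches."""
    n, T, _ = E.shape
    h_dim = params[f"bz_{direction}"].shape[0]
    Wz, Uz, bz = params[f"Wz_{direction}"], params[f"Uz_{direction}"], params[f"bz_{direction}"]
    Wr, Ur, br = params[f"Wr_{direction}"], params[f"Ur_{direction}"], params[f"br_{direction}"]
    Wn, Un, bn = params[f"Wn_{direction}"], params[f"Un_{direction}"], params[f"bn_{direction}"]
    h = np.zeros((n, h_dim))
    order = range(T - 1, -1, -1) if reverse else range(T)
    steps = []
    for t in order:
        x = E[:, t, :]
        z = _sigmoid(x @ Wz + h @ Uz + bz)
        r = _sigmoid(x @ Wr + h @ Ur + br)
        nc = np.tanh(x @ Wn + (r * h) @ Un + bn)
        h_new = (1.0 - z) * nc + z * h
        steps.append({"t": t, "x": x, "h_prev": h, "z": z, "r": r, "nc": nc})
        h = h_new
    return h, steps


def forward(params, X, static, config: ModelConfig, dropout_rng=None):
    """Probabilities (n, 9) and a cache for the backward pass.

    ``X`` is (n, months, features) of normalized exposures; ``static`` is
    (n, 4). Dropout is active only when ``dropout_rng`` is given (training).
    """
    n = X.shape[0]
    cache = {"X": X, "static": static}
    A_enc = X @ params["Wenc"] + params["benc"]  # (n, T, e)
    E = np.maximum(A_enc, 0.0)
    if dropout_rng is not None and config.dropout > 0:
        keep = 1.0 - config.dropout
        mask_enc = (dropout_rng.random(E.shape) < keep) / keep
        E = E * mask_enc
    else:
        mask_enc = None
    h_f, steps_f = _gru_direction(params, E, "f", reverse=False)
    h_b, steps_b = _gru_direction(params, E, "b", reverse=True)
    concat = np.concatenate([h_f, h_b, static], axis=1)
    a1 = concat @ params["W1"] + params["b1"]
    d1 = np.maximum(a1, 0.0)
    if dropout_rng is not None and config.dropout > 0:
        keep = 1.0 - config.dropout
        mask_d1 = (dropout_rng.random(d1.shape) < keep) / keep
        d1d = d1 * mask_d1
    else:
        mask_d1, d1d = None, d1
    a2 = d1d @ params["W2"] + params["b2"]
    d2 = np.maximum(a2, 0.0)
    logits = d2 @ params["W3"] + params["b3"]
    probs = _sigmoid(logits)
    cache.update(
        A_enc=A_enc, E=E, mask_enc=mask_enc, steps_f=steps_f, steps_b=steps_b,
        h_f=h_f, h_b=h_b, concat=concat, a1=a1, d1d=d1d, mask_d1=mask_d1,
        a2=a2, d2=d2, probs=probs, n=n,
    )
    return probs, cache


def _gru_backward(params, steps, dh, direction, dE):
    """Backprop one direction; accumulates dE in place, returns param grads."""
    g = {}
    for name in ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wn", "Un", "bn"):
        g[f"{name}_{direction}"] = np.zeros_like(params[f"{name}_{direction}"])
    Wz, Uz = params[f"Wz_{direction}"], params[f"Uz_{direction}"]
    Wr, Ur = params[f"Wr_{direction}"], params[f"Ur_{direction}"]
    Wn, Un = params[f"Wn_{direction}"], params[f"Un_{direction}"]
    for step in reversed(steps):
        t, x, h_prev = step["t"], step["x"], step["h_prev"]
        z, r, nc = step["z"], step["r"], step["nc"]
        dz = dh * (h_prev - nc)
        dnc = dh * (1.0 - z)
        dh_prev = dh * z
        da_n = dnc * (1.0 - nc * nc)
        g[f"Wn_{direction}"] += x.T @ da_n
        g[f"Un_{direction}"] += (r * h_prev).T @ da_n
        g[f"bn_{direction}"] += da_n.sum(axis=0)
        dx = da_n @ Wn.T
        drh = da_n @ Un.T
        dr = drh * h_prev
        dh_prev = dh_prev + drh * r
        da_z = dz * z * (1.0 - z)
        g[f"Wz_{direction}"] += x.T @ da_z
        g[f"Uz_{direction}"] += h_prev.T @ da_z
        g[f"bz_{direction}"] += da_z.sum(axis=0)
        dx += da_z @ Wz.T
        dh_prev = dh_prev + da_z @ Uz.T
        da_r = dr * r * (1.0 - r)
        g[f"Wr_{direction}"] += x.T @ da_r
        g[f"Ur_{direction}"] += h_prev.T @ da_r
        g[f"br_{direction}"] += da_r.sum(axis=0)
        dx += da_r @ Wr.T
        dh_prev = dh_prev + da_r @ Ur.T
        dE[:, t, :] += dx
        dh = dh_prev
    return g


def backward(params, cache, dlogits, config: ModelConfig):
    """Gradients w.r.t. every parameter and both inputs, given dL/dlogits."""
    grads = {}
    d2, d1d, concat = cache["d2"], cache["d1d"], cache["concat"]
    grads["W3"] = d2.T @ dlogits
    grads["b3"] = dlogits.sum(axis=0)
    dd2 = (dlogits @ params["W3"].T) * (cache["a2"] > 0)
    grads["W2"] = d1d.T @ dd2
    grads["b2"] = dd2.sum(axis=0)
    dd1 = dd2 @ params["W2"].T
    if cache["mask_d1"] is not None:
        dd1 = dd1 * cache["mask_d1"]
    dd1 = dd1 * (cache["a1"] > 0)
    grads["W1"] = concat.T @ dd1
    grads["b1"] = dd1.sum(axis=0)
    dconcat = dd1 @ params["W1"].T
    h = config.hidden_size
    dh_f, dh_b, dstatic = dconcat[:, :h], dconcat[:, h : 2 * h], dconcat[:, 2 * h :]

    dE = np.zeros_like(cache["E"])
    grads.update(_gru_backward(params, cache["steps_f"], dh_f, "f", dE))
    grads.update(_gru_backward(params, cache["steps_b"], dh_b, "b", dE))

    if cache["mask_enc"] is not None:
        dE = dE * cache["mask_enc"]
    dA = dE * (cache["A_enc"] > 0)
    X = cache["X"]
    n, T, F = X.shape
    grads["Wenc"] = X.reshape(n * T, F).T @ dA.reshape(n * T, -1)
    grads["benc"] = dA.sum(axis=(0, 1))
    dX = dA @ params["Wenc"].T
    return grads, dX, dstatic


# ---------------------------------------------------------------------------
# loss


def weighted_bce(probs, labels, weights, reduce=True):
    """Weighted cross entropy over the nine events.

    loss = -(1/9) sum_e [ w_e y_e log p_e + (1-w_e)(1-y_e) log(1-p_e) ],
    averaged over the batch. The positive term is amplified (w_e > 1-w_e
    whenever the event is rarer than 50%), counteracting label imbalance.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
        raise ValueError("predictions outside (0, 1)")
    p = np.clip(p, 1e-7, 1.0 - 1e-7)  # clamped logs for numerical safety
    y = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)
    per = -(w * y * np.log(p) + (1.0 - w) * (1.0 - y) * np.log(1.0 - p)) / p.shape[-1]
    per = per.sum(axis=-1)
    return float(per.mean()) if reduce else per


def _bce_dlogits(probs, labels, weights):
    """dL/dlogits for the mean weighted BCE (sigmoid folded in)."""
    n = probs.shape[0]
    y = labels
    w = weights[None, :]
    return (-(w * y) * (1.0 - probs) + (1.0 - w) * (1.0 - y) * probs) / (
        probs.shape[1] * n
    )


# ---------------------------------------------------------------------------
# training


class EarlyStopper:
    """Stop when validation loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self._since = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record epoch (1-based); return True when training should stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self._since = 0
        else:
            self._since += 1
        return self._since >= self.patience


@dataclass
class FitState:
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    best_epoch: int = 0
    params: dict = field(default_factory=dict)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def train_with_early_stopping(
    model: "Model",
    train_data: tuple,
    val_data: tuple,
    train_config: TrainConfig,
    weights: np.ndarray,
) -> FitState:
    """Adam + minibatches + patience-based early stopping; seeded.

    ``train_data``/``val_data`` are ``(X, static, labels)`` triples on
    disjoint patients. Returns the loss curves and the parameters of the
    epoch with the lowest validation loss.
    """
    Xtr, Str, ytr = train_data
    Xval, Sval, yval = val_data
    if Xtr.shape[0] == 0 or Xval.shape[0] == 0:
        raise ValueError("training and validation subsets must be nonempty")
    rng = np.random.default_rng(train_config.seed)
    params = model.params
    opt = _Adam(params, train_config.learning_rate)
    stopper = EarlyStopper(train_config.patience)
    state = FitState()
    best_params = copy.deepcopy(params)
    n = Xtr.shape[0]
    for epoch in range(1, train_config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            probs, cache = forward(
                params, Xtr[idx], Str[idx], model.config, dropout_rng=rng
            )
            epoch_loss += weighted_bce(probs, ytr[idx], weights) * idx.size
            dlogits = _bce_dlogits(probs, ytr[idx], weights)
            grads, _, _ = backward(params, cache, dlogits, model.config)
            opt.step(params, grads)
        state.train_losses.append(epoch_loss / n)
        val_probs, _ = forward(params, Xval, Sval, model.config)
        val_loss = weighted_bce(val_probs, yval, weights)
        state.val_losses.append(val_loss)
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_params = copy.deepcopy(params)
        if stop:
            break
    state.best_epoch = stopper.best_epoch
    state.params = best_params
    model.params = best_params
    return state


def predict(model: "Model", X, static) -> np.ndarray:
    """Event probabilities with dropout disabled; deterministic."""
    if X.size and float(np.max(X[:, :, : model.config.n_features_t - 1])) > 5.0:
        warnings.warn("drug entries much larger than 1: input looks unnormalized")
    probs, _ = forward(model.params, X, static, model.config)
    return probs


def input_gradients(model: "Model", X, static):
    """(probs, dP/dX, dP/dstatic) for every output.

    Returns gradients of each predicted probability with shapes
    (n, 9, months, features) and (n, 9, 4) — the primitive the
    expected-gradients attribution integrates.
    """
    probs, cache = forward(model.params, X, static, model.config)
    n = X.shape[0]
    k = model.config.n_outputs
    gX = np.zeros((n, k) + X.shape[1:])
    gS = np.zeros((n, k, static.shape[1]))
    for e in range(k):
        dlogits = np.zeros_like(probs)
        dlogits[:, e] = probs[:, e] * (1.0 - probs[:, e])  # d sigmoid
        _, dX, dS = backward(model.params, cache, dlogits, model.config)
        gX[:, e] = dX
        gS[:, e] = dS
    return probs, gX, gS


@dataclass
class Model:
    config: ModelConfig
    params: dict

    def clone(self) -> "Model":
        return Model(config=self.config, params=copy.deepcopy(self.params))


# ---------------------------------------------------------------------------
# hyperparameter selection


def cross_validate_hidden_size(
    folds: list,
    grid: tuple = (4, 8, 16, 32),
    seed: int = 0,
    train_config: TrainConfig = None,
    config: ModelConfig = ModelConfig(),
) -> tuple[int, dict]:
    """Select the GRU hidden size by mean cross-validated AUC.

    ``folds`` is a list of ``((Xtr, Str, ytr), (Xval, Sval, yval))``; for
    each candidate h the mean-over-events validation AUC is averaged over
    folds and the argmax returned with the full score table. A fold that
    fails marks its h invalid (NaN) rather than being silently skipped.
    """
    from .evaluation import mean_auc

    if train_config is None:
        train_config = TrainConfig(seed=seed)
    table = {h: [] for h in grid}
    for h in grid:
        cfg = ModelConfig(
            n_features_t=config.n_features_t,
            n_months=config.n_months,
            encoder_dim=config.encoder_dim,
            hidden_size=h,
            dense_dims=config.dense_dims,
            n_outputs=config.n_outputs,
            dropout=config.dropout,
        )
        for i, (train_sub, val_sub) in enumerate(folds):
            try:
                model = build_model(cfg, seed=seed + i)
                weights = 1.0 - train_sub[2].mean(axis=0)
                train_with_early_stopping(model, train_sub, val_sub, train_config, weights)
                probs = predict(model, val_sub[0], val_sub[1])
                table[h].append(mean_auc(probs, val_sub[2]))
            except Exception as exc:  # fold failure -> h invalid, not skipped
                warnings.warn(f"fold {i} failed for h={h}: {exc}")
                table[h].append(float("nan"))
    means = {
        h: (float(np.mean(v)) if not np.any(np.isnan(v)) else float("nan"))
        for h, v in table.items()
    }
    valid = {h: m for h, m in means.items() if not np.isnan(m)}
    if not valid:
        raise RuntimeError("all candidate hidden sizes failed cross-validation")
    best = max(sorted(valid), key=lambda h: valid[h])
    return best, {"per_fold": table, "mean": means}
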