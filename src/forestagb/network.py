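"""Single-hidden-layer regression network trained by Levenberg-Marquardt.

The network maps a feature vector x to a scalar biomass estimate through
one tanh hidden layer and a linear output:

    o = w2 . tanh(W1 x + b1) + b2

Inputs and target are min-max normalized to [-1, 1] (statistics taken on
the training split and stored with the weights).  Training follows the
damped Gauss-Newton (Levenberg-Marquardt) scheme standard for small
regression networks: per-sample output Jacobians from backpropagation,
trial steps from (J'J + lambda*I) d = J'e, lambda shrinking on accepted
steps and growing on rejected ones, with early stopping on a validation
split.

The module also provides the 70/15/15 split protocol and the classical
hidden-size heuristics plus a trial-and-error search over sizes 5..20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MLPConfig",
    "MLPWeights",
    "SplitSpec",
    "split_dataset",
    "hidden_size_candidates",
    "init_weights",
    "forward",
    "predict_mlp",
    "train_mlp_lm",
    "hidden_size_search",
]


@dataclass
class MLPConfig:
    n_inputs: int
    hidden_size: int = 10
    max_epochs: int = 200
    lm_lambda_init: float = 1e-3
    lm_lambda_factor: float = 10.0
    lm_lambda_max: float = 1e10
    validation_patience: int = 6
    goal_mse: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.lm_lambda_init <= 0 or self.lm_lambda_factor <= 1:
            raise ValueError("LM damping parameters must be positive (factor > 1)")


@dataclass
class MLPWeights:
    """Trained parameters plus the stored normalization."""

    w1: np.ndarray  # (hidden, n_inputs)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    feature_names: list[str] | None = None

    @property
    def hidden_size(self) -> int:
        return self.w1.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[1]

    @property
    def required_features(self) -> list[str] | None:
        return self.feature_names

    def predict(self, X) -> np.ndarray:
        return predict_mlp(self, X)


@dataclass
class SplitSpec:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0


def split_dataset(n: int, ratios=(0.70, 0.15, 0.15), seed: int = 0) -> SplitSpec:
    """Random disjoint train/validation/test index sets.

    Sizes are floor(r_train*n), floor(r_val*n) and the remainder, so the
    three sets always exhaust 0..n-1.
    """
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError("ratios must sum to 1")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    return SplitSpec(
        train=np.sort(perm[:n_train]),
        val=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
        ratios=tuple(ratios),
        seed=seed,
    )


def hidden_size_candidates(
    n_inputs: int,
    n_outputs: int = 1,
    k_samples: int | None = None,
    a_range: tuple[int, int] = (0, 10),
    literal_sum: bool = False,
) -> dict:
    """Hidden-layer size suggestions from the three classical heuristics.

    * ``combinatorial``: smallest M with sum_{i=0..n} C(M, i) > k, where
      C(M, i) := 0 for i > M (needs ``k_samples``).
    * ``sqrt_range``: ceil(sqrt(n + m)) + a for a in ``a_range`` (the
      literal additive form n + m + a is available via ``literal_sum``).
    * ``log2``: ceil(log2 n).
    * ``trial_range``: the trial-and-error range 5..20 inclusive.
    """
    if n_inputs < 1 or n_outputs < 1:
        raise ValueError("layer sizes must be positive")
    out: dict = {}
    if k_samples is not None:
        m = 1
        while True:
            total = sum(math.comb(m, i) for i in range(0, n_inputs + 1) if i <= m)
            if total > k_samples:
                break
            m += 1
        out["combinatorial"] = m
    a_lo, a_hi = a_range
    if literal_sum:
        base = n_inputs + n_outputs
    else:
        base = math.ceil(math.sqrt(n_inputs + n_outputs))
    out["sqrt_range"] = list(range(base + a_lo, base + a_hi + 1))
    out["log2"] = math.ceil(math.log2(n_inputs))
    out["trial_range"] = list(range(5, 21))
    return out


# --- parameter packing -------------------------------------------------------


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(p: np.ndarray, hidden: int, n_in: int):
    i = hidden * n_in
    w1 = p[:i].reshape(hidden, n_in)
    b1 = p[i : i + hidden]
    w2 = p[i + hidden : i + 2 * hidden]
    b2 = p[i + 2 * hidden]
    return w1, b1, w2, b2


def init_weights(n_inputs: int, hidden: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded uniform init in [-0.5, 0.5], first-layer weights scaled by fan-in."""
    w1 = rng.uniform(-0.5, 0.5, (hidden, n_inputs)) / math.sqrt(n_inputs)
    b1 = rng.uniform(-0.5, 0.5, hidden)
    w2 = rng.uniform(-0.5, 0.5, hidden) / math.sqrt(hidden)
    b2 = rng.uniform(-0.5, 0.5)
    return _pack(w1, b1, w2, b2)


def forward(params: np.ndarray, Xn: np.ndarray, hidden: int):
    """Network output and hidden activations on normalized inputs."""
    w1, b1, w2, b2 = _unpack(params, hidden, Xn.shape[1])
    hid = np.tanh(Xn @ w1.T + b1)
    return hid @ w2 + b2, hid


def output_jacobian(params: np.ndarray, Xn: np.ndarray, hidden: int) -> np.ndarray:
    """Per-sample Jacobian d(output)/d(params), shape (N, P)."""
    n_in = Xn.shape[1]
    w1, b1, w2, b2 = _unpack(params, hidden, n_in)
    hid = np.tanh(Xn @ w1.T + b1)  # (N, H)
    g = (1.0 - hid**2) * w2  # (N, H)
    j_w1 = (g[:, :, None] * Xn[:, None, :]).reshape(len(Xn), hidden * n_in)
    return np.hstack([j_w1, g, hid, np.ones((len(Xn), 1))])


# --- normalization -----------------------------------------------------------


def _norm_x(X, lo, hi):
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    out = 2.0 * (X - lo) / safe - 1.0
    return np.where(span == 0, 0.0, out)


def _denorm_y(yn, lo, hi):
    if hi == lo:
        return np.full_like(np.asarray(yn, dtype=float), lo)
    return (np.asarray(yn) + 1.0) / 2.0 * (hi - lo) + lo


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"missing features {missing}")
            X = X[feature_names]
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def predict_mlp(weights: MLPWeights, X) -> np.ndarray:
    """Deterministic forward pass: normalize, evaluate, denormalize."""
    Xm, _ = _as_matrix(X, weights.feature_names)
    if Xm.ndim != 2 or Xm.shape[1] != weights.n_inputs:
        raise ValueError(
            f"expected {weights.n_inputs} features, got shape {Xm.shape}"
        )
    Xn = _norm_x(Xm, weights.x_min, weights.x_max)
    params = _pack(weights.w1, weights.b1, weights.w2, weights.b2)
    on, _ = forward(params, Xn, weights.hidden_size)
    return _denorm_y(on, weights.y_min, weights.y_max)


# --- training ----------------------------------------------------------------


def train_mlp_lm(
    X,
    y,
    config: MLPConfig,
    split: SplitSpec | None = None,
    init_params: np.ndarray | None = None,
) -> tuple[MLPWeights, pd.DataFrame]:
    """Levenberg-Marquardt training with validation early stopping.

    Each epoch attempts a damped Gauss-Newton step; the damping lambda is
    divided by ``lm_lambda_factor`` after an accepted step (training SSE
    strictly decreased) and multiplied by it until a step is accepted or
    ``lm_lambda_max`` is exceeded.  Training stops on max_epochs, damping
    overflow, the MSE goal, or ``validation_patience`` consecutive
    validation-MSE increases; the returned weights are those with the best
    validation MSE seen (training MSE when no validation split exists).

    Returns ``(weights, history)`` with one history row per epoch
    (epoch, train_mse, val_mse, lambda, accepted) on the normalized scale.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if len(Xm) != len(yv):
        raise ValueError("X and y length mismatch")
    if np.isnan(Xm).any() or np.isnan(yv).any():
        raise ValueError("missing values are not allowed")
    if split is None:
        idx = np.arange(len(yv))
        split = SplitSpec(train=idx, val=np.array([], dtype=int), test=np.array([], dtype=int))

    x_lo = Xm[split.train].min(axis=0)
    x_hi = Xm[split.train].max(axis=0)
    y_lo = float(yv[split.train].min())
    y_hi = float(yv[split.train].max())
    Xn = _norm_x(Xm, x_lo, x_hi)
    yn = np.zeros_like(yv) if y_hi == y_lo else 2.0 * (yv - y_lo) / (y_hi - y_lo) - 1.0

    h = config.hidden_size
    rng = np.random.default_rng(config.seed)
    params = init_weights(Xm.shape[1], h, rng) if init_params is None else init_params.copy()

    tr, va = split.train, split.val
    lam = config.lm_lambda_init

    def mse(p, idx):
        o, _ = forward(p, Xn[idx], h)
        return float(np.mean((yn[idx] - o) ** 2)) if len(idx) else float("nan")

    best_params = params.copy()
    best_val = mse(params, va) if len(va) else mse(params, tr)
    prev_val = best_val
    val_fails = 0
    hist = []
    stop = None
    for epoch in range(1, config.max_epochs + 1):
        o, _ = forward(params, Xn[tr], h)
        e = yn[tr] - o
        sse = float(e @ e)
        J = output_jacobian(params, Xn[tr], h)
        JtJ = J.T @ J
        Jte = J.T @ e
        accepted = False
        while lam <= config.lm_lambda_max:
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(len(params)), Jte)
            except np.linalg.LinAlgError:
                lam *= config.lm_lambda_factor
                continue
            trial = params + delta
            o_t, _ = forward(trial, Xn[tr], h)
            e_t = yn[tr] - o_t
            if float(e_t @ e_t) < sse:
                params = trial
                lam = max(lam / config.lm_lambda_factor, 1e-20)
                accepted = True
                break
            lam *= config.lm_lambda_factor
        train_mse = mse(params, tr)
        val_mse = mse(params, va) if len(va) else float("nan")
        hist.append(
            {
                "epoch": epoch,
                "train_mse": train_mse,
                "val_mse": val_mse,
                "lambda": lam,
                "accepted": accepted,
            }
        )
        if not accepted:
            stop = "lambda-overflow"
            break
        score = val_mse if len(va) else train_mse
        if score < best_val:
            best_val = score
            best_params = params.copy()
        if len(va):
            if val_mse > prev_val:
                val_fails += 1
            else:
                val_fails = 0
            prev_val = val_mse
            if val_fails >= config.validation_patience:
                stop = "early-stopping"
                break
        if train_mse <= config.goal_mse:
            stop = "goal"
            break
    history = pd.DataFrame(hist)
    history.attrs["stop_reason"] = stop or "max-epochs"

    w1, b1, w2, b2 = _unpack(best_params, h, Xm.shape[1])
    weights = MLPWeights(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        x_min=x_lo,
        x_max=x_hi,
        y_min=y_lo,
        y_max=y_hi,
        feature_names=names,
    )
    return weights, history


def hidden_size_search(
    X,
    y,
    split: SplitSpec,
    sizes=range(5, 21),
    seeds=(0,),
    **config_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Trial-and-error hidden-size selection over ``sizes``.

    Each size is trained once per seed; the score is the mean best
    validation MSE over seeds.  The smallest size wins ties.  Returns
    ``(best_size, table)`` where the table has one row per size.
    """
    Xm, _ = _as_matrix(X)
    rows = []
    for size in sizes:
        scores = []
        for s in seeds:
            cfg = MLPConfig(n_inputs=Xm.shape[1], hidden_size=size, seed=s, **config_kwargs)
            _, hist = train_mlp_lm(X, y, cfg, split)
            col = "val_mse" if len(split.val) else "train_mse"
            scores.append(float(np.nanmin(hist[col])))
        rows.append({"hidden_size": size, "val_mse": float(np.mean(scores))})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["val_mse"].idxmin(), "hidden_size"])
    return best, table
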