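"""Particle swarm optimization and the PSO-trained biomass network.

Canonical global-best PSO: a swarm of N particles with positions x and
velocities v explores the search space; each particle remembers its best
visited position (pbest) and the swarm shares the overall best (gbest).
Per iteration

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    x <- x + v

with componentwise random r1, r2 ~ U(0,1), a componentwise velocity clamp
and optional position bounds.  The inertia weight w decreases linearly
over the run (0.9 -> 0.4 by default), the acceleration constants default
to the constriction-equivalent 1.49445, and the loop terminates on the
iteration budget or when gbest fitness reaches a tolerance.

:func:`pso_train_mlp` couples the optimizer to the single-hidden-layer
network: a particle is a flattened weight vector, fitness is training-set
MSE on the normalized scale, and by default the swarm optimum is polished
with Levenberg-Marquardt fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    MLPConfig,
    MLPWeights,
    SplitSpec,
    _as_matrix,
    _norm_x,
    _pack,
    _unpack,
    forward,
    train_mlp_lm,
)

__all__ = ["PSOConfig", "pso_minimize", "pso_train_mlp"]


@dataclass
class PSOConfig:
    swarm_size: int = 30
    max_iterations: int = 200
    w_start: float = 0.9
    w_end: float = 0.4
    c1: float = 1.49445
    c2: float = 1.49445
    velocity_clamp: float = 1.0
    position_bounds: tuple[float, float] = (-5.0, 5.0)
    fitness_tolerance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration constants must be >= 0")
        if self.velocity_clamp <= 0:
            raise ValueError("velocity_clamp must be > 0")


def pso_minimize(fitness, dim: int, config: PSOConfig):
    """Minimize ``fitness`` (vector -> scalar) over R^dim.

    Returns ``(gbest position, gbest fitness, history)`` where history is a
    DataFrame (iteration, gbest_fitness); the gbest trace is non-increasing
    by construction.  Iteration 0 records the random initialization, so a
    ``max_iterations=0`` run returns the best of the initial swarm.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.position_bounds
    n = config.swarm_size
    x = rng.uniform(lo, hi, (n, dim))
    v = rng.uniform(-config.velocity_clamp, config.velocity_clamp, (n, dim))

    def evaluate(positions):
        return np.array([float(fitness(p)) for p in positions])

    f = evaluate(x)
    if not np.all(np.isfinite(f)):
        raise ValueError("fitness must be finite on the initialization region")
    pbest = x.copy()
    pbest_f = f.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    hist = [{"iteration": 0, "gbest_fitness": gbest_f}]

    for it in range(1, config.max_iterations + 1):
        if gbest_f <= config.fitness_tolerance:
            break
        frac = it / max(config.max_iterations, 1)
        w = config.w_start + (config.w_end - config.w_start) * frac
        r1 = rng.uniform(size=(n, dim))
        r2 = rng.uniform(size=(n, dim))
        v = w * v + config.c1 * r1 * (pbest - x) + config.c2 * r2 * (gbest - x)
        np.clip(v, -config.velocity_clamp, config.velocity_clamp, out=v)
        x = np.clip(x + v, lo, hi)
        f = evaluate(x)
        improved = f < pbest_f
        pbest[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        hist.append({"iteration": it, "gbest_fitness": gbest_f})
    return gbest, gbest_f, pd.DataFrame(hist)


def pso_train_mlp(
    X,
    y,
    mlp_config: MLPConfig,
    pso_config: PSOConfig,
    split: SplitSpec | None = None,
    fine_tune: bool = True,
) -> tuple[MLPWeights, pd.DataFrame]:
    """Train the biomass network by PSO over its flattened weight vector.

    Fitness is training-split MSE on the normalized scale (the validation
    split is reserved for the fine-tuner's early stopping, avoiding
    leakage).  With ``fine_tune=True`` (default) the swarm optimum seeds a
    Levenberg-Marquardt polish; otherwise the gbest weights are returned
    as-is.  Returns ``(weights, history)`` with the PSO gbest trace (and
    the fine-tune epochs appended when enabled).
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if split is None:
        idx = np.arange(len(yv))
        split = SplitSpec(train=idx, val=np.array([], dtype=int), test=np.array([], dtype=int))
    x_lo = Xm[split.train].min(axis=0)
    x_hi = Xm[split.train].max(axis=0)
    y_lo = float(yv[split.train].min())
    y_hi = float(yv[split.train].max())
    Xn = _norm_x(Xm, x_lo, x_hi)
    yn = np.zeros_like(yv) if y_hi == y_lo else 2.0 * (yv - y_lo) / (y_hi - y_lo) - 1.0
    tr = split.train
    h = mlp_config.hidden_size
    dim = h * Xm.shape[1] + 2 * h + 1

    def fitness(p):
        o, _ = forward(p, Xn[tr], h)
        return float(np.mean((yn[tr] - o) ** 2))

    gbest, gbest_f, hist = pso_minimize(fitness, dim, pso_config)
    hist = hist.assign(phase="pso")

    if fine_tune:
        weights, lm_hist = train_mlp_lm(X, y, mlp_config, split, init_params=gbest)
        lm_hist = lm_hist.rename(columns={"epoch": "iteration", "train_mse": "gbest_fitness"})
        lm_hist = lm_hist[["iteration", "gbest_fitness"]].assign(phase="lm")
        history = pd.concat([hist, lm_hist], ignore_index=True)
        if names is not None and weights.feature_names is None:
            weights.feature_names = names
        return weights, history

    w1, b1, w2, b2 = _unpack(gbest, h, Xm.shape[1])
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
    return weights, hist
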