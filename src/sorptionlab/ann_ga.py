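"""Feed-forward ANN surrogate and genetic-algorithm process optimization.

A single-hidden-layer network (4 inputs, tanh hidden units, linear output)
is trained by Levenberg-Marquardt on min-max scaled data with a 70/15/15
train/validation/test split, the hidden-layer width chosen by a 1..14 neuron
scan on validation MSE. A real-coded genetic algorithm (tournament
selection, blend crossover, Gaussian mutation, elitism) then maximizes the
trained surrogate's predicted removal over the process-variable box.

The GA here searches the process space over a fixed trained network; an
optional GA-seeded weight initialization (``train_lm(..., ga_init=True)``)
is provided for the alternative reading in which the GA tunes weights before
gradient refinement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "AnnModel",
    "TrainReport",
    "GaConfig",
    "forward",
    "train_lm",
    "scan_hidden_neurons",
    "ga_optimize",
    "optimize_process_conditions",
]

N_INPUT = 4


@dataclass
class AnnModel:
    """4:nHidden:1 network with tanh hidden layer and linear output.

    Inputs and the response are min-max scaled to [-1, 1]; ``forward``
    applies the scaling, so predictions are in original response units.
    """

    w1: np.ndarray  # (nHidden, 4)
    b1: np.ndarray  # (nHidden,)
    w2: np.ndarray  # (nHidden,)
    b2: float
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    seed: Optional[int] = None

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[0]

    @property
    def n_params(self) -> int:
        return self.n_hidden * (N_INPUT + 2) + 1

    def scale_x(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.x_max > self.x_min, self.x_max - self.x_min, 1.0)
        return 2.0 * (x - self.x_min) / span - 1.0

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        span = self.y_max - self.y_min if self.y_max > self.y_min else 1.0
        return 2.0 * (y - self.y_min) / span - 1.0

    def unscale_y(self, sy: np.ndarray) -> np.ndarray:
        span = self.y_max - self.y_min if self.y_max > self.y_min else 1.0
        return (sy + 1.0) / 2.0 * span + self.y_min

    def predict(self, x) -> np.ndarray | float:
        return forward(self, x)

    def to_dict(self) -> dict:
        return {
            "topology": [N_INPUT, self.n_hidden, 1],
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "AnnModel":
        return cls(
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            x_min=np.asarray(d["x_min"], dtype=float),
            x_max=np.asarray(d["x_max"], dtype=float),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
            seed=d.get("seed"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "AnnModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainReport:
    mse: dict[str, float]  # train/validation/test, original response units
    r2: dict[str, float]
    epochs: int
    split: dict[str, np.ndarray]  # row indices per subset


@dataclass
class GaConfig:
    """Real-coded GA settings."""

    bounds: Sequence[tuple[float, float]] = ()
    population_size: int = 60
    generations: int = 120
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15
    mutation_scale: float = 0.1  # std of Gaussian mutation, fraction of gene range
    tournament_size: int = 3
    elitism: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population must be >= 4")
        for r in (self.crossover_rate, self.mutation_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


def forward(model: AnnModel, x) -> np.ndarray | float:
    """Network prediction in original response units.

    Points outside the fitted scaling range trigger an extrapolation warning,
    not an error.
    """
    x_arr = np.atleast_2d(np.asarray(x, dtype=float))
    if x_arr.shape[1] != N_INPUT:
        raise ValueError(f"expected {N_INPUT} inputs, got {x_arr.shape[1]}")
    if np.any(x_arr < model.x_min - 1e-12) or np.any(x_arr > model.x_max + 1e-12):
        warnings.warn("input outside the fitted scaling range: extrapolating")
    sx = model.scale_x(x_arr)
    hidden = np.tanh(sx @ model.w1.T + model.b1)
    sy = hidden @ model.w2 + model.b2
    out = model.unscale_y(sy)
    return float(out[0]) if np.ndim(x) == 1 else out


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta: np.ndarray, n_hidden: int):
    k = n_hidden * N_INPUT
    w1 = theta[:k].reshape(n_hidden, N_INPUT)
    b1 = theta[k : k + n_hidden]
    w2 = theta[k + n_hidden : k + 2 * n_hidden]
    b2 = float(theta[-1])
    return w1, b1, w2, b2


def _net_and_jacobian(theta: np.ndarray, sx: np.ndarray, n_hidden: int):
    """Scaled-space predictions and analytic Jacobian d(pred)/d(theta)."""
    w1, b1, w2, b2 = _unpack(theta, n_hidden)
    act = np.tanh(sx @ w1.T + b1)  # (n, H)
    pred = act @ w2 + b2
    dtanh = 1.0 - act ** 2  # (n, H)
    n = sx.shape[0]
    jac = np.empty((n, theta.size))
    # d/dW1[h, j] = w2[h] * dtanh[:, h] * sx[:, j]
    jw1 = (w2 * dtanh)[:, :, None] * sx[:, None, :]  # (n, H, 4)
    jac[:, : n_hidden * N_INPUT] = jw1.reshape(n, -1)
    jac[:, n_hidden * N_INPUT : n_hidden * (N_INPUT + 1)] = w2 * dtanh
    jac[:, n_hidden * (N_INPUT + 1) : -1] = act
    jac[:, -1] = 1.0
    return pred, jac


def _init_weights(rng: np.random.Generator, n_hidden: int) -> np.ndarray:
    """Nguyen-Widrow initialization for tanh hidden units on [-1,1] inputs."""
    scale = 0.7 * n_hidden ** (1.0 / N_INPUT)
    w1 = rng.uniform(-1.0, 1.0, size=(n_hidden, N_INPUT))
    w1 *= scale / np.linalg.norm(w1, axis=1, keepdims=True)
    b1 = scale * np.linspace(-1.0, 1.0, n_hidden) * np.sign(rng.uniform(-1.0, 1.0, n_hidden))
    w2 = rng.uniform(-0.5, 0.5, size=n_hidden)
    b2 = 0.0
    return _pack(w1, b1, w2, b2)


def _split_indices(n: int, rng: np.random.Generator):
    """70/15/15 split, rounding toward the training set."""
    perm = rng.permutation(n)
    n_val = int(np.floor(0.15 * n))
    n_test = int(np.floor(0.15 * n))
    n_train = n - n_val - n_test
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def train_lm(
    X: Sequence[Sequence[float]],
    y: Sequence[float],
    n_hidden: int = 8,
    epochs_max: int = 1000,
    seed: int = 0,
    patience: int = 6,
    lambda_init: float = 1e-3,
    ga_init: bool = False,
    ga_cfg: Optional[GaConfig] = None,
) -> tuple[AnnModel, TrainReport]:
    """Levenberg-Marquardt training with validation-based early stopping.

    Minimizes training MSE in scaled space; damping is multiplied by 10 on a
    rejected step and divided by 10 on acceptance. Training stops after
    ``patience`` consecutive epochs without a validation improvement, and the
    best-validation weights are returned. ``ga_init=True`` seeds the initial
    weights with a short GA search over weight space instead of random
    initialization.
    """
    if not (1 <= n_hidden <= 64):
        raise ValueError("n_hidden must be in 1..64")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    idx_train, idx_val, idx_test = _split_indices(n, rng)

    model = AnnModel(
        w1=np.zeros((n_hidden, N_INPUT)),
        b1=np.zeros(n_hidden),
        w2=np.zeros(n_hidden),
        b2=0.0,
        x_min=X.min(axis=0),
        x_max=X.max(axis=0),
        y_min=float(y.min()),
        y_max=float(y.max()),
        seed=seed,
    )
    n_params = model.n_params
    if len(idx_train) < n_params / 2:
        warnings.warn(
            f"only {len(idx_train)} training rows for {n_params} weights; fit may be unstable"
        )
    sx = model.scale_x(X)
    sy = model.scale_y(y)
    sx_tr, sy_tr = sx[idx_train], sy[idx_train]
    sx_val, sy_val = sx[idx_val], sy[idx_val]

    theta = _init_weights(rng, n_hidden)
    if ga_init:
        cfg = ga_cfg or GaConfig(
            bounds=[(-3.0, 3.0)] * n_params, population_size=40, generations=30,
            seed=int(rng.integers(2 ** 31 - 1)),
        )

        def weight_fitness(t: np.ndarray) -> float:
            pred, _ = _net_and_jacobian(t, sx_tr, n_hidden)
            return -float(np.mean((pred - sy_tr) ** 2))

        theta, _ = ga_optimize(weight_fitness, cfg)

    def val_mse(t: np.ndarray) -> float:
        if len(idx_val) == 0:
            return np.nan
        pred, _ = _net_and_jacobian(t, sx_val, n_hidden)
        return float(np.mean((pred - sy_val) ** 2))

    pred, jac = _net_and_jacobian(theta, sx_tr, n_hidden)
    resid = pred - sy_tr
    sse = float(resid @ resid)
    lam = lambda_init
    prev_val = val_mse(theta)
    best_theta, best_val = theta.copy(), prev_val
    consecutive_increases = 0
    epoch = 0
    while epoch < epochs_max:
        jtj = jac.T @ jac
        jtr = jac.T @ resid
        accepted = False
        while lam <= 1e12:
            damped = jtj + lam * np.diag(np.maximum(np.diag(jtj), 1e-12))
            try:
                step = np.linalg.solve(damped, -jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = theta + step
            cand_pred, cand_jac = _net_and_jacobian(cand, sx_tr, n_hidden)
            cand_resid = cand_pred - sy_tr
            cand_sse = float(cand_resid @ cand_resid)
            if cand_sse < sse:
                theta, pred, jac, resid, sse = cand, cand_pred, cand_jac, cand_resid, cand_sse
                lam = max(lam / 10.0, 1e-15)
                accepted = True
                break
            lam *= 10.0
        epoch += 1
        if not accepted:
            break  # damping exhausted: local minimum reached
        vm = val_mse(theta)
        if len(idx_val) > 0:
            if np.isnan(best_val) or vm < best_val:
                best_val, best_theta = vm, theta.copy()
            # patience counts consecutive epoch-over-epoch increases only;
            # any decrease (even above the running best) resets the counter
            if vm > prev_val:
                consecutive_increases += 1
                if consecutive_increases >= patience:
                    break
            else:
                consecutive_increases = 0
            prev_val = vm
        else:
            best_theta = theta.copy()
        if sse < 1e-24:
            best_theta = theta.copy() if len(idx_val) == 0 or vm <= best_val else best_theta
            break

    final = best_theta if len(idx_val) > 0 else theta
    model.w1, model.b1, model.w2, model.b2 = _unpack(final, n_hidden)

    mse, r2 = {}, {}
    for label, idx in (("train", idx_train), ("validation", idx_val), ("test", idx_test)):
        if len(idx) == 0:
            mse[label], r2[label] = np.nan, np.nan
            continue
        yhat = forward(model, X[idx])
        err = yhat - y[idx]
        mse[label] = float(np.mean(err ** 2))
        ss_tot = float(np.sum((y[idx] - y[idx].mean()) ** 2))
        r2[label] = 1.0 - float(err @ err) / ss_tot if ss_tot > 0 else np.nan
    report = TrainReport(
        mse=mse, r2=r2, epochs=epoch,
        split={"train": idx_train, "validation": idx_val, "test": idx_test},
    )
    return model, report


def scan_hidden_neurons(
    X: Sequence[Sequence[float]],
    y: Sequence[float],
    candidates: Sequence[int] = tuple(range(1, 15)),
    seed: int = 0,
    epochs_max: int = 300,
    tie_tol: float = 1e-8,
) -> tuple[int, dict[int, dict[str, float]]]:
    """Hidden-layer width selection by validation MSE.

    Every candidate is trained with the identical seed (hence identical
    split); the winner is the smallest width whose validation MSE is within
    ``tie_tol`` of the minimum.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    table: dict[int, dict[str, float]] = {}
    for n_h in candidates:
        _, report = train_lm(X, y, n_hidden=n_h, epochs_max=epochs_max, seed=seed)
        key = "validation" if not np.isnan(report.mse["validation"]) else "train"
        table[n_h] = {
            "mse_train": report.mse["train"],
            "mse_validation": report.mse["validation"],
            "mse_selection": report.mse[key],
            "r2_train": report.r2["train"],
            "epochs": report.epochs,
        }
    best_mse = min(row["mse_selection"] for row in table.values())
    best_n = min(n for n, row in table.items() if row["mse_selection"] <= best_mse + tie_tol)
    return best_n, table


def ga_optimize(
    fitness: Callable[[np.ndarray], float], cfg: GaConfig
) -> tuple[np.ndarray, float]:
    """Maximize a fitness function over a box by a real-coded GA.

    Tournament selection, per-gene blend (arithmetic) crossover, Gaussian
    mutation clipped to bounds, and elitism; returns the best individual ever
    evaluated. Deterministic for a fixed ``cfg.seed``.
    """
    bounds = np.asarray(cfg.bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("cfg.bounds must be a sequence of (lo, hi) pairs")
    if not np.all(np.isfinite(bounds)):
        raise ValueError("GA requires finite bounds")
    lo, hi = bounds[:, 0], bounds[:, 1]
    dim = len(bounds)
    rng = np.random.default_rng(cfg.seed)

    pop = rng.uniform(lo, hi, size=(cfg.population_size, dim))
    fit = np.array([fitness(ind) for ind in pop])
    best_i = int(np.argmax(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])

    for _ in range(cfg.generations):
        order = np.argsort(fit)[::-1]
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                parents.append(pop[contenders[np.argmax(fit[contenders])]])
            p1, p2 = parents
            if rng.random() < cfg.crossover_rate:
                u = rng.random(dim)
                child = u * p1 + (1.0 - u) * p2
            else:
                child = p1.copy()
            mutate = rng.random(dim) < cfg.mutation_rate
            noise = rng.normal(0.0, cfg.mutation_scale * (hi - lo))
            child = np.where(mutate, child + noise, child)
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        fit = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_f:
            best_x, best_f = pop[gen_best].copy(), float(fit[gen_best])
    return best_x, best_f


def optimize_process_conditions(
    model: AnnModel,
    bounds: Sequence[tuple[float, float]],
    cfg: Optional[GaConfig] = None,
) -> tuple[np.ndarray, float]:
    """GA maximization of the trained surrogate over the process box."""
    cfg = cfg or GaConfig()
    cfg = GaConfig(
        bounds=list(bounds),
        population_size=cfg.population_size,
        generations=cfg.generations,
        crossover_rate=cfg.crossover_rate,
        mutation_rate=cfg.mutation_rate,
        mutation_scale=cfg.mutation_scale,
        tournament_size=cfg.tournament_size,
        elitism=cfg.elitism,
        seed=cfg.seed,
    )

    def fit_fn(x: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(forward(model, x))

    return ga_optimize(fit_fn, cfg)
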