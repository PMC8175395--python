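"""Parameter estimation and the five-metric goodness-of-fit suite.

Two estimation routes for every registered model:

* ``linear_fit`` — ordinary least squares on the model's classical
  linearizing transform, parameters back-mapped, metrics recomputed on the
  original (untransformed) scale;
* ``de_fit`` — differential evolution (rand/1/bin, seeded) minimizing the
  original-scale sum of squared errors directly within parameter bounds.

Both report the same metric suite: R^2, RMSE (with n-1 in the denominator),
SAE, SSE and ARE, so linear and nonlinear estimates are comparable on one
scale. ``compare_methods`` assembles the side-by-side table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .models import (
    ModelDef,
    get_model,
    isotherm_conditional_linearization,
    isotherm_linearize,
    kinetic_linearize,
)

__all__ = [
    "Metrics",
    "FitResult",
    "DeConfig",
    "compute_metrics",
    "de_fit",
    "linear_fit",
    "compare_methods",
]


@dataclass(frozen=True)
class Metrics:
    """Goodness-of-fit suite evaluated on the original response scale.

    RMSE uses n-1 in the denominator (sample convention of the source field);
    ARE divides by the observation count by default. ``are`` is None when any
    observation is zero (relative error undefined).
    """

    r2: float
    rmse: float
    sae: float
    sse: float
    are: Optional[float]
    n: int
    p: int


@dataclass
class DeConfig:
    """Differential-evolution settings (rand/1/bin, seeded)."""

    popsize: int = 15  # population multiplier per free dimension
    mutation: float = 0.7
    recombination: float = 0.9
    maxiter: int = 2000
    tol: float = 1e-10
    seed: int = 0
    polish: bool = True
    restarts: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.recombination <= 1.0):
            raise ValueError("recombination must lie in (0, 1]")
        if self.popsize < 4:
            raise ValueError("population multiplier must be >= 4")
        if self.restarts < 1:
            raise ValueError("need at least one DE run")


@dataclass
class FitResult:
    model_name: str
    method: str  # "linear" | "nonlinear-DE"
    params: dict[str, float]
    metrics: Metrics
    iterations: Optional[int] = None
    seed: Optional[int] = None
    population_spread: Optional[float] = None
    notes: list[str] = field(default_factory=list)


def compute_metrics(
    observed: Sequence[float],
    predicted: Sequence[float],
    p: int,
    are_divisor: str = "n",
    r2_as_printed: bool = False,
) -> Metrics:
    """Five-metric suite comparing predictions to observations.

    SAE = sum |pred-obs|; SSE = sum (pred-obs)^2; RMSE = sqrt(SSE/(n-1));
    ARE = (100/n) * sum |pred-obs|/obs (``are_divisor='p'`` divides by the
    parameter count instead); R^2 = 1 - SSE / sum (obs-mean)^2.
    ``r2_as_printed=True`` returns the literal error-over-spread ratio
    sum (pred-obs)^2 / sum (pred-mean_obs)^2 for audit.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    resid = pred - obs
    sse = float(resid @ resid)
    sae = float(np.abs(resid).sum())
    rmse = float(np.sqrt(sse / (n - 1)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations are all equal: R^2 undefined")
    if r2_as_printed:
        denom = float(np.sum((pred - obs.mean()) ** 2))
        r2 = sse / denom if denom > 0 else np.inf
    else:
        r2 = 1.0 - sse / ss_tot
    if np.any(obs == 0):
        warnings.warn("observations contain zeros: ARE reported as missing")
        are = None
    else:
        divisor = n if are_divisor == "n" else p
        are = float(100.0 / divisor * np.sum(np.abs(resid) / np.abs(obs)))
    return Metrics(r2=float(r2), rmse=rmse, sae=sae, sse=sse, are=are, n=n, p=p)


def _resolve_bounds(
    mdef: ModelDef, bounds: Optional[Sequence[tuple[float, float]]]
) -> list[tuple[float, float]]:
    if bounds is None:
        return list(mdef.bounds)
    bounds = list(bounds)
    if len(bounds) != len(mdef.param_names):
        raise ValueError(f"{mdef.name}: expected {len(mdef.param_names)} bound pairs")
    return bounds


def de_fit(
    model: str,
    x: Sequence[float],
    y: Sequence[float],
    cfg: Optional[DeConfig] = None,
    bounds: Optional[Sequence[tuple[float, float]]] = None,
    are_divisor: str = "n",
) -> FitResult:
    """Nonlinear least squares by differential evolution.

    Minimizes original-scale SSE of the named model over its parameter box.
    Runs ``cfg.restarts`` independent DE searches with seeds derived from
    ``cfg.seed`` and keeps the lowest-SSE result: a single population can
    stagnate on the saturation plateau that every rate law exhibits when its
    rate constant is large. Deterministic for a fixed ``cfg.seed``.
    """
    mdef = get_model(model)
    cfg = cfg or DeConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < len(mdef.param_names) + 1:
        raise ValueError(
            f"{mdef.name}: need at least {len(mdef.param_names) + 1} points"
        )
    box = _resolve_bounds(mdef, bounds)
    if not all(np.isfinite(lo) and np.isfinite(hi) for lo, hi in box):
        raise ValueError("DE requires finite bounds")

    def objective(theta: np.ndarray) -> float:
        with np.errstate(all="ignore"):
            pred = mdef.predict(theta, x)
            sse = float(np.sum((pred - y) ** 2))
        return sse if np.isfinite(sse) else 1e300

    dim = len(box)
    n_pop = cfg.popsize * dim
    log_lo = np.log([max(b[0], 1e-300) for b in box])
    log_hi = np.log([b[1] for b in box])
    run_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.restarts) % (2**31 - 1)

    result = None
    for run_seed in run_seeds:
        # rate/affinity parameters span many decades within their bounds, so
        # the initial population is sampled log-uniformly (every parameter
        # here is strictly positive); a uniform draw would start ~99.9 % of
        # members on saturation plateaus of the objective
        rng_init = np.random.default_rng(int(run_seed))
        init_pop = np.exp(rng_init.uniform(log_lo, log_hi, size=(n_pop, dim)))
        res = differential_evolution(
            objective,
            bounds=box,
            strategy="rand1bin",
            popsize=cfg.popsize,
            mutation=cfg.mutation,
            recombination=cfg.recombination,
            maxiter=cfg.maxiter,
            tol=cfg.tol,
            seed=int(run_seed),
            polish=cfg.polish,
            init=init_pop,
        )
        if result is None or res.fun < result.fun:
            result = res
    if not np.isfinite(result.fun) or result.fun >= 1e300:
        raise ValueError(
            f"{mdef.name}: objective non-finite across the population; check bounds"
        )
    theta = np.clip(result.x, [b[0] for b in box], [b[1] for b in box])
    pred = mdef.predict(theta, x)
    metrics = compute_metrics(y, pred, p=len(theta), are_divisor=are_divisor)
    spread = float(np.std(result.population_energies)) if hasattr(result, "population_energies") else None
    return FitResult(
        model_name=mdef.name,
        method="nonlinear-DE",
        params=dict(zip(mdef.param_names, map(float, theta))),
        metrics=metrics,
        iterations=int(result.nit),
        seed=cfg.seed,
        population_spread=spread,
    )


def _ols_line(u: np.ndarray, v: np.ndarray, through_origin: bool) -> tuple[float, float]:
    if through_origin:
        return float(np.sum(u * v) / np.sum(u * u)), 0.0
    a = np.column_stack([u, np.ones_like(u)])
    (slope, icept), *_ = np.linalg.lstsq(a, v, rcond=None)
    return float(slope), float(icept)


#: grid used for the exponent scan of 3-parameter isotherm linearizations
EXPONENT_GRID = np.round(np.arange(0.05, 2.0001, 0.005), 4)


def linear_fit(
    model: str,
    x: Sequence[float],
    y: Sequence[float],
    qe_exp: Optional[float] = None,
    are_divisor: str = "n",
) -> FitResult:
    """Least squares on the model's linearizing transform.

    Parameters are back-mapped from the straight line and metrics are
    recomputed on the original scale. Three-parameter isotherms use an
    iterated linearization (exponent scanned on a grid, original-scale SSE
    decides); the result is flagged approximate. PFO/Boyd need ``qe_exp``.
    """
    mdef = get_model(model)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    notes: list[str] = []

    if mdef.kind == "isotherm" and not mdef.exact_linearization:
        best = None
        for expo in EXPONENT_GRID:
            lin = isotherm_conditional_linearization(mdef.name, x, y, float(expo))
            slope, icept = _ols_line(lin.u, lin.v, lin.through_origin)
            if slope <= 0 or (not lin.through_origin and icept <= 0):
                continue  # unphysical back-map for this exponent
            params = lin.back_map(slope, icept)
            if any(v <= 0 for v in params.values()):
                continue
            theta = np.array([params[p] for p in mdef.param_names])
            with np.errstate(all="ignore"):
                pred = mdef.predict(theta, x)
                sse = float(np.sum((pred - y) ** 2))
            if np.isfinite(sse) and (best is None or sse < best[0]):
                best = (sse, params, lin.n_dropped)
        if best is None:
            raise ValueError(f"{mdef.name}: exponent-grid linearization found no valid line")
        _, params, n_dropped = best
        notes.append("approximate: iterated linearization with exponent on a grid")
    else:
        if mdef.kind == "isotherm":
            lin = isotherm_linearize(mdef.name, x, y)
        else:
            lin = kinetic_linearize(mdef.name, x, y, qe_exp=qe_exp)
        slope, icept = _ols_line(lin.u, lin.v, lin.through_origin)
        params = lin.back_map(slope, icept)
        n_dropped = lin.n_dropped
    if n_dropped:
        notes.append(f"dropped {n_dropped} rows in transform space")
    theta = np.array([params[p] for p in mdef.param_names])
    pred = mdef.predict(theta, x)
    metrics = compute_metrics(y, pred, p=len(theta), are_divisor=are_divisor)
    return FitResult(
        model_name=mdef.name,
        method="linear",
        params={k: float(v) for k, v in params.items()},
        metrics=metrics,
        notes=notes,
    )


def compare_methods(
    models: Sequence[str],
    x: Sequence[float],
    y: Sequence[float],
    cfg: Optional[DeConfig] = None,
    qe_exp: Optional[float] = None,
) -> pd.DataFrame:
    """Linear vs nonlinear-DE comparison table for a list of models.

    One row per (model, method) with back-mapped parameters and the five
    metrics; per-model failures are recorded in an ``error`` column instead
    of aborting the whole table.
    """
    if not models:
        raise ValueError("need at least one model")
    rows = []
    for name in models:
        mdef = get_model(name)
        for method in ("linear", "nonlinear-DE"):
            row: dict[str, object] = {"model": mdef.name, "method": method}
            try:
                if method == "linear":
                    fit = linear_fit(name, x, y, qe_exp=qe_exp)
                else:
                    fit = de_fit(name, x, y, cfg=cfg)
                row["params"] = "; ".join(f"{k}={v:.6g}" for k, v in fit.params.items())
                row.update(
                    R2=fit.metrics.r2,
                    SAE=fit.metrics.sae,
                    SSE=fit.metrics.sse,
                    ARE=fit.metrics.are,
                    RMSE=fit.metrics.rmse,
                )
            except (ValueError, KeyError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
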