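"""Central composite design and second-order response-surface modelling.

A four-factor rotatable CCD (2^4 factorial + 8 axial + center replicates)
supports a full quadratic model of removal efficiency in pH, contact time,
initial concentration and adsorbent dosage. The module fits that quadratic by
ordinary least squares, decomposes it by ANOVA (partial SS, lack-of-fit from
center replicates), ranks term importance by squared-coefficient (Pareto)
shares, and maximizes the quadratic exactly over a box by stationary-point
plus facet enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FactorSpace",
    "CCDDesign",
    "QuadraticModel",
    "AnovaTable",
    "DEFAULT_FACTOR_SPACE",
    "PUBLISHED_QUADRATIC",
    "build_ccd",
    "expand_quadratic",
    "fit_quadratic",
    "predict_quadratic",
    "anova",
    "pareto_effects",
    "optimize_quadratic",
]

N_FACTORS = 4

#: column labels of the 15-term full quadratic expansion, in fit order
TERM_NAMES = (
    "intercept",
    "X1", "X2", "X3", "X4",
    "X1X2", "X1X3", "X1X4", "X2X3", "X2X4", "X3X4",
    "X1^2", "X2^2", "X3^2", "X4^2",
)

_PAIRS = tuple(itertools.combinations(range(N_FACTORS), 2))


@dataclass(frozen=True)
class FactorSpace:
    """Actual-unit geometry of the four process factors.

    ``center + step * coded`` maps coded levels {-alpha,-1,0,+1,+alpha}
    to actual units.
    """

    names: tuple[str, str, str, str] = ("pH", "contactTime", "initialConcentration", "dosage")
    center: tuple[float, ...] = (7.0, 20.0, 6.0, 2.2)
    step: tuple[float, ...] = (2.0, 5.0, 2.0, 0.9)
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if len(self.names) != N_FACTORS or len(self.center) != N_FACTORS or len(self.step) != N_FACTORS:
            raise ValueError("FactorSpace requires exactly 4 factors")
        if any(s <= 0 for s in self.step):
            raise ValueError("factor steps must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def to_actual(self, coded: np.ndarray) -> np.ndarray:
        return np.asarray(self.center) + np.asarray(self.step) * np.asarray(coded)

    def to_coded(self, actual: np.ndarray) -> np.ndarray:
        return (np.asarray(actual) - np.asarray(self.center)) / np.asarray(self.step)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        """Actual-unit box spanned by the axial levels (+-alpha)."""
        return [
            (c - self.alpha * s, c + self.alpha * s)
            for c, s in zip(self.center, self.step)
        ]


#: Factor geometry used throughout: five coded levels per factor with
#: rotatable alpha = (2^4)^(1/4) = 2. Actual ranges: pH 3-11, time 10-30 min,
#: concentration 2-10 mg/L, dosage 0.4-4 g/L.
DEFAULT_FACTOR_SPACE = FactorSpace()


@dataclass(frozen=True)
class CCDDesign:
    runs: np.ndarray  # (n, 4) coded
    actuals: np.ndarray  # (n, 4) actual units
    nCenter: int

    def __len__(self) -> int:
        return self.runs.shape[0]

    @property
    def center_mask(self) -> np.ndarray:
        return np.all(self.runs == 0.0, axis=1)


def build_ccd(space: FactorSpace, nCenter: int = 6) -> CCDDesign:
    """Full central composite design: 2^4 factorial, 8 axial, nCenter centers.

    With nCenter=6 this is the standard 30-run four-factor CCD.
    """
    if nCenter < 1:
        raise ValueError("nCenter must be >= 1")
    factorial = np.array(list(itertools.product((-1.0, 1.0), repeat=N_FACTORS)))
    axial = np.zeros((2 * N_FACTORS, N_FACTORS))
    for i in range(N_FACTORS):
        axial[2 * i, i] = -space.alpha
        axial[2 * i + 1, i] = space.alpha
    center = np.zeros((nCenter, N_FACTORS))
    coded = np.vstack([factorial, axial, center])
    return CCDDesign(runs=coded, actuals=space.to_actual(coded), nCenter=nCenter)


def rotatable_alpha(k: int = N_FACTORS) -> float:
    """Axial distance giving a rotatable CCD: (2^k)^(1/4)."""
    return (2.0 ** k) ** 0.25


@dataclass(frozen=True)
class QuadraticModel:
    """Full second-order polynomial in the four process factors.

    Coefficients are in actual units; prediction is pure polynomial
    evaluation with no clipping. Term order matches :data:`TERM_NAMES`.
    """

    intercept: float
    linear: tuple[float, float, float, float]
    interaction: tuple[float, float, float, float, float, float]  # 12,13,14,23,24,34
    quadratic: tuple[float, float, float, float]
    factor_order: tuple[str, ...] = ("pH", "contactTime", "initialConcentration", "dosage")

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate(
            [[self.intercept], self.linear, self.interaction, self.quadratic]
        )

    @classmethod
    def from_coefficients(cls, beta: Sequence[float], factor_order=None) -> "QuadraticModel":
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (15,):
            raise ValueError(f"expected 15 coefficients, got {beta.shape}")
        kwargs = {} if factor_order is None else {"factor_order": tuple(factor_order)}
        return cls(
            intercept=float(beta[0]),
            linear=tuple(beta[1:5]),
            interaction=tuple(beta[5:11]),
            quadratic=tuple(beta[11:15]),
            **kwargs,
        )

    def predict(self, x: np.ndarray) -> np.ndarray | float:
        return predict_quadratic(self, x)

    def hessian(self) -> np.ndarray:
        """Hessian/2 convention-free: H with f(x) = c + g.x + x'Hx, H sym."""
        h = np.diag(np.asarray(self.quadratic, dtype=float))
        for (i, j), b in zip(_PAIRS, self.interaction):
            h[i, j] = h[j, i] = b / 2.0
        return h


#: Quadratic removal-efficiency model published for diazinon adsorption on
#: acid-treated pumice (coefficients in actual units; X1=pH, X2=contact time
#: min, X3=initial concentration mg/L, X4=dosage g/L).
PUBLISHED_QUADRATIC = QuadraticModel(
    intercept=32.577,
    linear=(-4.588, 1.547, 8.249, 0.272),
    interaction=(-0.055, 0.256, -0.005, 0.043, -0.005, 0.015),
    quadratic=(0.158, -0.013, -1.011, -0.024),
)


def expand_quadratic(X: np.ndarray) -> np.ndarray:
    """Expand an (n,4) design matrix to the 15-column quadratic basis."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != N_FACTORS:
        raise ValueError(f"expected 4 factor columns, got {X.shape[1]}")
    cols = [np.ones(X.shape[0])]
    cols.extend(X[:, i] for i in range(N_FACTORS))
    cols.extend(X[:, i] * X[:, j] for i, j in _PAIRS)
    cols.extend(X[:, i] ** 2 for i in range(N_FACTORS))
    return np.column_stack(cols)


def fit_quadratic(X: np.ndarray, y: np.ndarray) -> QuadraticModel:
    """Ordinary least squares fit of the full 15-term quadratic."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 15:
        raise ValueError(f"need >= 15 runs to fit 15 coefficients, got {X.shape[0]}")
    design = expand_quadratic(X)
    rank = np.linalg.matrix_rank(design)
    if rank < 15:
        # identify (nearly) collinear columns via the R diagonal of a QR pass
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [TERM_NAMES[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"singular design (rank {rank} < 15); collinear columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return QuadraticModel.from_coefficients(beta)


def predict_quadratic(model: QuadraticModel, x: np.ndarray) -> np.ndarray | float:
    """Evaluate the quadratic polynomial at actual-unit point(s) x."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    out = expand_quadratic(np.atleast_2d(x)) @ model.coefficients
    return float(out[0]) if scalar else out


@dataclass
class AnovaTable:
    """ANOVA decomposition of a quadratic response-surface fit.

    ``terms`` maps each non-intercept term to (SS, df, MS, F, p). Lack-of-fit
    rows are present only when replicate runs supply a pure-error estimate.
    """

    terms: dict[str, tuple[float, int, float, float, float]]
    ss_model: float
    df_model: int
    ss_residual: float
    df_residual: int
    ss_total: float
    df_total: int
    r2: float
    adj_r2: float
    f_model: float
    p_model: float
    ss_lack_of_fit: Optional[float] = None
    df_lack_of_fit: Optional[int] = None
    ss_pure_error: Optional[float] = None
    df_pure_error: Optional[int] = None
    f_lack_of_fit: Optional[float] = None
    p_lack_of_fit: Optional[float] = None
    warnings: list[str] = field(default_factory=list)


def _sse(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def anova(
    model: QuadraticModel,
    X: np.ndarray,
    y: np.ndarray,
    center_replicate_mask: Optional[np.ndarray] = None,
    ss_type: str = "III",
) -> AnovaTable:
    """ANOVA of the fitted quadratic on (X, y).

    Type-III (partial) sums of squares by default: each term's SS is the SSE
    increase when that single column is dropped from the full model.
    ``ss_type='I'`` gives sequential SS in :data:`TERM_NAMES` order. Pure
    error is estimated from replicate runs flagged by
    ``center_replicate_mask``; without replicates the lack-of-fit split is
    omitted with a warning.
    """
    if ss_type not in ("I", "III"):
        raise ValueError("ss_type must be 'I' or 'III'")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    design = expand_quadratic(X)
    n = len(y)
    yhat = design @ model.coefficients
    resid = y - yhat
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_mod = ss_tot - ss_res
    df_model, df_res = 14, n - 15
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    terms: dict[str, tuple[float, int, float, float, float]] = {}
    if ss_type == "III":
        sse_full = _sse(design, y)
        for k, name in enumerate(TERM_NAMES[1:], start=1):
            reduced = np.delete(design, k, axis=1)
            ss_term = _sse(reduced, y) - sse_full
            terms[name] = _term_row(ss_term, ms_res, df_res)
    else:
        prev_sse = _sse(design[:, :1], y)
        for k, name in enumerate(TERM_NAMES[1:], start=1):
            cur_sse = _sse(design[:, : k + 1], y)
            terms[name] = _term_row(prev_sse - cur_sse, ms_res, df_res)
            prev_sse = cur_sse

    f_model = (ss_mod / df_model) / ms_res if df_res > 0 else np.nan
    p_model = float(stats.f.sf(f_model, df_model, df_res)) if df_res > 0 else np.nan
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (ss_res / df_res) / (ss_tot / (n - 1)) if df_res > 0 else np.nan

    table = AnovaTable(
        terms=terms,
        ss_model=ss_mod,
        df_model=df_model,
        ss_residual=ss_res,
        df_residual=df_res,
        ss_total=ss_tot,
        df_total=n - 1,
        r2=r2,
        adj_r2=adj_r2,
        f_model=f_model,
        p_model=p_model,
    )

    if center_replicate_mask is not None and int(np.sum(center_replicate_mask)) >= 2:
        mask = np.asarray(center_replicate_mask, dtype=bool)
        reps = y[mask]
        ss_pe = float(np.sum((reps - reps.mean()) ** 2))
        df_pe = int(mask.sum()) - 1
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        table.ss_pure_error, table.df_pure_error = ss_pe, df_pe
        table.ss_lack_of_fit, table.df_lack_of_fit = ss_lof, df_lof
        if df_lof > 0 and df_pe > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            table.f_lack_of_fit = f_lof
            table.p_lack_of_fit = float(stats.f.sf(f_lof, df_lof, df_pe))
    else:
        table.warnings.append("no replicate runs: lack-of-fit rows omitted")
    return table


def _term_row(ss: float, ms_res: float, df_res: int):
    ss = max(ss, 0.0)
    f = ss / ms_res if df_res > 0 and ms_res > 0 else np.nan
    p = float(stats.f.sf(f, 1, df_res)) if df_res > 0 and ms_res > 0 else np.nan
    return (ss, 1, ss, f, p)


def pareto_effects(model: QuadraticModel, linear_only: bool = False) -> dict[str, float]:
    """Squared-coefficient importance shares, P_i = 100 * b_i^2 / sum b^2.

    By default the denominator runs over all 14 non-intercept coefficients
    (linear, interaction and pure-quadratic terms); ``linear_only=True``
    restricts both numerator terms and the denominator to the 4 linear
    coefficients.
    """
    beta = model.coefficients[1:]
    names = TERM_NAMES[1:]
    if linear_only:
        beta, names = beta[:4], names[:4]
    total = float(np.sum(beta ** 2))
    if total == 0:
        raise ValueError("all coefficients are zero: Pareto effects undefined")
    return {name: 100.0 * float(b) ** 2 / total for name, b in zip(names, beta)}


def optimize_quadratic(
    model: QuadraticModel,
    bounds: Sequence[tuple[float, float]],
    fixed: Optional[dict[int, float]] = None,
    maximize: bool = True,
) -> tuple[np.ndarray, float]:
    """Exact global optimum of the quadratic over a box.

    Enumerates every face of the box: each free factor is either pinned to a
    bound or left interior, the stationary system of the restricted quadratic
    is solved on each face, and feasible candidates are compared. Exact for
    quadratics in 4 variables (3^4 = 81 faces), so the optimum is
    deterministic. ``fixed`` pins factors (by index) to given values.
    """
    fixed = dict(fixed or {})
    bounds = list(bounds)
    if len(bounds) != N_FACTORS:
        raise ValueError("need bounds for all 4 factors")
    hess = model.hessian()
    grad0 = np.asarray(model.linear, dtype=float)
    free = [i for i in range(N_FACTORS) if i not in fixed]
    if any(not np.isfinite(bounds[i][0]) or not np.isfinite(bounds[i][1]) for i in free):
        eigs = np.linalg.eigvalsh(hess[np.ix_(free, free)])
        definite = np.all(eigs < 0) if maximize else np.all(eigs > 0)
        if not definite:
            raise ValueError("unbounded optimization: infinite bounds with indefinite Hessian")

    best_x, best_val = None, -np.inf if maximize else np.inf
    for assignment in itertools.product((0, 1, 2), repeat=len(free)):
        x = np.zeros(N_FACTORS)
        for i, v in fixed.items():
            x[i] = v
        interior = []
        feasible = True
        for i, a in zip(free, assignment):
            lo, hi = bounds[i]
            if a == 0:
                if not np.isfinite(lo):
                    feasible = False
                    break
                x[i] = lo
            elif a == 1:
                if not np.isfinite(hi):
                    feasible = False
                    break
                x[i] = hi
            else:
                interior.append(i)
        if not feasible:
            continue
        if interior:
            idx = np.array(interior)
            others = np.array([i for i in range(N_FACTORS) if i not in interior])
            h_ii = hess[np.ix_(idx, idx)]
            g = grad0[idx].copy()
            if len(others):
                g = g + 2.0 * hess[np.ix_(idx, others)] @ x[others]
            try:
                sol = np.linalg.solve(2.0 * h_ii, -g)
            except np.linalg.LinAlgError:
                continue
            ok = all(
                bounds[i][0] - 1e-12 <= s <= bounds[i][1] + 1e-12
                for i, s in zip(interior, sol)
            )
            if not ok:
                continue
            x[idx] = np.clip(sol, [bounds[i][0] for i in interior], [bounds[i][1] for i in interior])
        val = predict_quadratic(model, x)
        if (maximize and val > best_val) or (not maximize and val < best_val):
            best_x, best_val = x.copy(), val
    if best_x is None:
        raise ValueError("no feasible candidate found (check bounds)")
    return best_x, float(best_val)
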