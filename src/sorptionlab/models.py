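"""Closed-form isotherm and kinetic model library.

Six equilibrium isotherms (Freundlich, Langmuir, Temkin, Redlich-Peterson,
Sips, Toth) and four sorption-rate laws (pseudo-first-order,
pseudo-second-order, Weber-Morris intraparticle diffusion, Boyd film
diffusion), each with forward prediction, default fitting bounds, and the
linearized transform classically used to estimate its parameters by straight
-line regression. Three-parameter isotherms have no exact linearization; an
iterated (exponent-grid) linearization is provided and flagged approximate.

Functional forms (concentrations ce in mg/L, loadings q in mg/g, time t min):

- Freundlich      qe = K_F * ce**b_F
- Langmuir        qe = K_L * b_L * ce / (1 + b_L * ce)
- Temkin          qe = B_T * ln(K_T * ce)
- Redlich-Peterson qe = K_R * ce / (1 + a_R * ce**alpha)
- Sips            qe = K_s * b_s * ce**n_s / (1 + b_s * ce**n_s)
- Toth            qe = K_th * ce / (b_th + ce**n_th)**(1/n_th)
- PFO             qt = qe * (1 - exp(-K1 * t))
- PSO             qt = K2 * qe**2 * t / (1 + K2 * qe * t)
- Weber-Morris    qt = K_id * sqrt(t)
- Boyd            qt = qe * (1 - (6/pi^2) * exp(-B * t))

The Boyd form is the single-exponential film-diffusion approximation, so its
parameter vector is (B, qe); its qt(0) = qe*(1 - 6/pi^2) != 0 is an artifact
of that truncation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "IsothermSpec",
    "KineticSpec",
    "ISOTHERM_MODELS",
    "KINETIC_MODELS",
    "REFERENCE_ISOTHERMS_NL",
    "REFERENCE_KINETICS_NL",
    "get_model",
    "isotherm_predict",
    "kinetic_predict",
    "isotherm_linearize",
    "kinetic_linearize",
]

DEFAULT_BOUNDS = (1e-6, 1e3)
EXPONENT_BOUNDS = (0.05, 2.0)


@dataclass(frozen=True)
class ModelDef:
    """Registry entry for a named model form."""

    name: str
    kind: str  # "isotherm" | "kinetic"
    param_names: tuple[str, ...]
    predict: Callable[[np.ndarray, np.ndarray], np.ndarray]
    bounds: tuple[tuple[float, float], ...]
    exact_linearization: bool = True


def _freundlich(p, ce):
    kf, bf = p
    return kf * np.power(ce, bf)


def _langmuir(p, ce):
    kl, bl = p
    return kl * bl * ce / (1.0 + bl * ce)


def _temkin(p, ce):
    bt, kt = p
    ce = np.asarray(ce, dtype=float)
    if np.any(ce <= 0):
        raise ValueError("Temkin isotherm requires ce > 0")
    return bt * np.log(kt * ce)


def _redlich_peterson(p, ce):
    kr, ar, alpha = p
    return kr * ce / (1.0 + ar * np.power(ce, alpha))


def _sips(p, ce):
    ks, bs, ns = p
    u = bs * np.power(ce, ns)
    return ks * u / (1.0 + u)


def _toth(p, ce):
    kth, bth, nth = p
    return kth * ce / np.power(bth + np.power(ce, nth), 1.0 / nth)


def _pfo(p, t):
    k1, qe = p
    return qe * (1.0 - np.exp(-k1 * np.asarray(t, dtype=float)))


def _pso(p, t):
    k2, qe = p
    t = np.asarray(t, dtype=float)
    return k2 * qe ** 2 * t / (1.0 + k2 * qe * t)


def _weber_morris(p, t):
    (kid,) = p
    return kid * np.sqrt(np.asarray(t, dtype=float))


BOYD_CONST = 6.0 / np.pi ** 2  # ~0.6079; -ln of it is 0.4977


def _boyd(p, t):
    b, qe = p
    return qe * (1.0 - BOYD_CONST * np.exp(-b * np.asarray(t, dtype=float)))


ISOTHERM_MODELS: dict[str, ModelDef] = {
    "freundlich": ModelDef("freundlich", "isotherm", ("K_F", "b_F"), _freundlich,
                           (DEFAULT_BOUNDS, EXPONENT_BOUNDS)),
    "langmuir": ModelDef("langmuir", "isotherm", ("K_L", "b_L"), _langmuir,
                         (DEFAULT_BOUNDS, DEFAULT_BOUNDS)),
    "temkin": ModelDef("temkin", "isotherm", ("B_T", "K_T"), _temkin,
                       (DEFAULT_BOUNDS, DEFAULT_BOUNDS)),
    "redlich_peterson": ModelDef("redlich_peterson", "isotherm", ("K_R", "a_R", "alpha"),
                                 _redlich_peterson,
                                 (DEFAULT_BOUNDS, DEFAULT_BOUNDS, EXPONENT_BOUNDS),
                                 exact_linearization=False),
    "sips": ModelDef("sips", "isotherm", ("K_s", "b_s", "n_s"), _sips,
                     (DEFAULT_BOUNDS, DEFAULT_BOUNDS, EXPONENT_BOUNDS),
                     exact_linearization=False),
    "toth": ModelDef("toth", "isotherm", ("K_th", "b_th", "n_th"), _toth,
                     (DEFAULT_BOUNDS, DEFAULT_BOUNDS, EXPONENT_BOUNDS),
                     exact_linearization=False),
}

KINETIC_MODELS: dict[str, ModelDef] = {
    "pfo": ModelDef("pfo", "kinetic", ("K1", "qe"), _pfo, (DEFAULT_BOUNDS, DEFAULT_BOUNDS)),
    "pso": ModelDef("pso", "kinetic", ("K2", "qe"), _pso, (DEFAULT_BOUNDS, DEFAULT_BOUNDS)),
    "weber_morris": ModelDef("weber_morris", "kinetic", ("K_id",), _weber_morris,
                             (DEFAULT_BOUNDS,)),
    "boyd": ModelDef("boyd", "kinetic", ("B", "qe"), _boyd, (DEFAULT_BOUNDS, DEFAULT_BOUNDS)),
}

_ALL_MODELS = {**ISOTHERM_MODELS, **KINETIC_MODELS}


def get_model(name: str) -> ModelDef:
    key = name.lower().replace("-", "_").replace(" ", "_")
    aliases = {"rp": "redlich_peterson", "wm": "weber_morris", "weber": "weber_morris"}
    key = aliases.get(key, key)
    if key not in _ALL_MODELS:
        raise KeyError(f"unknown model '{name}'; available: {sorted(_ALL_MODELS)}")
    return _ALL_MODELS[key]


@dataclass
class IsothermSpec:
    """A named isotherm plus its parameter vector."""

    name: str
    params: dict[str, float]
    bounds: Optional[dict[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        mdef = get_model(self.name)
        if mdef.kind != "isotherm":
            raise ValueError(f"{self.name} is not an isotherm model")
        missing = set(mdef.param_names) - set(self.params)
        if missing:
            raise ValueError(f"{self.name}: missing parameters {sorted(missing)}")
        if any(v <= 0 for v in self.params.values()):
            raise ValueError(f"{self.name}: all parameters must be positive")
        for pname in ("alpha", "n_s", "n_th"):
            if pname in self.params and not (0 < self.params[pname] <= 2):
                raise ValueError(f"{self.name}: exponent {pname} must lie in (0, 2]")

    @property
    def vector(self) -> np.ndarray:
        mdef = get_model(self.name)
        return np.array([self.params[p] for p in mdef.param_names])

    def predict(self, ce):
        return isotherm_predict(self, ce)


@dataclass
class KineticSpec:
    """A named kinetic rate law plus its parameter vector."""

    name: str
    params: dict[str, float]
    bounds: Optional[dict[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        mdef = get_model(self.name)
        if mdef.kind != "kinetic":
            raise ValueError(f"{self.name} is not a kinetic model")
        missing = set(mdef.param_names) - set(self.params)
        if missing:
            raise ValueError(f"{self.name}: missing parameters {sorted(missing)}")
        if any(v <= 0 for v in self.params.values()):
            raise ValueError(f"{self.name}: all parameters must be positive")

    @property
    def vector(self) -> np.ndarray:
        mdef = get_model(self.name)
        return np.array([self.params[p] for p in mdef.param_names])

    def predict(self, t):
        return kinetic_predict(self, t)


#: Published nonlinear (DE-estimated) parameter sets for diazinon adsorption
#: on pumice, used as reference fixtures for round-trip recovery tests.
REFERENCE_ISOTHERMS_NL: dict[str, IsothermSpec] = {
    "freundlich": IsothermSpec("freundlich", {"K_F": 20.27, "b_F": 0.433}),
    "langmuir": IsothermSpec("langmuir", {"K_L": 10.42, "b_L": 0.161}),
    "temkin": IsothermSpec("temkin", {"B_T": 1.370, "K_T": 2.43}),
    "redlich_peterson": IsothermSpec(
        "redlich_peterson", {"K_R": 1.763, "a_R": 0.191, "alpha": 0.964}
    ),
    "sips": IsothermSpec("sips", {"K_s": 10.54, "b_s": 0.162, "n_s": 0.962}),
    "toth": IsothermSpec("toth", {"K_th": 10.73, "b_th": 0.180, "n_th": 0.947}),
}

REFERENCE_KINETICS_NL: dict[str, KineticSpec] = {
    "pfo": KineticSpec("pfo", {"K1": 0.044, "qe": 3.49}),
    "pso": KineticSpec("pso", {"K2": 0.0054, "qe": 5.4342}),
    "weber_morris": KineticSpec("weber_morris", {"K_id": 0.442}),
    "boyd": KineticSpec("boyd", {"B": 0.068, "qe": 2.210}),
}


def isotherm_predict(spec: IsothermSpec, ce) -> np.ndarray | float:
    """Equilibrium loading qe (mg/g) at residual concentration ce (mg/L)."""
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValueError("ce must be nonnegative")
    out = get_model(spec.name).predict(spec.vector, ce_arr)
    return float(out) if np.isscalar(ce) or np.ndim(ce) == 0 else out


def kinetic_predict(spec: KineticSpec, t) -> np.ndarray | float:
    """Loading qt (mg/g) at contact time t (min)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    out = get_model(spec.name).predict(spec.vector, t_arr)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


@dataclass
class Linearization:
    """Transformed data plus the straight-line -> parameter back-map."""

    u: np.ndarray
    v: np.ndarray
    back_map: Callable[[float, float], dict[str, float]]
    through_origin: bool = False
    approximate: bool = False
    fixed_params: dict[str, float] = field(default_factory=dict)
    n_dropped: int = 0


def _drop_invalid(ce, qe, require_qe_pos=True, require_ce_pos=True):
    ce = np.asarray(ce, dtype=float)
    qe = np.asarray(qe, dtype=float)
    keep = np.ones(len(ce), dtype=bool)
    if require_ce_pos:
        keep &= ce > 0
    if require_qe_pos:
        keep &= qe > 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} rows with nonpositive values under log transform")
    return ce[keep], qe[keep], dropped


def isotherm_linearize(name: str, ce: Sequence[float], qe: Sequence[float]) -> Linearization:
    """Classical linearizing transform for an isotherm.

    Freundlich: ln qe on ln ce; Langmuir: ce/qe on ce; Temkin: qe on ln ce.
    Redlich-Peterson / Sips / Toth admit no exact linearization: the exponent
    is scanned on a grid and, per candidate, the remaining two parameters are
    obtained from a conditional straight line; the result is flagged
    approximate (handled in fit_engine.linear_fit).
    """
    mdef = get_model(name)
    if mdef.kind != "isotherm":
        raise ValueError(f"{name} is not an isotherm model")
    if len(ce) != len(qe):
        raise ValueError("ce and qe must have equal length")
    key = mdef.name

    if key == "freundlich":
        c, q, nd = _drop_invalid(ce, qe)
        _need_two(c)
        return Linearization(
            np.log(c), np.log(q),
            lambda slope, icept: {"K_F": float(np.exp(icept)), "b_F": float(slope)},
            n_dropped=nd,
        )
    if key == "langmuir":
        c, q, nd = _drop_invalid(ce, qe)
        _need_two(c)

        def back(slope, icept):
            kl = 1.0 / slope
            return {"K_L": float(kl), "b_L": float(1.0 / (icept * kl))}

        return Linearization(c, c / q, back, n_dropped=nd)
    if key == "temkin":
        c, q, nd = _drop_invalid(ce, qe, require_qe_pos=False)
        _need_two(c)
        return Linearization(
            np.log(c), q,
            lambda slope, icept: {"B_T": float(slope), "K_T": float(np.exp(icept / slope))},
            n_dropped=nd,
        )
    raise ValueError(
        f"{name} has no exact linearization; use the exponent-grid path in fit_engine"
    )


def isotherm_conditional_linearization(
    name: str, ce: Sequence[float], qe: Sequence[float], exponent: float
) -> Linearization:
    """Straight-line sub-problem of a 3-parameter isotherm at fixed exponent."""
    mdef = get_model(name)
    c, q, nd = _drop_invalid(ce, qe)
    _need_two(c)
    key = mdef.name
    if key == "redlich_peterson":
        # ce/qe = 1/K_R + (a_R/K_R) * ce**alpha
        def back(slope, icept):
            kr = 1.0 / icept
            return {"K_R": float(kr), "a_R": float(slope * kr), "alpha": float(exponent)}

        return Linearization(np.power(c, exponent), c / q, back,
                             approximate=True, fixed_params={"alpha": exponent}, n_dropped=nd)
    if key == "sips":
        # 1/qe = 1/K_s + (1/(K_s b_s)) * ce**(-n)
        def back(slope, icept):
            ks = 1.0 / icept
            return {"K_s": float(ks), "b_s": float(1.0 / (slope * ks)), "n_s": float(exponent)}

        return Linearization(np.power(c, -exponent), 1.0 / q, back,
                             approximate=True, fixed_params={"n_s": exponent}, n_dropped=nd)
    if key == "toth":
        # (ce/qe)**n = b_th/K_th**n + (1/K_th**n) * ce**n
        def back(slope, icept):
            kth = slope ** (-1.0 / exponent)
            return {"K_th": float(kth), "b_th": float(icept / slope), "n_th": float(exponent)}

        return Linearization(np.power(c, exponent), np.power(c / q, exponent), back,
                             approximate=True, fixed_params={"n_th": exponent}, n_dropped=nd)
    raise ValueError(f"{name} has an exact linearization; use isotherm_linearize")


def kinetic_linearize(
    name: str, t: Sequence[float], qt: Sequence[float], qe_exp: Optional[float] = None
) -> Linearization:
    """Classical linearizing transform for a kinetic rate law.

    PFO: ln(qe_exp - qt) on t; PSO: t/qt on t; Weber-Morris: qt on sqrt(t)
    through the origin; Boyd: Bt = -0.4977 - ln(1 - qt/qe_exp) on t through
    the origin, slope = B. PFO and Boyd need the experimental equilibrium
    loading ``qe_exp``; rows with qt >= qe_exp are dropped with a warning.
    """
    mdef = get_model(name)
    if mdef.kind != "kinetic":
        raise ValueError(f"{name} is not a kinetic model")
    t = np.asarray(t, dtype=float)
    qt = np.asarray(qt, dtype=float)
    if len(t) != len(qt):
        raise ValueError("t and qt must have equal length")
    key = mdef.name

    if key in ("pfo", "boyd"):
        if qe_exp is None or qe_exp <= 0:
            raise ValueError(f"{key} linearization requires qe_exp > 0")
        keep = qt < qe_exp
        nd = int((~keep).sum())
        if nd:
            warnings.warn(f"dropped {nd} rows with qt >= qe_exp under log transform")
        tt, qq = t[keep], qt[keep]
        _need_two(tt)
        if key == "pfo":
            return Linearization(
                tt, np.log(qe_exp - qq),
                lambda slope, icept: {"K1": float(-slope), "qe": float(np.exp(icept))},
                fixed_params={"qe_exp": qe_exp}, n_dropped=nd,
            )
        # Bt = -0.4977 - ln(1 - F) with 0.4977 = -ln(6/pi^2)
        bt = np.log(BOYD_CONST) - np.log(1.0 - qq / qe_exp)
        return Linearization(
            tt, bt,
            lambda slope, icept: {"B": float(slope), "qe": float(qe_exp)},
            through_origin=True, fixed_params={"qe_exp": qe_exp}, n_dropped=nd,
        )
    if key == "pso":
        keep = (qt > 0) & (t > 0)
        nd = int((~keep).sum())
        if nd:
            warnings.warn(f"dropped {nd} rows with nonpositive t or qt")
        tt, qq = t[keep], qt[keep]
        _need_two(tt)

        def back(slope, icept):
            qe = 1.0 / slope
            return {"K2": float(1.0 / (icept * qe ** 2)), "qe": float(qe)}

        return Linearization(tt, tt / qq, back, n_dropped=nd)
    if key == "weber_morris":
        _need_two(t)
        return Linearization(
            np.sqrt(t), qt,
            lambda slope, icept: {"K_id": float(slope)},
            through_origin=True,
        )
    raise AssertionError(key)


def _need_two(arr) -> None:
    if len(arr) < 2:
        raise ValueError("need at least 2 valid points for a straight-line fit")
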