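"""End-to-end analysis pipeline over batch adsorption data.

Reproduces the study's analysis sequence on any dataset (measured CSVs or
the synthetic generators): quadratic response-surface fit with ANOVA, Pareto
effects and exact box-constrained optimum; ANN surrogate (neuron scan, LM
training) with GA process optimization; linear-vs-nonlinear isotherm and
kinetic comparison tables; and van't Hoff thermodynamics. Stages run
independently: a stage with no input is skipped with a logged reason, and
every stochastic stage records its seed in the report.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import ann_ga, fitting, rsm, thermo
from .io import (
    DESIGN_SCHEMA,
    EQUILIBRIUM_SCHEMA,
    KINETICS_SCHEMA,
    THERMO_SCHEMA,
    read_table,
    write_json,
    write_table,
)

logger = logging.getLogger("sorptionlab")

__all__ = ["PipelineConfig", "run_pipeline"]

ISOTHERM_DEFAULTS = ["freundlich", "langmuir", "temkin", "redlich_peterson", "sips", "toth"]
KINETIC_DEFAULTS = ["pfo", "pso", "weber_morris", "boyd"]


class FactorSpaceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    names: tuple[str, str, str, str] = ("pH", "contactTime", "initialConcentration", "dosage")
    center: tuple[float, float, float, float] = (7.0, 20.0, 6.0, 2.2)
    step: tuple[float, float, float, float] = (2.0, 5.0, 2.0, 0.9)
    alpha: float = 2.0

    def build(self) -> rsm.FactorSpace:
        return rsm.FactorSpace(
            names=self.names, center=self.center, step=self.step, alpha=self.alpha
        )


class AnnConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scan_candidates: tuple[int, ...] = tuple(range(1, 15))
    epochs_max: int = 300
    seed: int = 7


class GaSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    population_size: int = 60
    generations: int = 120
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15
    seed: int = 11


class DeSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    popsize: int = 15
    mutation: float = 0.7
    recombination: float = 0.9
    maxiter: int = 2000
    tol: float = 1e-10
    seed: int = 3

    def build(self) -> fitting.DeConfig:
        return fitting.DeConfig(
            popsize=self.popsize,
            mutation=self.mutation,
            recombination=self.recombination,
            maxiter=self.maxiter,
            tol=self.tol,
            seed=self.seed,
        )


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    design_csv: Optional[str] = None
    equilibrium_csv: Optional[str] = None
    kinetics_csv: Optional[str] = None
    thermo_csv: Optional[str] = None
    factor_space: FactorSpaceConfig = Field(default_factory=FactorSpaceConfig)
    isotherm_models: list[str] = Field(default_factory=lambda: list(ISOTHERM_DEFAULTS))
    kinetic_models: list[str] = Field(default_factory=lambda: list(KINETIC_DEFAULTS))
    ann: AnnConfig = Field(default_factory=AnnConfig)
    ga: GaSettings = Field(default_factory=GaSettings)
    de: DeSettings = Field(default_factory=DeSettings)
    qe_exp: Optional[float] = None  # experimental equilibrium loading for PFO/Boyd lines
    out_dir: Optional[str] = None


def _rsm_stage(cfg: PipelineConfig, out: Optional[Path]) -> dict:
    df = read_table(cfg.design_csv, DESIGN_SCHEMA)
    space = cfg.factor_space.build()
    X = df[list(space.names)].to_numpy()
    y = df["response"].to_numpy()
    model = rsm.fit_quadratic(X, y)
    center_mask = np.all(np.isclose(space.to_coded(X), 0.0), axis=1)
    table = rsm.anova(model, X, y, center_replicate_mask=center_mask)
    pareto = rsm.pareto_effects(model)
    best_x, best_val = rsm.optimize_quadratic(model, space.bounds)
    block = {
        "coefficients": dict(zip(rsm.TERM_NAMES, model.coefficients)),
        "anova": {
            "r2": table.r2,
            "adj_r2": table.adj_r2,
            "f_model": table.f_model,
            "p_model": table.p_model,
            "ss_model": table.ss_model,
            "ss_residual": table.ss_residual,
            "ss_total": table.ss_total,
            "p_lack_of_fit": table.p_lack_of_fit,
        },
        "pareto_percent": pareto,
        "optimum": {"x": dict(zip(space.names, best_x)), "response": best_val},
    }
    if out is not None:
        anova_rows = [
            {"term": name, "SS": ss, "df": dfree, "MS": ms, "F": f, "p": p}
            for name, (ss, dfree, ms, f, p) in table.terms.items()
        ]
        import pandas as pd

        write_table(pd.DataFrame(anova_rows), out / "rsm_anova.csv")
    return block


def _ann_stage(cfg: PipelineConfig, out: Optional[Path]) -> dict:
    df = read_table(cfg.design_csv, DESIGN_SCHEMA)
    space = cfg.factor_space.build()
    X = df[list(space.names)].to_numpy()
    y = df["response"].to_numpy()
    best_n, scan = ann_ga.scan_hidden_neurons(
        X, y, candidates=cfg.ann.scan_candidates,
        seed=cfg.ann.seed, epochs_max=cfg.ann.epochs_max,
    )
    model, report = ann_ga.train_lm(
        X, y, n_hidden=best_n, epochs_max=cfg.ann.epochs_max, seed=cfg.ann.seed
    )
    ga_cfg = ann_ga.GaConfig(
        bounds=space.bounds,
        population_size=cfg.ga.population_size,
        generations=cfg.ga.generations,
        crossover_rate=cfg.ga.crossover_rate,
        mutation_rate=cfg.ga.mutation_rate,
        seed=cfg.ga.seed,
    )
    opt_x, opt_val = ann_ga.optimize_process_conditions(model, space.bounds, ga_cfg)
    if out is not None:
        model.save(out / "ann_model.json")
    return {
        "best_n_hidden": best_n,
        "scan": {str(k): v for k, v in scan.items()},
        "mse": report.mse,
        "r2": report.r2,
        "epochs": report.epochs,
        "seed": cfg.ann.seed,
        "ga_seed": cfg.ga.seed,
        "optimum": {"x": dict(zip(space.names, opt_x)), "response": opt_val},
    }


def _fit_stage(cfg: PipelineConfig, kind: str, out: Optional[Path]) -> dict:
    if kind == "isotherms":
        df = read_table(cfg.equilibrium_csv, EQUILIBRIUM_SCHEMA)
        x, y = df["ce_mg_L"].to_numpy(), df["qe_mg_g"].to_numpy()
        models = cfg.isotherm_models
        qe_exp = None
    else:
        df = read_table(cfg.kinetics_csv, KINETICS_SCHEMA)
        x, y = df["t_min"].to_numpy(), df["qt_mg_g"].to_numpy()
        models = cfg.kinetic_models
        qe_exp = cfg.qe_exp if cfg.qe_exp is not None else 1.05 * float(np.max(y))
    table = fitting.compare_methods(models, x, y, cfg=cfg.de.build(), qe_exp=qe_exp)
    if out is not None:
        write_table(table, out / f"{kind}_comparison.csv")
    return {
        "seed": cfg.de.seed,
        "table": table.to_dict(orient="records"),
    }


def _thermo_stage(cfg: PipelineConfig, out: Optional[Path]) -> dict:
    df = read_table(cfg.thermo_csv, THERMO_SCHEMA)
    series = thermo.ThermoSeries(
        temperatures=tuple(df["T_K"]), bL=tuple(df["bL_L_per_mg"])
    )
    result = thermo.vant_hoff_fit(series)
    return {
        "temperatures_K": result.temperatures,
        "ke": result.ke,
        "dG_kJ_mol": result.dG,
        "dH_kJ_mol": result.dH,
        "dS_J_mol_K": result.dS,
        "vant_hoff_r2": result.vant_hoff_r2,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; return the report bundle.

    Stage order: RSM, ANN-GA, isotherms, kinetics, thermodynamics. A stage
    without inputs is skipped with a logged reason; a stage that raises
    aborts the run with the stage name in the exception.
    """
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    stages = [
        ("rsm", cfg.design_csv, _rsm_stage),
        ("ann_ga", cfg.design_csv, _ann_stage),
        ("isotherms", cfg.equilibrium_csv, lambda c, o: _fit_stage(c, "isotherms", o)),
        ("kinetics", cfg.kinetics_csv, lambda c, o: _fit_stage(c, "kinetics", o)),
        ("thermodynamics", cfg.thermo_csv, _thermo_stage),
    ]
    for name, inp, fn in stages:
        if inp is None:
            logger.info("stage %s skipped: no input configured", name)
            report["stages"][name] = {"skipped": "no input configured"}
            continue
        try:
            report["stages"][name] = fn(cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    if out is not None:
        write_json(report, out / "report.json")
    return report
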