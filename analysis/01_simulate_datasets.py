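"""Generate the synthetic study datasets every later stage consumes.

The study's raw measurements are not distributed, so seeded generators
emulate them: a 30-run CCD response table from the published quadratic
(replicate noise sd 0.5 %), a 21-point equilibrium curve and a 3-30 min
kinetic trace from the published nonlinear parameter sets, and a
4-temperature affinity series from a chosen endothermic ground truth.

Writes CSVs under results/data/.
"""

from pathlib import Path

import pandas as pd

import sorptionlab as sl

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

THERMO_TRUTH = {"dH_kJ_mol": 30.0, "dS_J_mol_K": 150.0}


def main() -> None:
    space = sl.DEFAULT_FACTOR_SPACE

    from sorptionlab.io import write_table

    design, _, n_trunc = sl.gen_ccd_response(space, sl.PUBLISHED_QUADRATIC, noise_sd=0.5, seed=101)
    write_table(design, OUT / "ccd_design.csv")
    print(f"CCD design: 30 runs, {n_trunc} truncated responses -> {OUT/'ccd_design.csv'}")

    eq, _ = sl.gen_equilibrium(sl.REFERENCE_ISOTHERMS_NL["langmuir"], noise_sd=0.1, seed=102)
    write_table(eq, OUT / "equilibrium.csv")
    print(f"equilibrium curve: {len(eq)} points (Langmuir truth K_L=10.42, b_L=0.161)")

    kin, _ = sl.gen_kinetics(sl.REFERENCE_KINETICS_NL["pso"], noise_sd=0.03, seed=103)
    write_table(kin, OUT / "kinetics.csv")
    print(f"kinetic trace: {len(kin)} points (PSO truth K2=0.0054, qe=5.4342)")

    series = sl.gen_thermo_series(THERMO_TRUTH["dH_kJ_mol"], THERMO_TRUTH["dS_J_mol_K"])
    write_table(
        pd.DataFrame({"T_K": series.temperatures, "bL_L_per_mg": series.bL}),
        OUT / "thermo_series.csv",
    )
    print(f"thermo series: 4 temperatures, ground truth dH={THERMO_TRUTH['dH_kJ_mol']} kJ/mol, "
          f"dS={THERMO_TRUTH['dS_J_mol_K']} J/(mol K)")


if __name__ == "__main__":
    main()
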