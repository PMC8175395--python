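"""van't Hoff analysis of the temperature series of Langmuir affinities.

Converts each affinity b_L (L/mg) to the dimensionless equilibrium constant
Ke°, regresses ln Ke° on 1/T, and reports dH°, dS° and dG°(T). Writes
results/thermo_summary.json.
"""

from pathlib import Path

import sorptionlab as sl
from sorptionlab.io import THERMO_SCHEMA, read_table, write_json

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = read_table(ROOT / "data" / "thermo_series.csv", THERMO_SCHEMA)
    series = sl.ThermoSeries(
        temperatures=tuple(df["T_K"]), bL=tuple(df["bL_L_per_mg"])
    )
    res = sl.vant_hoff_fit(series)

    print(f"van't Hoff fit (R2 {res.vant_hoff_r2:.6f}): "
          f"dH = {res.dH:.3f} kJ/mol, dS = {res.dS:.3f} J/(mol K)")
    for t, ke, g in zip(res.temperatures, res.ke, res.dG):
        print(f"  T = {t:.0f} K: Ke = {ke:.4g}, dG = {g:.3f} kJ/mol")
    sign = "endothermic" if res.dH > 0 else "exothermic"
    spont = "spontaneous (dG < 0) at all temperatures" if all(g < 0 for g in res.dG) \
        else "not spontaneous at every temperature"
    print(f"adsorption is {sign} and {spont}")

    write_json(
        {
            "dH_kJ_mol": res.dH,
            "dS_J_mol_K": res.dS,
            "vant_hoff_r2": res.vant_hoff_r2,
            "per_temperature": [
                {"T_K": t, "Ke": k, "dG_kJ_mol": g}
                for t, k, g in zip(res.temperatures, res.ke, res.dG)
            ],
        },
        ROOT / "thermo_summary.json",
    )


if __name__ == "__main__":
    main()
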