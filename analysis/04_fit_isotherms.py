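"""Fit all six isotherms to the equilibrium data, linear vs nonlinear-DE.

Produces the side-by-side comparison (parameters plus R2/SAE/SSE/ARE/RMSE
per method) and reports which model family the nonlinear route ranks best.

Writes results/isotherm_comparison.csv.
"""

from pathlib import Path

import sorptionlab as sl
from sorptionlab.fitting import DeConfig, compare_methods
from sorptionlab.io import EQUILIBRIUM_SCHEMA, read_table, write_table

ROOT = Path(__file__).resolve().parents[1] / "results"

MODELS = ["freundlich", "langmuir", "temkin", "redlich_peterson", "sips", "toth"]


def main() -> None:
    df = read_table(ROOT / "data" / "equilibrium.csv", EQUILIBRIUM_SCHEMA)
    table = compare_methods(
        MODELS, df["ce_mg_L"], df["qe_mg_g"], cfg=DeConfig(seed=21)
    )
    write_table(table, ROOT / "isotherm_comparison.csv")

    nl = table[table.method == "nonlinear-DE"].set_index("model")
    best = nl["RMSE"].idxmin()
    print(table.to_string(index=False))
    print(f"\nbest nonlinear fit by RMSE: {best} "
          f"(RMSE {nl.loc[best, 'RMSE']:.4g}, R2 {nl.loc[best, 'R2']:.4f})")
    print("the data were generated from a Langmuir truth, so Langmuir-family "
          "forms (Langmuir/Sips/Toth/R-P near their limiting cases) should lead")


if __name__ == "__main__":
    main()
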