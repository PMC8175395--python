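"""Train the ANN surrogate on the CCD table and optimize it with the GA.

Scans hidden-layer widths 1-14 on validation MSE, retrains the winner
(Levenberg-Marquardt, 70/15/15 split), and maximizes the surrogate's
predicted removal over the factor box with the genetic algorithm. With only
30 design points the surrogate is data-limited; the methods note discusses
what the scan and the optimum do and do not establish at this sample size.

Writes results/ann_scan.csv, results/ann_model.json, results/ann_summary.json.
"""

import warnings
from pathlib import Path

import pandas as pd

import sorptionlab as sl
from sorptionlab import ann_ga
from sorptionlab.io import DESIGN_SCHEMA, read_table, write_json, write_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    space = sl.DEFAULT_FACTOR_SPACE
    df = read_table(ROOT / "data" / "ccd_design.csv", DESIGN_SCHEMA)
    X = df[list(space.names)].to_numpy()
    y = df["response"].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best_n, scan = ann_ga.scan_hidden_neurons(X, y, seed=7, epochs_max=300)
        model, report = ann_ga.train_lm(X, y, n_hidden=best_n, epochs_max=300, seed=7)
        cfg = ann_ga.GaConfig(population_size=80, generations=200, seed=11)
        x_opt, removal_opt = ann_ga.optimize_process_conditions(model, space.bounds, cfg)

    print(f"hidden-neuron scan winner: {best_n} neurons "
          f"(validation MSE {scan[best_n]['mse_validation']:.4g})")
    print(f"retrained {best_n}-neuron net: "
          + ", ".join(f"{k} R2 {v:.3f}" for k, v in report.r2.items()))
    print("GA optimum of the surrogate: "
          + ", ".join(f"{n}={v:.3g}" for n, v in zip(space.names, x_opt))
          + f" -> {removal_opt:.2f} % predicted removal")

    write_table(
        pd.DataFrame([{"n_hidden": n, **row} for n, row in scan.items()]),
        ROOT / "ann_scan.csv",
    )
    model.save(ROOT / "ann_model.json")
    write_json(
        {
            "best_n_hidden": best_n,
            "r2": report.r2,
            "mse": report.mse,
            "epochs": report.epochs,
            "ga_optimum": {"x": dict(zip(space.names, x_opt)), "removal": removal_opt},
            "seeds": {"train": 7, "ga": 11},
        },
        ROOT / "ann_summary.json",
    )


if __name__ == "__main__":
    main()
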