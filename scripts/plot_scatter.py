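#!/usr/bin/env python
"""Scatter exports from a cohort observable table: tumor-vs-normal
Y and c_Hb per run, in the style of ensemble scatter comparisons.

    python scripts/plot_scatter.py --table results/observables.csv \
        --out scratch/scatter

Writes scatter_<x>_<y>.csv pairs and, when matplotlib is available, a
PNG alongside each.
"""

import argparse
import pathlib

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--table", required=True)
    ap.add_argument("--out", default="scratch/scatter")
    args = ap.parse_args()
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    df = pd.read_csv(args.table)
    norm = df[df["region"] == "normal_t0"].set_index("seed")
    tum = df[df["region"] == "tumor_sphere"].set_index("seed")
    common = norm.index.intersection(tum.index)
    for var in ("Y", "c_Hb", "rBV", "rBF"):
        if var not in df.columns:
            continue
        pairs = pd.DataFrame({f"{var}_normal": norm.loc[common, var],
                              f"{var}_tumor": tum.loc[common, var]})
        path = out / f"scatter_{var}.csv"
        pairs.to_csv(path)
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.scatter(pairs.iloc[:, 0], pairs.iloc[:, 1], s=18)
            lim = [pairs.min().min() * 0.9, pairs.max().max() * 1.1]
            ax.plot(lim, lim, "k--", lw=0.8)
            ax.set_xlabel(f"{var} (normal)")
            ax.set_ylabel(f"{var} (tumor)")
            fig.tight_layout()
            fig.savefig(path.with_suffix(".png"), dpi=150)
            plt.close(fig)
        except ImportError:
            pass
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
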