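#!/usr/bin/env python
"""Draw loop plots and H_A / H_mu distribution figures from a fitted network."""

import argparse
from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

from ch4hyst import analyze_dataset
from ch4hyst.pipeline import results_to_frame
from ch4hyst.plots import plot_hysteresis_distributions, plot_loop
from ch4hyst.synthetic import read_network


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic_network"))
    ap.add_argument("--out", type=Path, default=Path("results/figures"))
    ap.add_argument("--n-loops", type=int, default=6)
    args = ap.parse_args()

    dataset = read_network(args.data)
    results, day_table, _ = analyze_dataset(dataset)
    args.out.mkdir(parents=True, exist_ok=True)

    for r in results[: args.n_loops]:
        ax = plot_loop(r, day_table)
        ax.figure.tight_layout()
        ax.figure.savefig(args.out / f"loop_{r.site_id}_{r.season_year}.png", dpi=130)
        plt.close(ax.figure)

    frame = results_to_frame(results)
    axes = plot_hysteresis_distributions(frame)
    axes[0].figure.tight_layout()
    axes[0].figure.savefig(args.out / "hysteresis_distributions.png", dpi=130)
    print(f"wrote {min(args.n_loops, len(results))} loop plots and the "
          f"distribution figure to {args.out}")


if __name__ == "__main__":
    main()
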