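#!/usr/bin/env python
"""Plot the synapse-size distributions measured from the simulated volumes.

Reads the per-synapse CSVs from results/em_counts/ (04_count_synapses.py),
overlays the per-layer SAS area histograms with their fitted log-normal
densities, and writes results/size_distributions.png.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from synapcount import densify


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--counts", type=Path, default=Path("results/em_counts"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/size_distributions.png"))
    args = ap.parse_args()

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats

    files = sorted(args.counts.glob("*_synapses.csv"))
    fig, axes = plt.subplots(1, len(files), figsize=(4 * len(files), 3.2),
                             sharex=True, squeeze=False)
    for ax, path in zip(axes[0], files):
        df = pd.read_csv(path)
        areas = df.loc[df.type == "AS", "sas_area_um2"].to_numpy() * 1e6
        fit = densify.fit_lognormal(areas)
        ax.hist(areas / 1e6, bins=25, density=True, alpha=0.6,
                color="tab:green")
        grid = np.linspace(areas.min(), areas.max(), 300)
        pdf = stats.lognorm(s=fit.sigma, scale=np.exp(fit.mu)).pdf(grid)
        ax.plot(grid / 1e6, pdf * 1e6, "k-",
                label=f"log-normal\nmu={fit.mu:.2f}, sigma={fit.sigma:.2f}")
        ax.set_title(path.stem.replace("_synapses", ""))
        ax.set_xlabel("SAS area (um^2)")
        ax.legend(fontsize=8)
    axes[0][0].set_ylabel("density")
    fig.tight_layout()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(args.out, dpi=150)
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
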