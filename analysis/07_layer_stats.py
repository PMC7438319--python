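#!/usr/bin/env python
"""Compare per-stack synapse densities between layers.

Reads results/calibration.json (from 05_calibrate.py), runs the gated
omnibus comparison (ANOVA vs Kruskal-Wallis + Dunn) on the per-stack AS
densities, and writes results/layer_comparison.json.
"""

import argparse
import json
from pathlib import Path

from synapcount import statcmp


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--calibration", type=Path,
                    default=Path("results/calibration.json"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/layer_comparison.json"))
    args = ap.parse_args()

    report = json.loads(args.calibration.read_text())
    groups = {layer: [s["density_as"] for s in d["per_stack"]]
              for layer, d in report["layers"].items()}
    comp = statcmp.compare_groups(groups)
    result = statcmp.comparison_to_dict(comp)
    args.out.write_text(json.dumps(result, indent=2))
    print(f"{comp.test}: statistic={comp.statistic:.3f} "
          f"p={comp.p_value:.4f}")
    for p in comp.pairwise:
        print(f"  {p.group_a} vs {p.group_b}: p_adj={p.p_adjusted:.4f}")
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
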