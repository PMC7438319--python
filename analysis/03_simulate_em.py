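#!/usr/bin/env python
"""Render synthetic FIB-SEM-like labeled volumes for the three layers.

Writes one multipage TIFF + label-map JSON + ground-truth CSV per layer
under results/em/.
"""

import argparse
from pathlib import Path

from synapcount import refdata, synthgen
from synapcount.pipeline import stage_seed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/em"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    layers = refdata.CA1_LAYER_SUMMARY.query("layer != 'all'")
    for row in layers.itertuples():
        spec = synthgen.EmVolumeSpec(
            as_density=row.as_density,
            ss_density=round(row.as_density * 0.046, 4),
            seed=stage_seed(args.seed, f"em-demo-{row.layer}"))
        labels, truth = synthgen.make_em_volume(spec)
        path = args.out / f"{row.layer}.tif"
        synthgen.write_volume(path, labels, truth, spec)
        print(f"{row.layer}: {len(truth)} synapses "
              f"({(truth.type == 'AS').sum()} AS / "
              f"{(truth.type == 'SS').sum()} SS) in "
              f"{spec.volume_um3:.1f} um^3 -> {path}")


if __name__ == "__main__":
    main()
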