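#!/usr/bin/env python
"""Quantify cell shape anisotropy along the radius and find the transition.

Generates an ellipse cell field (180 cells in a 120 um section: tangential,
aspect ratio 2.25 outside R0/3; random orientation, 1.5 inside), measures
every cell by moment-based ellipse fitting, bins aspect ratio against
normalized radius and locates the high->low anisotropy change point.
"""

import argparse
from pathlib import Path

import numpy as np

from beadstress.anisotropy import anisotropy_profile, detect_transition, measure_cell_field
from beadstress.imaging import SpheroidGeometry
from beadstress.synthetic import make_cell_field

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cells", type=int, default=180)
    ap.add_argument("--bins", type=int, default=9)
    args = ap.parse_args()

    labels, truth = make_cell_field(120.0, args.n_cells, seed=args.seed)
    npx = labels.shape[0]
    geom = SpheroidGeometry(
        center=(npx / 2.0, npx / 2.0, 0.0), radius=120.0,
        contour_area=float(np.pi * 120.0**2),
    )
    shapes = measure_cell_field(labels, geom, pixel_size=1.0)
    prof = anisotropy_profile(shapes, n_bins=args.bins)
    res = detect_transition(prof)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    prof.bins.to_csv(results / "anisotropy_profile.csv", index=False)

    outer = prof.bins[prof.bins["r_norm"] > 0.5]["value"].mean()
    inner = prof.bins["value"].iloc[0]
    print(f"{len(shapes)} cells measured")
    print(f"outer-shell mean aspect ratio: {outer:.2f} (generated 2.25)")
    print(f"innermost-bin mean aspect ratio: {inner:.2f} (generated 1.50)")
    if res.r_transition is None:
        print("no significant anisotropy transition detected")
    else:
        print(f"anisotropy transition at r/R0 = {res.r_transition:.3f} "
              f"(generated 0.333; variance reduction {res.variance_reduction:.0%})")
    print(f"profile written to {results/'anisotropy_profile.csv'}")


if __name__ == "__main__":
    main()
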