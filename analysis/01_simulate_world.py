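"""Generate the synthetic study world and write its artifacts.

Builds the default 50x50 gridded world — survey table, three cover
products, three age products, climate fields and deltas, suitability
surfaces with MTSS thresholds, CO2 trajectories, cVeg ensemble, area
targets — and reports the headline facts of the landscape.
"""

import argparse
from pathlib import Path

import numpy as np

from forestcarbon.grids import total_area_mha
from forestcarbon.synthetic import SyntheticConfig, generate_world, write_world


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/world"))
    args = ap.parse_args()

    cfg = SyntheticConfig(seed=args.seed)
    world = generate_world(cfg)
    write_world(world, args.out)

    fmask = world.truth["forest_mask"]
    domain = total_area_mha(np.ones(world.grid.shape, bool), world.grid)
    forest = total_area_mha(fmask, world.grid)
    print(f"world: {world.grid.rows}x{world.grid.cols} cells, "
          f"{domain:.1f} Mha domain, {forest:.1f} Mha true forest "
          f"({forest / domain:.0%})")
    print(f"survey: {len(world.survey)} records over {cfg.n_types} types, "
          f"noise sd {cfg.survey_noise_sd} Mg/ha")
    print(f"cover products: pairwise disagreement target "
          f"{cfg.product_disagreement_rate:.0%} (per-product flip rate "
          f"{world.truth['flip_rate']:.3f})")
    print(f"artifacts written to {args.out}")


if __name__ == "__main__":
    main()
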