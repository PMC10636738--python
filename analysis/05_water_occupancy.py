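#!/usr/bin/env python
"""Active-site water occupancy on a synthetic trajectory.

Generates 10,000 frames in which a water oxygen enters the 2 Å probe
sphere (midpoint between the anomeric carbon and the acid/base
carboxylate group) with per-frame probability 0.75 — the occupancy regime
that licenses the hydrolytic second step — and recovers the occupancy
fraction and count histogram from the frames alone.
"""

import argparse
from pathlib import Path

import numpy as np

from glycopucker.pipeline import water_occupancy_recovery

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main(seed: int = 0) -> None:
    res = water_occupancy_recovery(p_occupancy=0.75, n_frames=10_000, seed=seed)
    p, n = res["p_true"], res["n_frames"]
    sigma = np.sqrt(p * (1 - p) / n)
    print(f"designed occupancy p = {p}; estimated {res['fraction']:.4f} "
          f"over {n} frames (binomial sigma {sigma:.4f})")
    print(f"generator truth fraction: {res['truth_fraction']:.4f}")
    out = RESULTS / "water_occupancy.tsv"
    with open(out, "w") as fh:
        fh.write(f"# occupancy fraction {res['fraction']:.6f} over {n} frames\n")
        fh.write("waters_in_sphere\tframes\n")
        for count, frames in sorted(res["histogram"].items()):
            fh.write(f"{count}\t{frames}\n")
    print(f"histogram -> {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(**vars(ap.parse_args()))
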