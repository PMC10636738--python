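#!/usr/bin/env python
"""Build the canonical conformer catalog and classify reference geometries.

Generates the 38-conformer catalog from idealized geometries, writes it as
a table, and classifies two reference rings: an ideal 4C1 chair (the
ground-state sugar conformation) and a ring at the boat/twist-boat midpoint
(the preactivated conformation seen in the substrate complex, intermediate
between 1,4B and 1S3).
"""

from pathlib import Path

from glycopucker.catalog import classify_conformation, generate_conformer_catalog
from glycopucker.ring import build_ideal_ring, compute_cremer_pople

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    catalog = generate_conformer_catalog(Q_ref=0.55)
    out = RESULTS / "conformer_catalog.tsv"
    with open(out, "w") as fh:
        fh.write("label\ttheta_deg\tphi_deg\tfamily\n")
        for e in catalog:
            fh.write(f"{e.label}\t{e.theta_ref:.4f}\t{e.phi_ref:.4f}\t{e.family}\n")
    print(f"catalog: {len(catalog)} conformers -> {out}")

    for name, (theta, phi) in {
        "ideal chair": (0.0, 0.0),
        "preactivated boat/twist midpoint": (90.0, 225.0),
        "envelope transition-state region": (54.7356, 240.0),
    }.items():
        p = compute_cremer_pople(build_ideal_ring(0.55, theta, phi))
        asg = classify_conformation(p, catalog)
        print(
            f"{name}: theta={p.theta:7.2f} phi={p.phi:7.2f} -> {asg.label} "
            f"(d={asg.distance_deg:.2f} deg; runner-up {asg.runner_up} "
            f"at {asg.runner_up_distance_deg:.2f} deg)"
        )


if __name__ == "__main__":
    main()
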