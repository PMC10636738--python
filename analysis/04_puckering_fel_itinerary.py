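#!/usr/bin/env python
"""Conformational landscape and itinerary on a designed puckering FEL.

Builds a free-energy surface over the Cremer–Pople angles with a basin at
the preactivated boat/twist midpoint (between 1,4B and 1S3), a slightly
higher basin at the 4C1 chair, and a designed saddle at the 4E envelope.
Runs the landscape analysis — minima, minimax barrier, minimum-energy
path, itinerary — and exports the Mercator representation with
1 kcal/mol isolines.  Also measures the energy of the 4E/4H5 region on a
variant surface with a 4.5 kcal/mol shelf there (the penalty regime
reported for envelope/half-chair conformations trapped in inactive-mutant
structures).
"""

from pathlib import Path

from glycopucker.fes import export_mercator, minimum_energy_path, region_energy
from glycopucker.io import write_fes
from glycopucker.pipeline import designed_fel_itinerary
from glycopucker.synthetic import Basin, FELSpec, make_fel

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    res = designed_fel_itinerary(saddle_energy=5.0, chair_offset=0.5)
    fes = res["fes"]
    write_fes(fes, RESULTS / "puckering_fel.dat")
    for m in res["minima"]:
        print(f"minimum at phi={m.location[0]:.1f}, theta={m.location[1]:.1f}: "
              f"{m.energy:.2f} kcal/mol")
    print(f"minimax barrier boat->chair: {res['barrier']:.2f} kcal/mol "
          f"(saddle at phi={res['saddle'].location[0]:.1f}, "
          f"theta={res['saddle'].location[1]:.1f})")
    print("itinerary (ring opening direction):", res["itinerary_forward"])
    print("itinerary (cyclization direction): ", res["itinerary_reverse"])

    path = minimum_energy_path(fes, res["minima"][0], res["minima"][1])
    export_mercator(
        fes,
        isoline_step=1.0,
        png_path=str(RESULTS / "puckering_fel_mercator.png"),
        data_path=str(RESULTS / "puckering_fel_mercator.tsv"),
        path=path,
    )
    print(f"Mercator plot -> {RESULTS / 'puckering_fel_mercator.png'} (isolines 1 kcal/mol)")

    shelf, _ = make_fel(FELSpec(
        basins=(Basin("1,4B/1S3", 0.0), Basin("4C1", 0.5)), saddle=("4E", 4.5)
    ))
    e4 = region_energy(shelf, "4E", radius_deg=3.0)
    h45 = region_energy(shelf, "4H5", radius_deg=3.0)
    print(f"shelf surface: 4E region {e4:.2f} kcal/mol, 4H5 region {h45:.2f} kcal/mol "
          "above the global minimum")


if __name__ == "__main__":
    main()
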