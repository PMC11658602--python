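#!/usr/bin/env python
"""Generate the three depot phantom geometries and tabulate their ground
truth.

An ellipsoidal depot (the well-localized single-end-hole injection case), a
lobed depot (multi-hole / multi-prong spread), and a branched-leak depot
(gel intravasation into vessels) are rendered as CT-like volumes with iodine
encoded linearly in HU. The table written to results/phantom_truth.csv is
the reference everything downstream is checked against.
"""

import sys
from pathlib import Path

import pandas as pd

from depotkit.phantoms import DepotSpec, make_depot_phantom

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for shape in ("ellipsoid", "lobed", "branched-leak"):
        vol, truth = make_depot_phantom(DepotSpec(shape=shape, spacing=0.75, seed=SEED))
        rows.append(
            {
                "shape": shape,
                "grid": "x".join(map(str, vol.shape)),
                "spacing_mm": vol.spacing[0],
                "true_volume_ml": truth.volume_ml,
                "true_surface_cm2": truth.surface_area_cm2,
                "hu_min": vol.values.min(),
                "hu_max": vol.values.max(),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "phantom_truth.csv", index=False, float_format="%.6g")
    print(df.to_string(index=False))
    print(
        "\nEllipsoid truth is analytic (4/3 pi abc); composite shapes carry "
        "their voxelized analytic mask as truth. 40 mg/mL maps to "
        f"{rows[0]['hu_max']:.0f} HU at the depot core."
    )


if __name__ == "__main__":
    main()
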