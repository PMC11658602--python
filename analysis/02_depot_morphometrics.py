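#!/usr/bin/env python
"""3D and 2D morphometrics of the three depot geometries.

Segments each phantom by HU thresholding and computes the descriptor panel
(volume, surface area, sphericity, solidity, SA/V, radiodensity; and on the
mid-coronal slice: area, axes, perimeter, circularity, 2D solidity). The
expected ordering — ellipsoid most spherical and most solid, branched-leak
least solid — mirrors how depot leakage reads out in these metrics.
"""

import sys
from pathlib import Path

import pandas as pd

from depotkit.morphometrics import metrics2d, metrics3d
from depotkit.phantoms import DepotSpec, make_depot_phantom
from depotkit.volumetric import segment_depot

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows3d, rows2d = [], []
    for shape in ("ellipsoid", "lobed", "branched-leak"):
        vol, truth = make_depot_phantom(DepotSpec(shape=shape, spacing=0.75, seed=SEED))
        mask = segment_depot(vol, 300.0, 2000.0)
        m3 = metrics3d(mask, vol)
        rows3d.append({"shape": shape, **m3.as_dict(), "true_volume_ml": truth.volume_ml})
        mid = mask.values[:, mask.shape[1] // 2, :]
        if mid.any():
            rows2d.append({"shape": shape, **metrics2d(mid, mask.spacing[0]).as_dict()})
    df3, df2 = pd.DataFrame(rows3d), pd.DataFrame(rows2d)
    df3.to_csv(OUT / "morphometrics_3d.csv", index=False, float_format="%.6g")
    df2.to_csv(OUT / "morphometrics_2d.csv", index=False, float_format="%.6g")
    print(df3[["shape", "volume_ml", "surface_area_cm2", "sphericity", "solidity", "sa_v_cm1"]].to_string(index=False))
    print()
    print(df2.to_string(index=False))
    sol = df3.set_index("shape")["solidity"]
    print(
        f"\nSolidity ordering ellipsoid ({sol['ellipsoid']:.2f}) > lobed "
        f"({sol['lobed']:.2f}) > branched-leak ({sol['branched-leak']:.2f}): "
        "vessel-leak branches inflate the convex hull faster than the volume."
    )


if __name__ == "__main__":
    main()
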