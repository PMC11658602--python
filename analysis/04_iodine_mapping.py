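#!/usr/bin/env python
"""Relative iodine concentration mapping over time.

Maps the mid-coronal HU slice of a radial-gaussian depot to concentration,
emulates post-injection diffusion by progressive smoothing, and tracks the
cross-sectional area of the three concentration ranges (7-13.4, 13.4-27,
27-40 mg/mL) plus their trapezoidal AUC over 4 h, and a normalized-distance
line profile through the depot.
"""

import sys
from pathlib import Path

import pandas as pd
from scipy.ndimage import gaussian_filter

from depotkit.iodine import hu_to_iodine, line_profile, range_areas, temporal_range_auc
from depotkit.phantoms import DepotSpec, make_depot_phantom

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
TIMES = (0.0, 30.0, 60.0, 120.0, 180.0, 240.0)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    vol, _ = make_depot_phantom(
        DepotSpec(concentration_profile="radial-gaussian", spacing=0.75, seed=SEED)
    )
    k = vol.shape[0] // 2
    rows, series = [], []
    for i, t in enumerate(TIMES):
        hu = vol.values[k] if i == 0 else gaussian_filter(vol.values[k], sigma=0.35 * i)
        imap = hu_to_iodine(hu, 50.0, 1050.0, spacing=vol.spacing[1:])
        ras = range_areas(imap, timepoint_min=t)
        series.append(ras)
        for rng, area in zip(ras.ranges, ras.areas_cm2):
            rows.append({"time_min": t, "range_mg_ml": f"{rng[0]}-{rng[1]}", "area_cm2": area})
    areas = pd.DataFrame(rows)
    areas.to_csv(OUT / "iodine_range_areas.csv", index=False, float_format="%.6g")
    print(areas.pivot(index="time_min", columns="range_mg_ml", values="area_cm2").to_string())

    aucs = temporal_range_auc(series)
    auc_df = pd.DataFrame([{"range_mg_ml": f"{lo}-{hi}", "auc_au": v} for (lo, hi), v in aucs.items()])
    auc_df.to_csv(OUT / "iodine_range_auc.csv", index=False, float_format="%.6g")
    print()
    print(auc_df.to_string(index=False))

    imap0 = hu_to_iodine(vol.values[k], 50.0, 1050.0, spacing=vol.spacing[1:])
    ny, nx = imap0.concentration.shape
    prof = line_profile(
        imap0,
        ((ny // 2 * vol.spacing[1], 0.0), (ny // 2 * vol.spacing[1], (nx - 1) * vol.spacing[2])),
    )
    pd.DataFrame({"position": prof.positions, "conc_mg_ml": prof.concentrations}).to_csv(
        OUT / "iodine_line_profile.csv", index=False, float_format="%.6g"
    )
    top = [s.areas_cm2[2] for s in series]
    print(
        f"\nLine-profile AUC over normalized distance: {prof.auc:.1f} mg/mL "
        "(40.0 would be a depot at the ceiling across the whole segment). "
        f"The 27-40 mg/mL area declines {top[0]:.2f} -> {top[-1]:.2f} cm^2 as "
        "smoothing spreads the concentrated core into the lower ranges — the "
        "readout a diffusing depot produces."
    )


if __name__ == "__main__":
    main()
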