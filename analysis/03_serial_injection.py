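#!/usr/bin/env python
"""Serial per-mL injection analysis and post-injection volume decay.

Renders the growing depot at cumulative 1, 2, 3 and 4 mL on a common grid,
differences consecutive masks to recover the per-mL increments, and then
emulates the post-injection phase as a shrinking series to exercise the
percent-of-initial-volume readout (a 26.6% loss over 4 h is the regime
reported for gel depots in liver).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from depotkit.morphometrics import volume_percent
from depotkit.phantoms import DepotSpec, make_depot_phantom
from depotkit.volumetric import BinaryMask, serial_increments

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    # nested balls with analytic volumes 1..4 mL on one shared grid
    spacing = 0.6
    radii = [(3 * v * 1000 / (4 * np.pi)) ** (1 / 3) for v in (1.0, 2.0, 3.0, 4.0)]
    n = int(np.ceil((max(radii) + 2) / spacing))
    ax = np.arange(-n, n + 1) * spacing
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = x**2 + y**2 + z**2
    masks = [BinaryMask(r2 <= r**2, (spacing,) * 3) for r in radii]
    incs = serial_increments(masks)
    df = pd.DataFrame(
        {
            "injected_ml": [1, 2, 3, 4],
            "cumulative_ml": [m.volume_ml for m in masks],
            "increment_ml": [masks[0].volume_ml] + [i.volume_ml for i in incs],
        }
    )
    df.to_csv(OUT / "serial_increments.csv", index=False, float_format="%.6g")
    print(df.to_string(index=False))

    # post-injection decay: 26.6% total volume loss over 240 min
    times = [0, 30, 60, 90, 120, 180, 240]
    v0 = masks[-1].volume_ml
    loss = 0.266
    vols = [v0 * (1 - loss * t / times[-1]) for t in times]
    pct = volume_percent(vols)
    decay = pd.DataFrame({"time_min": times, "volume_ml": vols, "volume_pct": pct})
    decay.to_csv(OUT / "volume_percent.csv", index=False, float_format="%.6g")
    print()
    print(decay.to_string(index=False))
    print(f"\nEach increment recovers ~1 mL (max dev {np.abs(df.increment_ml - 1).max():.3f} mL); "
          f"final volume {pct[-1]:.1f}% of the 0-min depot.")


if __name__ == "__main__":
    main()
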