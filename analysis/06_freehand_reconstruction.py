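#!/usr/bin/env python
"""Freehand 3D reconstruction from tracked 2D sweeps.

Sweeps a ball phantom with parallel tracked frames at several step sizes,
splats them into a 3D grid, re-segments the depot and compares its volume to
the analytic truth — quantifying how sweep density limits volumetry without
ionizing imaging.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from depotkit.phantoms import DepotSpec, SpeckleParams, make_depot_phantom, make_us_frames, sweep_poses
from depotkit.volumetric import reconstruct_volume, segment_depot

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    vol, truth = make_depot_phantom(
        DepotSpec(semi_axes=(10.0, 10.0, 10.0), spacing=0.75, margin=5.0, seed=SEED)
    )
    rows = []
    for step in (0.75, 1.0, 2.0, 3.0):
        nz = vol.shape[0] * vol.spacing[0]
        poses = sweep_poses(int(np.ceil(nz / step)) + 1, step, vol.spacing[2], (vol.origin[0], vol.origin[1], vol.origin[2]))
        frames = make_us_frames(vol, poses, SpeckleParams(enabled=False), frame_shape=vol.shape[1:])
        recon, visited = reconstruct_volume(frames, out_spacing=0.75)
        mask = segment_depot(recon, 130.0, 300.0)
        rows.append(
            {
                "step_mm": step,
                "n_frames": len(frames),
                "reconstructed_ml": mask.volume_ml,
                "true_ml": truth.volume_ml,
                "rel_error_pct": abs(mask.volume_ml - truth.volume_ml) / truth.volume_ml * 100,
                "visited_fraction": float(visited.values.mean()),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "reconstruction_density.csv", index=False, float_format="%.6g")
    print(df.to_string(index=False))
    print(
        f"\nDense sweeps recover the depot within {df.rel_error_pct.iloc[0]:.1f}%; "
        "coarse sweeps leave unvisited gaps and systematically underestimate."
    )


if __name__ == "__main__":
    main()
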