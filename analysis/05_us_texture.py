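#!/usr/bin/env python
"""B-mode texture time-course of a depot losing echogenicity.

Synthesizes speckled frames of the depot with the hyperechoic level decaying
over 4 h (microbubble washout), then computes acoustic intensity,
heterogeneity and histogram entropy in the depot ROI together with the 2D
shape panel per timepoint.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from depotkit.morphometrics import metrics2d
from depotkit.phantoms import DepotSpec, SpeckleParams, make_depot_phantom, make_us_frames, sweep_poses
from depotkit.texture import texture_metrics

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
TIMES = (0.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    vol, truth = make_depot_phantom(DepotSpec(spacing=0.75, seed=SEED))
    k = vol.shape[0] // 2
    roi = truth.mask.values[k]
    rng = np.random.default_rng(SEED)
    rows = []
    for t in TIMES:
        decay = float(np.exp(-t / 150.0))
        frames = make_us_frames(
            vol,
            sweep_poses(1, 1.0, vol.spacing[2], (vol.origin[0], vol.origin[1], vol.origin[2] + k * vol.spacing[0])),
            SpeckleParams(depot_level=60.0 + 140.0 * decay, seed=int(rng.integers(2**31))),
            frame_shape=roi.shape,
        )
        rows.append({**texture_metrics(frames[0].image, roi, timepoint_min=t), **metrics2d(roi, vol.spacing[1]).as_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "us_texture_timecourse.csv", index=False, float_format="%.6g")
    print(df[["timepoint_min", "acoustic_intensity", "heterogeneity", "entropy_bits", "area_cm2"]].to_string(index=False))
    print(
        f"\nIntensity decays {df.acoustic_intensity.iloc[0]:.1f} -> "
        f"{df.acoustic_intensity.iloc[-1]:.1f} a.u. as the depot washes out; "
        "entropy stays in the 6-8 bit speckle band throughout."
    )


if __name__ == "__main__":
    main()
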