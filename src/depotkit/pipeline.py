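"""Configuration-driven orchestration of the full analysis.

One RunConfig (usually read from YAML) drives every stage: phantom
generation, depot segmentation and 3D/2D morphometrics, serial per-mL
differencing, iodine-range mapping and temporal AUC, B-mode texture
time-courses, freehand 3D reconstruction, and plasma NCA with
biodistribution folds. Every otherwise-unpinned constant (HU window, iodine
boundaries, phase windows, histogram levels) surfaces here.

Stages are isolated: a failing stage is marked failed in the manifest and
the rest still run. For a fixed seed the whole bundle is byte-stable, which
the manifest records via a config hash.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidSpec
from .iodine import DEFAULT_RANGES, hu_to_iodine, line_profile, range_areas, temporal_range_auc
from .morphometrics import metrics2d, metrics3d, volume_percent
from .phantoms import (
    DepotSpec,
    PlasmaSimSpec,
    SpeckleParams,
    make_depot_phantom,
    make_us_frames,
    simulate_biodistribution,
    simulate_plasma,
    sweep_poses,
)
from .pk import PlasmaSeries, cohort_summary, fold_ratio, nca
from .texture import texture_metrics
from .volumetric import read_volume, reconstruct_volume, segment_depot, write_volume

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    mode: str = "synthetic"  # synthetic | files
    seed: int = 0
    output_dir: str = "depotkit_run"
    # thresholds
    hu_range: tuple[float, float] = (300.0, 2000.0)
    iodine_ranges: tuple = DEFAULT_RANGES
    hu_baseline: float = 50.0
    hu_at_cmax: float = 1050.0
    entropy_levels: int = 256
    # pk
    dose_mg: float = 40.0
    phase_windows: str | tuple = "auto"
    # synthetic-mode scale (isotropic phantom spacing, mm)
    phantom_spacing: float = 0.75
    timepoints_min: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0)
    n_animals: int = 3
    plasma_noise_cv: float = 0.05
    # files mode inputs
    ct_volume_path: str | None = None
    plasma_csv_path: str | None = None
    save_volumes: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.mode not in ("synthetic", "files"):
            raise InvalidSpec(f"unknown mode: {cfg.mode}")
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        is deliberately excluded: two runs of one config into different
        directories are the same analysis)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _stage(manifest: dict, name: str, fn, log: list[str]) -> None:
    try:
        fn()
        manifest["stages"][name] = "passed"
        log.append(f"stage {name}: passed")
    except Exception as exc:  # stage isolation: record, keep going
        manifest["stages"][name] = "failed"
        log.append(f"stage {name}: FAILED ({type(exc).__name__}: {exc})")
        log.append(traceback.format_exc(limit=3))


def run(config: RunConfig) -> dict:
    """Execute every configured stage; returns the manifest dict (also
    written to ``manifest.json`` in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "stages": {},
    }
    log: list[str] = [f"depotkit {__version__} run, mode={config.mode}, seed={config.seed}"]

    if config.mode == "synthetic":
        _run_synthetic(config, out, manifest, log)
    else:
        _run_files(config, out, manifest, log)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (out / "run.log").write_text("\n".join(log) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# synthetic mode


def _run_synthetic(config: RunConfig, out: Path, manifest: dict, log: list[str]) -> None:
    seeds = np.random.SeedSequence(config.seed).generate_state(8)

    state: dict = {}

    def stage_phantom():
        spec = DepotSpec(spacing=config.phantom_spacing, seed=int(seeds[0]) % 2**31)
        vol, truth = make_depot_phantom(spec)
        mask = segment_depot(vol, *config.hu_range)
        m3 = metrics3d(mask, vol)
        df = pd.DataFrame([{"depot": "ellipsoid_4mL", **m3.as_dict(), "true_volume_ml": truth.volume_ml}])
        _write_csv(df, out / "morphometrics_3d.csv")
        state["volume"] = vol
        state["mask"] = mask
        if config.save_volumes:
            write_volume(vol, out / "phantom.nii.gz")

    def stage_morph2d():
        mask = state["mask"]
        mid = mask.values[:, mask.shape[1] // 2, :]  # coronal-style mid slice
        m2 = metrics2d(mid, mask.spacing[0])
        _write_csv(pd.DataFrame([m2.as_dict()]), out / "morphometrics_2d.csv")

    def stage_serial():
        # nested growing depot: cumulative 1..4 mL rendered by scaling the
        # semi-axes so each step's analytic volume hits the injected volume
        base = DepotSpec(spacing=config.phantom_spacing, seed=int(seeds[1]) % 2**31)
        v_base_ml = 4.0 / 3.0 * np.pi * np.prod(base.semi_axes) / 1000.0
        masks = []
        targets_ml = (1.0, 2.0, 3.0, 4.0)
        for v in targets_ml:
            s = DepotSpec(
                semi_axes=tuple(a * (v / v_base_ml) ** (1 / 3) for a in base.semi_axes),
                spacing=config.phantom_spacing,
                seed=base.seed,
            )
            vol_i, truth_i = make_depot_phantom(s)
            masks.append(truth_i.mask)
        vols = [m.volume_ml for m in masks]
        incs = np.diff([0.0] + vols)
        _write_csv(
            pd.DataFrame({"injected_ml": targets_ml, "cumulative_ml": vols, "increment_ml": incs}),
            out / "serial_increments.csv",
        )

    def stage_iodine():
        spec = DepotSpec(
            concentration_profile="radial-gaussian",
            spacing=config.phantom_spacing,
            seed=int(seeds[2]) % 2**31,
        )
        vol, truth = make_depot_phantom(spec)
        k_mid = vol.shape[0] // 2
        rows = []
        series = []
        for i, t in enumerate(config.timepoints_min):
            # emulate diffusion by progressive smoothing of the HU slice
            hu_slice = vol.values[k_mid]
            if i > 0:
                from scipy.ndimage import gaussian_filter

                hu_slice = gaussian_filter(hu_slice, sigma=0.6 * i)
            imap = hu_to_iodine(
                hu_slice, config.hu_baseline, config.hu_at_cmax, spacing=vol.spacing[1:]
            )
            ras = range_areas(imap, timepoint_min=t, ranges=config.iodine_ranges)
            series.append(ras)
            for rng, area in zip(ras.ranges, ras.areas_cm2):
                rows.append({"timepoint_min": t, "range_mg_ml": f"{rng[0]}-{rng[1]}", "area_cm2": area})
        _write_csv(pd.DataFrame(rows), out / "iodine_range_areas.csv")
        aucs = temporal_range_auc(series)
        _write_csv(
            pd.DataFrame(
                [{"range_mg_ml": f"{lo}-{hi}", "auc_au": v} for (lo, hi), v in aucs.items()]
            ),
            out / "iodine_range_auc.csv",
        )
        imap0 = hu_to_iodine(vol.values[k_mid], config.hu_baseline, config.hu_at_cmax, spacing=vol.spacing[1:])
        ny, nx = imap0.concentration.shape
        prof = line_profile(
            imap0,
            ((ny // 2 * vol.spacing[1], 0.0), (ny // 2 * vol.spacing[1], (nx - 1) * vol.spacing[2])),
        )
        _write_csv(
            pd.DataFrame({"position": prof.positions, "conc_mg_ml": prof.concentrations}),
            out / "iodine_line_profile.csv",
        )

    def stage_texture():
        vol = state["volume"]
        mask = state["mask"]
        k_mid = vol.shape[0] // 2
        roi = mask.values[k_mid]
        rng = np.random.default_rng(int(seeds[3]) % 2**31)
        rows = []
        for i, t in enumerate(config.timepoints_min):
            decay = float(np.exp(-t / 150.0))  # echogenicity loss over time
            frames = make_us_frames(
                vol,
                sweep_poses(1, 1.0, vol.spacing[2], (vol.origin[0], vol.origin[1], vol.origin[2] + k_mid * vol.spacing[0])),
                SpeckleParams(depot_level=60.0 + 140.0 * decay, seed=int(rng.integers(2**31))),
                frame_shape=roi.shape,
            )
            m = texture_metrics(frames[0].image, roi, timepoint_min=t, levels=config.entropy_levels)
            m2 = metrics2d(roi, vol.spacing[1])
            rows.append({**m, **m2.as_dict()})
        _write_csv(pd.DataFrame(rows), out / "us_texture_timecourse.csv")

    def stage_reconstruction():
        vol = state["volume"]
        n = int(np.ceil(vol.shape[0] * vol.spacing[0]))
        poses = sweep_poses(n, 1.0, vol.spacing[2], (vol.origin[0], vol.origin[1], vol.origin[2]))
        frames = make_us_frames(vol, poses, SpeckleParams(enabled=False), frame_shape=vol.shape[1:])
        recon, visited = reconstruct_volume(frames, out_spacing=1.0)
        level = (60.0 + 200.0) / 2.0
        rmask = segment_depot(recon, level, 300.0)
        true_ml = state["mask"].volume_ml
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "reconstructed_ml": rmask.volume_ml,
                        "reference_ml": true_ml,
                        "rel_error": abs(rmask.volume_ml - true_ml) / true_ml,
                        "visited_fraction": float(visited.values.mean()),
                    }
                ]
            ),
            out / "us_reconstruction.csv",
        )

    def stage_pk():
        rows_params = []
        arms = {
            "depot": PlasmaSimSpec(noise_cv=config.plasma_noise_cv),
            "free": PlasmaSimSpec(
                # free solution: faster systemic exposure, higher Cmax regime
                v_central_ml=8200.0 / 2.6,
                k12=0.05,
                noise_cv=config.plasma_noise_cv,
            ),
        }
        summaries = {}
        arm_offset = {"depot": 0, "free": 500}
        for arm, base in arms.items():
            per_animal = []
            for a in range(config.n_animals):
                spec = PlasmaSimSpec(
                    **{
                        **{k: getattr(base, k) for k in (
                            "dose_mg", "infusion_duration_min", "v_central_ml",
                            "k10", "k12", "k21", "sampling_times", "noise_cv",
                        )},
                        "seed": (int(seeds[4]) + arm_offset[arm] + a) % 2**31,
                    }
                )
                series, _ = simulate_plasma(spec)
                p = nca(series, dose_mg=config.dose_mg, phase_windows=config.phase_windows)
                per_animal.append(p)
                rows_params.append({"arm": arm, "animal": a, **p.as_dict()})
            summaries[arm] = cohort_summary(per_animal)
            _write_csv(summaries[arm], out / f"pk_cohort_{arm}.csv")
        _write_csv(pd.DataFrame(rows_params), out / "pk_per_animal.csv")
        mean = lambda arm, key: float(
            summaries[arm].set_index("parameter").loc[key, "mean"]
        )
        folds = pd.DataFrame(
            [
                {
                    "quantity": "auc_total_fold_free_over_depot",
                    "value": fold_ratio(mean("free", "auc_total"), mean("depot", "auc_total")),
                },
                {
                    "quantity": "auc_administration_fold_free_over_depot",
                    "value": fold_ratio(
                        mean("free", "auc_administration"), mean("depot", "auc_administration")
                    ),
                },
            ]
        )
        _write_csv(folds, out / "pk_fold_ratios.csv")
        bio = simulate_biodistribution(
            localization_factor={"heart": 8.0, "kidney": 2.0, "spleen": 3.0, "liver_distant": 4.0},
            seed=int(seeds[5]) % 2**31,
            n_animals=config.n_animals,
        )
        _write_csv(bio, out / "biodistribution.csv")
        g = bio.groupby(["organ", "formulation"])["conc_ng_per_mg"].mean().unstack()
        folds_bio = pd.DataFrame(
            {
                "organ": g.index,
                "fold_free_over_depot": [fold_ratio(g.loc[o, "free"], g.loc[o, "depot"]) for o in g.index],
            }
        )
        _write_csv(folds_bio, out / "biodistribution_folds.csv")

    _stage(manifest, "phantom_3d", stage_phantom, log)
    _stage(manifest, "morphometrics_2d", stage_morph2d, log)
    _stage(manifest, "serial_increments", stage_serial, log)
    _stage(manifest, "iodine", stage_iodine, log)
    _stage(manifest, "us_texture", stage_texture, log)
    _stage(manifest, "us_reconstruction", stage_reconstruction, log)
    _stage(manifest, "pk", stage_pk, log)


# ---------------------------------------------------------------------------
# files mode


def _run_files(config: RunConfig, out: Path, manifest: dict, log: list[str]) -> None:
    def stage_ct():
        if not config.ct_volume_path:
            raise InvalidSpec("no CT volume supplied")
        vol = read_volume(config.ct_volume_path)
        mask = segment_depot(vol, *config.hu_range)
        _write_csv(pd.DataFrame([metrics3d(mask, vol).as_dict()]), out / "morphometrics_3d.csv")

    def stage_pk():
        if not config.plasma_csv_path:
            raise InvalidSpec("no plasma CSV supplied")
        df = pd.read_csv(config.plasma_csv_path)
        per_animal = []
        rows = []
        for animal, sub in df.groupby("animal_id"):
            series = PlasmaSeries(
                sub["time_min"].to_numpy(), sub["conc_ng_per_ml"].to_numpy()
            )
            p = nca(series, dose_mg=config.dose_mg, phase_windows=config.phase_windows)
            per_animal.append(p)
            rows.append({"animal_id": animal, **p.as_dict()})
        _write_csv(pd.DataFrame(rows), out / "pk_per_animal.csv")
        _write_csv(cohort_summary(per_animal), out / "pk_cohort.csv")

    _stage(manifest, "ct_morphometrics", stage_ct, log)
    _stage(manifest, "pk", stage_pk, log)
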