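"""Voxel containers, file I/O, segmentation, serial differencing and freehand
3D reconstruction.

Conventions
-----------
Arrays are indexed ``[k, j, i]`` with ``i`` the fastest axis; the physical
axes are right-handed millimetres with ``i <-> x``, ``j <-> y``, ``k <-> z``.
``spacing`` and ``origin`` are stored in *array* order ``(z, y, x)``; world
points handed to poses, meshes and profiles are in ``(x, y, z)`` order.
Masks always carry the geometry of the volume they were derived from.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import EmptyReconstruction, InvalidSpec, NoDepotFound

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "TrackedFrame",
    "segment_depot",
    "serial_increments",
    "reconstruct_volume",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "write_poses_csv",
    "read_poses_csv",
]

MM3_PER_ML = 1000.0


@dataclass
class _Grid:
    values: np.ndarray
    spacing: tuple[float, float, float]  # mm per axis, array order (z, y, x)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # world mm (x, y, z)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.values.ndim != 3:
            raise InvalidSpec("expected a 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise InvalidSpec("grid spacing must be positive on every axis")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def index_to_world(self, kji: np.ndarray) -> np.ndarray:
        """Continuous array indices (k, j, i) -> world points (x, y, z) mm."""
        kji = np.atleast_2d(np.asarray(kji, dtype=float))
        zyx = kji * np.asarray(self.spacing)
        return zyx[:, ::-1] + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """World points (x, y, z) mm -> continuous array indices (k, j, i)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        zyx = (xyz - np.asarray(self.origin))[:, ::-1]
        return zyx / np.asarray(self.spacing)

    def same_geometry(self, other: "_Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class VoxelVolume(_Grid):
    """Anisotropic 3D scalar grid in Hounsfield units."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(float, copy=False)
        if not np.all(np.isfinite(self.values)):
            raise InvalidSpec("volume contains non-finite values")


@dataclass
class BinaryMask(_Grid):
    """Boolean grid sharing the geometry of its source volume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(bool, copy=False)

    @property
    def volume_mm3(self) -> float:
        return float(self.values.sum()) * self.voxel_volume_mm3

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / MM3_PER_ML


@dataclass
class TrackedFrame:
    """A 2D grayscale frame with a rigid pose into world millimetres.

    ``pose_rotation`` columns are the world directions of the frame's column
    (u), row (v) and out-of-plane (w) axes; a pixel at (row, col) maps to
    ``translation + col * pixel_spacing * u + row * pixel_spacing * v``.
    """

    image: np.ndarray
    pixel_spacing: float  # mm, isotropic in-plane
    pose_rotation: np.ndarray  # 3x3, orthonormal, det +1
    pose_translation: np.ndarray  # (3,) world mm (x, y, z)
    empty: bool = False
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.pose_rotation = np.asarray(self.pose_rotation, dtype=float)
        self.pose_translation = np.asarray(self.pose_translation, dtype=float)
        if self.image.ndim != 2:
            raise InvalidSpec("frame image must be 2D")
        R = self.pose_rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-6
        ):
            raise InvalidSpec("pose rotation must be orthonormal with det +1")

    def pixel_to_world(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Pixel (row, col) coordinates -> world (x, y, z) points in mm."""
        u = self.pose_rotation[:, 0]
        v = self.pose_rotation[:, 1]
        rows = np.asarray(rows, dtype=float)[..., None]
        cols = np.asarray(cols, dtype=float)[..., None]
        return self.pose_translation + cols * self.pixel_spacing * u + rows * self.pixel_spacing * v


# ---------------------------------------------------------------------------
# segmentation


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise InvalidSpec(f"unsupported 3D connectivity: {connectivity}")


def segment_depot(
    volume: VoxelVolume,
    hu_low: float,
    hu_high: float,
    select: str = "largest",
    connectivity: int = 26,
) -> BinaryMask | list[BinaryMask]:
    """Threshold a volume into HU range [hu_low, hu_high] and group voxels
    into connected components (26-connected by default).

    ``select='largest'`` returns the maximal-volume component as one mask;
    ``select='all'`` returns one mask per component, largest first.
    """
    if hu_low >= hu_high:
        raise InvalidSpec("hu_low must be < hu_high")
    in_range = (volume.values >= hu_low) & (volume.values <= hu_high)
    if not in_range.any():
        raise NoDepotFound(f"no voxel in HU range [{hu_low}, {hu_high}]")
    labels, n = ndimage.label(in_range, structure=_connectivity_structure(connectivity))
    counts = np.bincount(labels.ravel())[1:]
    order = np.argsort(counts)[::-1] + 1
    if select == "largest":
        return BinaryMask(labels == order[0], volume.spacing, volume.origin)
    if select == "all":
        return [BinaryMask(labels == lab, volume.spacing, volume.origin) for lab in order]
    raise InvalidSpec(f"unknown select mode: {select}")


# ---------------------------------------------------------------------------
# serial per-mL differencing


def _apply_rigid_to_mask(mask: BinaryMask, rotation: np.ndarray, translation: np.ndarray) -> BinaryMask:
    """Resample a mask through a rigid world transform onto its own grid.

    The transform maps source world points to the common (aligned) frame;
    nearest-neighbour interpolation keeps the mask binary.
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if np.allclose(R, np.eye(3)) and np.allclose(t, 0.0):
        return mask
    kk, jj, ii = np.meshgrid(*(np.arange(n) for n in mask.shape), indexing="ij")
    out_world = mask.index_to_world(np.c_[kk.ravel(), jj.ravel(), ii.ravel()])
    # inverse transform: aligned frame -> source frame
    src_world = (out_world - t) @ R  # == R.T applied to rows
    src_idx = mask.world_to_index(src_world)
    sampled = ndimage.map_coordinates(
        mask.values.astype(np.float32), src_idx.T, order=0, mode="constant", cval=0.0
    )
    return BinaryMask(sampled.reshape(mask.shape) > 0.5, mask.spacing, mask.origin)


def serial_increments(
    masks: list[BinaryMask],
    alignment: list[tuple[np.ndarray, np.ndarray]] | None = None,
    shrink_tolerance: float = 0.05,
) -> list[BinaryMask]:
    """Per-step set differences of an ordered series of depot masks.

    ``alignment`` optionally supplies one rigid transform (rotation,
    translation) per mask mapping it into a common frame; registration itself
    is out of scope and is consumed, never estimated. Increment ``n`` is
    ``mask_n \\ mask_{n-1}``; a series step whose total volume shrinks by more
    than ``shrink_tolerance`` (fraction) raises a warning but is still
    reported.
    """
    if len(masks) < 2:
        raise InvalidSpec("need at least two masks to form increments")
    if alignment is not None:
        if len(alignment) != len(masks):
            raise InvalidSpec("one alignment transform per mask is required")
        masks = [_apply_rigid_to_mask(m, R, t) for m, (R, t) in zip(masks, alignment)]
    geom = masks[0]
    for m in masks[1:]:
        if not geom.same_geometry(m):
            raise InvalidSpec("masks must share geometry after alignment")
    increments = []
    for prev, cur in zip(masks[:-1], masks[1:]):
        inc = cur.values & ~prev.values
        lost = prev.values.sum() - (cur.values & prev.values).sum()
        if prev.values.sum() > 0 and lost / prev.values.sum() > shrink_tolerance:
            warnings.warn(
                "non-monotone series: a mask shrank by more than the tolerance; "
                "negative growth is reported as-is",
                stacklevel=2,
            )
        increments.append(BinaryMask(inc, cur.spacing, cur.origin))
    return increments


# ---------------------------------------------------------------------------
# freehand 3D reconstruction


def reconstruct_volume(
    frames: list[TrackedFrame],
    out_spacing: float,
    out_shape: tuple[int, int, int] | None = None,
    out_origin: tuple[float, float, float] | None = None,
    fill_missing: float = np.nan,
) -> tuple[VoxelVolume, BinaryMask]:
    """Splat pose-tracked 2D frames into a 3D grid.

    Each pixel sample is distributed onto the voxels within a 1-voxel kernel
    radius of its world position with inverse-distance weights (the standard
    pixel-based freehand-US distribution step); voxel value = weighted mean of
    contributing samples. Returns the volume plus a "visited" mask; unvisited
    voxels hold ``fill_missing`` (NaN by default) and are False in the mask.
    """
    if len(frames) < 2:
        raise InvalidSpec("need at least two frames to reconstruct")
    live = [f for f in frames if not f.empty]
    if not live:
        raise EmptyReconstruction("every frame is flagged empty")

    pts = []
    vals = []
    for f in live:
        rows, cols = np.meshgrid(
            np.arange(f.image.shape[0]), np.arange(f.image.shape[1]), indexing="ij"
        )
        pts.append(f.pixel_to_world(rows.ravel(), cols.ravel()))
        vals.append(f.image.ravel().astype(float))
    pts = np.vstack(pts)
    vals = np.concatenate(vals)

    if out_origin is None or out_shape is None:
        lo = pts.min(axis=0) - out_spacing
        hi = pts.max(axis=0) + out_spacing
        if out_origin is None:
            out_origin = tuple(lo)
        if out_shape is None:
            extent = (hi - np.asarray(out_origin))[::-1] / out_spacing
            out_shape = tuple((np.ceil(extent).astype(int) + 1).tolist())
    spacing = (out_spacing,) * 3
    num = np.zeros(out_shape, dtype=float)
    den = np.zeros(out_shape, dtype=float)

    # continuous index of every sample
    zyx = (pts - np.asarray(out_origin))[:, ::-1] / out_spacing
    base = np.floor(zyx).astype(int)
    frac = zyx - base
    inside_any = False
    eps = 1e-3
    for dk in (0, 1):
        for dj in (0, 1):
            for di in (0, 1):
                idx = base + (dk, dj, di)
                ok = np.all((idx >= 0) & (idx < np.asarray(out_shape)), axis=1)
                if not ok.any():
                    continue
                inside_any = True
                d = np.linalg.norm(frac[ok] - (dk, dj, di), axis=1)
                w = 1.0 / (d + eps)
                w[d > 1.0] = 0.0  # 1-voxel kernel radius
                flat = np.ravel_multi_index(idx[ok].T, out_shape)
                np.add.at(num.ravel(), flat, w * vals[ok])
                np.add.at(den.ravel(), flat, w)
    if not inside_any or not (den > 0).any():
        raise EmptyReconstruction("no frame sample fell inside the output extent")
    visited = den > 0
    values = np.full(out_shape, fill_missing, dtype=float)
    values[visited] = num[visited] / den[visited]
    if np.isnan(fill_missing):
        # VoxelVolume requires finite values; store background 0 where missing
        values[~visited] = 0.0
    vol = VoxelVolume(values, spacing, tuple(out_origin))
    return vol, BinaryMask(visited, spacing, tuple(out_origin))


# ---------------------------------------------------------------------------
# file I/O


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) with spacing and
    origin in the header."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        sx, sy, sz = volume.spacing[::-1]
        affine = np.diag([sx, sy, sz, 1.0])
        affine[:3, 3] = volume.origin
        data = np.transpose(volume.values, (2, 1, 0))  # (k,j,i)->(i,j,k)
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif name.endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(volume.values)
        img.SetSpacing(tuple(volume.spacing[::-1]))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise InvalidSpec(f"unsupported volume format: {path.name}")


def read_volume(path: str | Path) -> VoxelVolume:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(float)
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, ax])) for ax in (2, 1, 0))
        origin = tuple(float(x) for x in aff[:3, 3])
        return VoxelVolume(data, spacing, origin)
    if name.endswith((".mha", ".mhd")):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).astype(float)
        spacing = tuple(img.GetSpacing()[::-1])
        origin = tuple(img.GetOrigin())
        return VoxelVolume(data, spacing, origin)
    raise InvalidSpec(f"unsupported volume format: {path.name}")


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Masks travel as uint8 NIfTI/MetaImage."""
    write_volume(VoxelVolume(mask.values.astype(np.uint8), mask.spacing, mask.origin), path)


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.values > 0.5, vol.spacing, vol.origin)


def write_poses_csv(frames: list[TrackedFrame], path: str | Path) -> None:
    """Poses CSV: frame_id, 3x3 rotation row-major r00..r22, translation mm."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["frame_id"]
            + [f"r{i}{j}" for i in range(3) for j in range(3)]
            + ["tx_mm", "ty_mm", "tz_mm", "pixel_spacing_mm"]
        )
        for f in frames:
            w.writerow(
                [f.frame_id]
                + [f"{x:.9g}" for x in f.pose_rotation.ravel()]
                + [f"{x:.9g}" for x in f.pose_translation]
                + [f"{f.pixel_spacing:.9g}"]
            )


def read_poses_csv(path: str | Path) -> list[dict]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            R = np.array([float(row[f"r{i}{j}"]) for i in range(3) for j in range(3)]).reshape(3, 3)
            t = np.array([float(row["tx_mm"]), float(row["ty_mm"]), float(row["tz_mm"])])
            out.append(
                {
                    "frame_id": int(row["frame_id"]),
                    "rotation": R,
                    "translation": t,
                    "pixel_spacing": float(row["pixel_spacing_mm"]),
                }
            )
    return out
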