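"""B-mode texture descriptors within a region of interest.

Three scalar time-course descriptors of a grayscale frame restricted to an
ROI mask:

  * acoustic intensity — mean gray level (a.u.);
  * acoustic heterogeneity — population standard deviation of gray levels
    (a.u.); the population (not sample) convention matches pixel-statistics
    usage and differs negligibly at realistic ROI sizes;
  * entropy — Shannon entropy of the ROI gray-level histogram in bits,
    bounded by log2(levels) (8 bits for 8-bit frames).

ROIs are supplied as boolean masks; nothing here draws or estimates them.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidSpec, NoDepotFound

__all__ = ["acoustic_intensity", "heterogeneity", "entropy", "texture_metrics"]


def _roi_pixels(frame: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if frame.shape != roi_mask.shape:
        raise InvalidSpec("frame and ROI mask shapes differ")
    if not roi_mask.any():
        raise NoDepotFound("empty ROI")
    return frame[roi_mask]


def acoustic_intensity(frame: np.ndarray, roi_mask: np.ndarray) -> float:
    """Mean pixel value over the ROI (a.u.)."""
    return float(_roi_pixels(frame, roi_mask).mean())


def heterogeneity(frame: np.ndarray, roi_mask: np.ndarray) -> float:
    """Population standard deviation of ROI pixels (a.u.)."""
    return float(_roi_pixels(frame, roi_mask).std())


def entropy(frame: np.ndarray, roi_mask: np.ndarray, levels: int = 256) -> float:
    """Shannon entropy -sum p log2 p of the ROI gray-level histogram, bits."""
    px = _roi_pixels(frame, roi_mask)
    if np.any(px < 0) or np.any(px > levels - 1):
        raise InvalidSpec(f"pixel values must be quantized to [0, {levels - 1}]")
    counts = np.bincount(px.astype(np.int64).ravel(), minlength=levels)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def texture_metrics(frame: np.ndarray, roi_mask: np.ndarray, timepoint_min: float = 0.0, levels: int = 256) -> dict:
    """All three descriptors for one frame/ROI pair, as a flat record."""
    return {
        "timepoint_min": timepoint_min,
        "acoustic_intensity": acoustic_intensity(frame, roi_mask),
        "heterogeneity": heterogeneity(frame, roi_mask),
        "entropy_bits": entropy(frame, roi_mask, levels=levels),
    }
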