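"""Spleen volumetry from sparse keyframe contours.

The measurement procedure mirrors slice-wise manual outlining: the organ is
contoured on keyframe slices spaced ``slice_step`` apart (default 20), the
missing slices are filled in by interpolating the keyframe contours, and
the volume is the count of mask voxels times the known voxel volume (e.g.
(26 um)^3). Keyframe contouring is automatic here — Otsu threshold, bright-
artifact exclusion by an intensity-percentile cap, largest connected
component, hole filling, marching-squares boundary — and externally drawn
keyframe polygons can be supplied instead to preserve a manual workflow.

Contour interpolation blends the signed Euclidean distance transforms of
the two bracketing keyframe masks linearly in z and thresholds at zero,
the standard reproducible choice for shape interpolation. Slices outside
the first/last keyframe are empty; keyframes are anchored at the first and
last slices that intersect the object so the poles are covered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw, filters, measure

from .volume_io import ImageVolume

logger = logging.getLogger(__name__)


@dataclass
class ContourStack:
    """Closed keyframe polygons, one per keyframe slice.

    ``keyframes`` maps slice index -> (N, 2) array of (x, y) vertices in
    0-based voxel coordinates (x = column, y = row).
    """

    keyframes: dict[int, np.ndarray]
    slice_step: int
    volume_shape: tuple[int, int, int]  # (nz, ny, nx)

    def __post_init__(self) -> None:
        nz = self.volume_shape[0]
        for z, poly in self.keyframes.items():
            if not (0 <= z < nz):
                raise ValueError(f"keyframe slice {z} outside volume")
            if np.asarray(poly).ndim != 2 or np.asarray(poly).shape[1] != 2:
                raise ValueError(f"keyframe {z}: polygon must be (N, 2)")


@dataclass
class VolumeMask:
    """Boolean organ mask plus the physical volume of one voxel (mm^3)."""

    mask: np.ndarray
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be > 0")
        self.mask = np.asarray(self.mask, dtype=bool)


def _contour_slice(img: np.ndarray, threshold: float,
                   artifact_percentile: float) -> np.ndarray | None:
    """Segment one slice and trace its boundary polygon; None if empty."""
    cap = np.percentile(img, artifact_percentile)
    mask = (img > threshold) & (img <= cap)
    if mask.sum() < 8:
        return None
    lab, nlab = ndimage.label(mask)
    if nlab == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    # pad so components touching the image border still yield closed contours
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    boundary = max(contours, key=len) - 1.0  # unpad; (row, col) vertices
    return boundary[:, ::-1].copy()  # -> (x, y)


def auto_contour_keyframes(volume: ImageVolume, slice_step: int = 20,
                           artifact_percentile: float = 99.9) -> ContourStack:
    """Contour the organ on keyframe slices spaced ``slice_step`` apart.

    The object/background threshold is Otsu's, computed once over the whole
    volume (per-slice thresholds are unstable on slices containing little or
    no object). Voxels above the per-slice ``artifact_percentile`` intensity
    are excluded, emulating the exclusion of highly attenuating streak
    artifacts. Keyframes are anchored at the first and last object slices;
    empty keyframes are skipped with a warning.
    """
    vals = volume.values
    if vals.ndim != 3:
        raise ValueError("auto_contour_keyframes requires a 3-D volume")
    # exclude the bright-artifact tail before estimating the tissue threshold,
    # otherwise extreme streaks dominate the between-class variance
    cap_global = np.percentile(vals, artifact_percentile)
    threshold = float(filters.threshold_otsu(
        vals[vals <= cap_global].astype(np.float64)))
    per_slice = (vals > threshold).sum(axis=(1, 2))
    object_slices = np.nonzero(per_slice > 8)[0]
    if object_slices.size == 0:
        raise ValueError("no object found above the Otsu threshold")
    z_first, z_last = int(object_slices[0]), int(object_slices[-1])
    zs = list(range(z_first, z_last + 1, slice_step))
    if zs[-1] != z_last:
        zs.append(z_last)

    keyframes: dict[int, np.ndarray] = {}
    for z in zs:
        poly = _contour_slice(vals[z], threshold, artifact_percentile)
        if poly is None:
            logger.warning("keyframe slice %d contains no object; skipped", z)
            continue
        keyframes[z] = poly
    if not keyframes:
        raise ValueError("every keyframe slice was empty")
    return ContourStack(keyframes=keyframes, slice_step=slice_step,
                        volume_shape=vals.shape)


def rasterize_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed (x, y) polygon into a boolean (ny, nx) image."""
    poly = np.asarray(poly, dtype=np.float64)
    rr, cc = draw.polygon(poly[:, 1], poly[:, 0], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed EDT: negative inside the region, positive outside."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return outside - inside


def interpolate_contours(contours: ContourStack,
                         voxel_size_um: float = 26.0) -> VolumeMask:
    """Fill the slices between keyframes by signed-distance interpolation.

    Each keyframe polygon is rasterised; an intermediate slice at fraction
    t between keyframes z0 < z1 is the zero sub-level set of
    (1 - t) * sdf(z0) + t * sdf(z1). Keyframe slices of the result equal
    the rasterised keyframe polygons exactly.
    """
    zs = sorted(contours.keyframes)
    if len(zs) < 2:
        raise ValueError(
            "contour interpolation needs at least 2 keyframes; "
            "reduce slice_step or supply more contours")
    nz, ny, nx = contours.volume_shape
    mask = np.zeros((nz, ny, nx), dtype=bool)
    rasters = {z: rasterize_polygon(contours.keyframes[z], (ny, nx)) for z in zs}
    sdfs = {z: _signed_distance(rasters[z]) for z in zs}
    for z in zs:
        mask[z] = rasters[z]
    for z0, z1 in zip(zs[:-1], zs[1:]):
        for z in range(z0 + 1, z1):
            t = (z - z0) / (z1 - z0)
            blended = (1.0 - t) * sdfs[z0] + t * sdfs[z1]
            mask[z] = blended < 0
    voxel_volume = (voxel_size_um * 1e-3) ** 3
    return VolumeMask(mask=mask, voxel_volume_mm3=voxel_volume)


def measure_volume(mask: VolumeMask) -> float:
    """Total mask volume in mm^3: voxel count times voxel volume."""
    return float(mask.mask.sum()) * mask.voxel_volume_mm3


def measure_spleen_volume(volume: ImageVolume, slice_step: int = 20,
                          artifact_percentile: float = 99.9) -> float:
    """End-to-end volumetry: keyframe contours -> interpolation -> mm^3."""
    contours = auto_contour_keyframes(volume, slice_step, artifact_percentile)
    mask = interpolate_contours(contours, voxel_size_um=volume.voxel_size_um)
    return measure_volume(mask)


def save_contours(contours: ContourStack, path) -> None:
    """Write keyframe polygons as JSON (slice index -> (x, y) vertex list)."""
    payload = {
        "slice_step": contours.slice_step,
        "volume_shape": list(contours.volume_shape),
        "keyframes": {str(z): np.asarray(p).tolist()
                      for z, p in contours.keyframes.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_contours(path) -> ContourStack:
    """Read keyframe polygons written by :func:`save_contours`."""
    payload = json.loads(Path(path).read_text())
    return ContourStack(
        keyframes={int(z): np.asarray(p, dtype=np.float64)
                   for z, p in payload["keyframes"].items()},
        slice_step=int(payload["slice_step"]),
        volume_shape=tuple(payload["volume_shape"]))
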