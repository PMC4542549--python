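"""Preprocessing chain for texture analysis.

The standard order is: ROI extraction -> linear 32-to-8-bit scaling ->
per-ROI histogram equalisation -> width-3 median filter. Equalisation can
amplify noise, which is the motivation for the median filter, so by default
the filter runs after equalisation; the reverse order is available via
``order="median-then-equalize"`` in :func:`preprocess_roi`.

Equalisation is applied per ROI, which maintains intra-sample contrast at
the cost of inter-sample comparability of absolute grey values; this is
recorded in the volume provenance.
"""

from __future__ import annotations

import logging

import numpy as np

from .volume_io import QUANTISED_8BIT, RAW_FLOAT, ImageVolume, ROISpec

logger = logging.getLogger(__name__)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round non-negative values half-up (0.5 -> 1), unlike numpy's banker's rounding."""
    return np.floor(np.asarray(x) + 0.5)


def extract_roi(volume: ImageVolume, roi: ROISpec) -> ImageVolume:
    """Extract a rectangular sub-volume; voxel size and dtype role are preserved."""
    if volume.values.ndim != 3:
        raise ValueError("extract_roi requires a 3-D volume")
    nz, ny, nx = volume.values.shape
    (x0, y0, z0), (rx, ry, rz) = roi.origin, roi.shape
    if x0 + rx > nx or y0 + ry > ny or z0 + rz > nz:
        cx = min(x0, max(nx - rx, 0))
        cy = min(y0, max(ny - ry, 0))
        cz = min(z0, max(nz - rz, 0))
        raise ValueError(
            f"ROI origin={roi.origin} shape={roi.shape} exceeds volume "
            f"(nx,ny,nz)=({nx},{ny},{nz}); nearest fitting origin would be "
            f"({cx},{cy},{cz})")
    sub = volume.values[roi.slices()].copy()
    return volume.with_values(sub, note=f"ROI origin={roi.origin} shape={roi.shape}")


def auto_roi(volume: ImageVolume, mask: np.ndarray,
             shape: tuple[int, int, int]) -> ROISpec:
    """Place an ROI of ``shape`` (nx, ny, nz) at the centroid of ``mask``.

    The ROI is centred on the mask centroid (rounded to the nearest voxel)
    and shifted minimally to fit inside the volume; a clamp is logged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.values.shape:
        raise ValueError("mask shape must match volume shape")
    if not mask.any():
        raise ValueError("mask is empty")
    nz, ny, nx = volume.values.shape
    rx, ry, rz = shape
    if rx > nx or ry > ny or rz > nz:
        raise ValueError(f"ROI shape {shape} larger than volume ({nx},{ny},{nz})")
    cz, cy, cx = (float(c) for c in np.mean(np.argwhere(mask), axis=0))
    origin = []
    clamped = False
    for centre, extent, limit in ((cx, rx, nx), (cy, ry, ny), (cz, rz, nz)):
        o = int(np.floor(centre + 0.5)) - extent // 2
        oc = min(max(o, 0), limit - extent)
        clamped = clamped or (oc != o)
        origin.append(oc)
    if clamped:
        logger.warning("auto_roi: ROI clamped to fit inside volume")
    return ROISpec(origin=tuple(origin), shape=tuple(shape))


def scale_to_8bit(volume: ImageVolume) -> ImageVolume:
    """Linearly rescale a raw-float volume to 8-bit integers.

    v -> round(255 * (v - min) / (max - min)) with round-half-up, so the
    minimum maps to exactly 0 and the maximum to exactly 255. A constant
    volume maps to all zeros.
    """
    v = np.asarray(volume.values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("volume contains non-finite values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        out = np.zeros(v.shape, dtype=np.uint8)
    else:
        out = _round_half_up(255.0 * (v - lo) / (hi - lo)).astype(np.uint8)
    return volume.with_values(out, dtype_role=QUANTISED_8BIT,
                              note="scaled to 8-bit (linear min-max)")


def equalize_histogram(volume: ImageVolume) -> ImageVolume:
    """Histogram-equalise an 8-bit volume.

    Uses the classical mapping v -> round(255 * (cdf(v) - cdf_min) /
    (N - cdf_min)), where cdf is the cumulative voxel count and cdf_min the
    count at the lowest occupied grey level. The mapping is monotone
    non-decreasing; a constant volume is returned unchanged.
    """
    if volume.dtype_role != QUANTISED_8BIT:
        raise ValueError("equalize_histogram requires a quantised-8bit volume")
    v = volume.values
    hist = np.bincount(v.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = int(cdf[-1])
    occupied = np.nonzero(hist)[0]
    if occupied.size <= 1:
        return volume.with_values(v.copy(), note="equalised (constant: unchanged)")
    cdf_min = int(cdf[occupied[0]])
    mapping = _round_half_up(255.0 * (cdf - cdf_min) / (n - cdf_min))
    mapping = np.clip(mapping, 0, 255).astype(np.uint8)
    out = mapping[v]
    return volume.with_values(
        out, note="histogram equalised per ROI "
        "(inter-sample comparability of absolute values sacrificed)")


def median_filter(volume: ImageVolume, width: int = 3) -> ImageVolume:
    """Median-filter with a cubic (3-D) or square (2-D) window of odd ``width``.

    Windows are truncated at the boundary rather than padded, so no invented
    intensities enter the image; truncated windows of even size use the
    lower median. The filter is value-preserving: every output value occurs
    somewhere in the corresponding input window.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError(f"width must be odd and >= 1, got {width}")
    v = volume.values
    if width == 1:
        return volume.with_values(v.copy(), note="median width=1 (identity)")
    ndim = v.ndim
    half = width // 2
    pad = [(half, half)] * ndim
    padded = np.pad(v.astype(np.float64), pad, mode="constant",
                    constant_values=np.nan)
    # Stack every window offset as a leading axis, sort (NaN sorts last),
    # then pick the lower median among the valid entries of each window.
    offsets = np.stack(np.meshgrid(*([np.arange(width)] * ndim), indexing="ij"),
                       axis=-1).reshape(-1, ndim)
    shape = v.shape
    stack = np.empty((len(offsets),) + shape, dtype=np.float64)
    for idx, off in enumerate(offsets):
        sl = tuple(slice(o, o + s) for o, s in zip(off, shape))
        stack[idx] = padded[sl]
    stack.sort(axis=0)
    valid = (~np.isnan(stack)).sum(axis=0)
    pick = (valid - 1) // 2
    out = np.take_along_axis(stack, pick[None, ...], axis=0)[0]
    if np.issubdtype(v.dtype, np.integer):
        out = out.astype(v.dtype)
    else:
        out = out.astype(v.dtype, copy=False)
    return volume.with_values(out, note=f"median filtered width={width}")


def preprocess_roi(volume: ImageVolume, roi: ROISpec | None = None,
                   order: str = "equalize-then-median",
                   median_width: int = 3) -> ImageVolume:
    """Run the full preprocessing chain on a volume.

    ``order`` selects whether the median filter runs after equalisation
    (default) or before it.
    """
    if order not in ("equalize-then-median", "median-then-equalize"):
        raise ValueError(f"unknown order {order!r}")
    out = extract_roi(volume, roi) if roi is not None else volume
    if out.dtype_role == RAW_FLOAT:
        out = scale_to_8bit(out)
    if order == "equalize-then-median":
        out = equalize_histogram(out)
        out = median_filter(out, median_width)
    else:
        out = median_filter(out, median_width)
        out = equalize_histogram(out)
    return out
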