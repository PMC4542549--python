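"""Grey-level co-occurrence matrices in 2-D and three-reference-point 3-D form.

The classical 2-D GLCM counts ordered pairs of grey values at a fixed
displacement. The 3-D extension implemented here adds a *third* reference
point so that each count is indexed by a triple (i, j, k):

    reference:    I(x, y, z)            = i
    second point: I(x + dx, y + dy, z)  = j
    third point:  I(x, y + dy, z + dz)  = k

with the displacement vector derived from a pixel displacement d and angle
theta as dx = dz = round(d cos theta), dy = round(d sin theta)
(round-half-away-from-zero per component). The second point probes in-plane
structure; the third probes the same in-plane offset combined with depth,
which is what makes the statistic sensitive to 3-D rather than purely
per-slice texture.

Texture features on the normalised tensor P(i, j, k):

    contrast    = sum P(i,j,k) * [(i-j)^2 + (i-k)^2 + (j-k)^2]
    homogeneity = sum P(i,j,k) / [1 + (i-j)^2 + (i-k)^2 + (j-k)^2]

Matrices are unsymmetrised; normalisation divides by the number of valid
(fully in-bounds) triples; triples with any point outside the volume are
skipped, never padded or wrapped. Per-angle matrices are averaged
arithmetically over the angle set before features are taken — because both
features are linear in P, :func:`texture_curve` may equivalently average
per-angle feature values, which it does to avoid materialising Ng^3 tensors.

At theta = 90 deg the displacement has dx = dz = 0, so the second and third
points coincide and all mass falls on j = k; the angle is retained in the
default set for fidelity to the four-direction average, with a debug note
in the logs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .volume_io import ImageVolume, QUANTISED_8BIT

logger = logging.getLogger(__name__)

DEFAULT_ANGLES: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x)) if x else 0


@dataclass(frozen=True)
class Offset3:
    """Integer displacement vector for one (d, theta) pair; dx == dz always."""

    dx: int
    dy: int
    dz: int
    d: int
    theta: float


def displacement_offsets(d: int, theta: float,
                         convention: str = "round") -> Offset3:
    """Map pixel displacement d and angle theta (degrees) to integer offsets.

    ``convention="round"`` rounds d*cos(theta) and d*sin(theta) half away
    from zero per component. ``convention="chessboard"`` instead uses
    +/- d on both axes at the diagonal angles (45 deg -> (d, d), 135 deg ->
    (-d, d)), an alternative reading of how diagonal displacements are laid
    out on the pixel grid.
    """
    if int(d) != d or d < 1:
        raise ValueError(f"displacement d must be a positive integer, got {d}")
    d = int(d)
    if convention == "chessboard" and (theta % 45 == 0) and (theta % 90 != 0):
        c = -1.0 if math.cos(math.radians(theta)) < 0 else 1.0
        s = -1.0 if math.sin(math.radians(theta)) < 0 else 1.0
        dx, dy = int(c) * d, int(s) * d
    elif convention in ("round", "chessboard"):
        rad = math.radians(theta)
        dx = _round_half_away(d * math.cos(rad))
        dy = _round_half_away(d * math.sin(rad))
    else:
        raise ValueError(f"unknown offset convention {convention!r}")
    if dx == 0 and abs(theta % 180.0 - 90.0) < 1e-9:
        logger.debug("theta=90 deg: dx=dz=0, second and third points coincide")
    return Offset3(dx=dx, dy=dy, dz=dx, d=d, theta=float(theta))


@dataclass
class GLCM2:
    """Normalised 2-D co-occurrence matrix over ``levels`` grey levels."""

    levels: int
    P: np.ndarray  # (levels, levels), sums to 1
    valid_pair_count: int
    d: int | None = None
    angles: tuple[float, ...] = ()


@dataclass
class GLCM3:
    """Normalised three-point co-occurrence tensor over ``levels`` grey levels."""

    levels: int
    P: np.ndarray  # (levels, levels, levels), sums to 1
    valid_triple_count: int
    d: int | None = None
    angles: tuple[float, ...] = ()


def _as_level_array(image: ImageVolume | np.ndarray, levels: int) -> np.ndarray:
    """Return an integer array with values in [0, levels).

    8-bit data with values >= ``levels`` are requantised by v * levels // 256
    (uniform bin widths); data already below ``levels`` pass through.
    """
    if levels < 2:
        raise ValueError(f"need at least 2 grey levels, got {levels}")
    arr = image.values if isinstance(image, ImageVolume) else np.asarray(image)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("GLCM input must be an integer (quantised) image")
    arr = arr.astype(np.int64, copy=False)
    if arr.size and arr.max() >= levels:
        if arr.max() > 255 or arr.min() < 0:
            raise ValueError("values outside [0, 255] cannot be requantised")
        arr = arr * levels // 256
    return arr


def _pair_views(img: np.ndarray, dx: int, dy: int):
    """Views (i, j) of all in-bounds ordered pairs at offset (dx, dy)."""
    ny, nx = img.shape
    ly, hy = max(0, -dy), ny - max(0, dy)
    lx, hx = max(0, -dx), nx - max(0, dx)
    if hy <= ly or hx <= lx:
        return None
    i = img[ly:hy, lx:hx]
    j = img[ly + dy:hy + dy, lx + dx:hx + dx]
    return i, j


def _triple_views(vol: np.ndarray, dx: int, dy: int, dz: int):
    """Views (i, j, k) of all in-bounds triples at offset (dx, dy, dz)."""
    nz, ny, nx = vol.shape
    lz, hz = max(0, -dz), nz - max(0, dz)
    ly, hy = max(0, -dy), ny - max(0, dy)
    lx, hx = max(0, -dx), nx - max(0, dx)
    if hz <= lz or hy <= ly or hx <= lx:
        return None
    i = vol[lz:hz, ly:hy, lx:hx]
    j = vol[lz:hz, ly + dy:hy + dy, lx + dx:hx + dx]
    k = vol[lz + dz:hz + dz, ly + dy:hy + dy, lx:hx]
    return i, j, k


def compute_glcm2d(image: ImageVolume | np.ndarray, d: int, theta: float,
                   levels: int = 256, convention: str = "round") -> GLCM2:
    """Standard (two-point, unsymmetrised) GLCM of a 2-D slice."""
    img = _as_level_array(image, levels)
    if img.ndim != 2:
        raise ValueError("compute_glcm2d requires a 2-D image")
    off = displacement_offsets(d, theta, convention)
    views = _pair_views(img, off.dx, off.dy)
    if views is None:
        raise ValueError(f"no valid pairs for d={d}, theta={theta}")
    i, j = views
    counts = np.bincount((i * levels + j).ravel(), minlength=levels * levels)
    n = int(counts.sum())
    P = counts.reshape(levels, levels).astype(np.float64) / n
    return GLCM2(levels=levels, P=P, valid_pair_count=n, d=d, angles=(theta,))


def compute_glcm3d(volume: ImageVolume | np.ndarray, d: int, theta: float,
                   levels: int = 256, convention: str = "round") -> GLCM3:
    """Three-reference-point GLCM of a 3-D volume at one (d, theta)."""
    vol = _as_level_array(volume, levels)
    if vol.ndim != 3:
        raise ValueError("compute_glcm3d requires a 3-D volume")
    off = displacement_offsets(d, theta, convention)
    views = _triple_views(vol, off.dx, off.dy, off.dz)
    if views is None:
        raise ValueError(
            f"no valid triples for d={d}, theta={theta} on shape {vol.shape}")
    i, j, k = views
    flat = (i.astype(np.int64) * levels + j) * levels + k
    counts = np.bincount(flat.ravel(), minlength=levels ** 3)
    n = int(counts.sum())
    P = counts.reshape(levels, levels, levels).astype(np.float64) / n
    return GLCM3(levels=levels, P=P, valid_triple_count=n, d=d, angles=(theta,))


def average_over_angles(volume: ImageVolume | np.ndarray, d: int,
                        angles: Sequence[float] = DEFAULT_ANGLES,
                        levels: int = 256, dims: int = 3,
                        convention: str = "round") -> GLCM3 | GLCM2:
    """Arithmetic mean of per-angle normalised matrices at one displacement.

    Angles that yield no valid pairs/triples (displacement larger than the
    image) are excluded with a warning; if every angle is excluded an error
    is raised.
    """
    if not angles:
        raise ValueError("need at least one angle")
    mats = []
    for theta in angles:
        try:
            if dims == 3:
                mats.append(compute_glcm3d(volume, d, theta, levels, convention))
            elif dims == 2:
                mats.append(compute_glcm2d(volume, d, theta, levels, convention))
            else:
                raise ValueError(f"dims must be 2 or 3, got {dims}")
        except ValueError as exc:
            if "no valid" not in str(exc):
                raise
            logger.warning("angle %s excluded at d=%d: %s", theta, d, exc)
    if not mats:
        raise ValueError(f"no angle yields valid co-occurrences at d={d}")
    P = np.mean([m.P for m in mats], axis=0)
    n = sum(m.valid_triple_count if dims == 3 else m.valid_pair_count
            for m in mats)
    used = tuple(m.angles[0] for m in mats)
    if dims == 3:
        return GLCM3(levels=levels, P=P, valid_triple_count=n, d=d, angles=used)
    return GLCM2(levels=levels, P=P, valid_pair_count=n, d=d, angles=used)


# ---------------------------------------------------------------------------
# Features


def _check_normalised(P: np.ndarray) -> None:
    s = float(P.sum())
    if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError(f"GLCM is not normalised (sum={s!r}); "
                         "divide by the valid count first")


def _pairwise_sq_weights3(levels: int) -> np.ndarray:
    idx = np.arange(levels)
    i = idx[:, None, None]
    j = idx[None, :, None]
    k = idx[None, None, :]
    return ((i - j) ** 2 + (i - k) ** 2 + (j - k) ** 2).astype(np.float64)


def contrast3d(glcm: GLCM3) -> float:
    """Sum of P(i,j,k) weighted by (i-j)^2 + (i-k)^2 + (j-k)^2."""
    _check_normalised(glcm.P)
    return float(np.sum(glcm.P * _pairwise_sq_weights3(glcm.levels)))


def homogeneity3d(glcm: GLCM3) -> float:
    """Sum of P(i,j,k) / (1 + (i-j)^2 + (i-k)^2 + (j-k)^2); in (0, 1]."""
    _check_normalised(glcm.P)
    return float(np.sum(glcm.P / (1.0 + _pairwise_sq_weights3(glcm.levels))))


def contrast2d(glcm: GLCM2) -> float:
    """Two-point contrast: sum of P(i,j) * (i-j)^2."""
    _check_normalised(glcm.P)
    idx = np.arange(glcm.levels)
    w = (idx[:, None] - idx[None, :]) ** 2
    return float(np.sum(glcm.P * w))


def homogeneity2d(glcm: GLCM2) -> float:
    """Two-point homogeneity: sum of P(i,j) / (1 + (i-j)^2)."""
    _check_normalised(glcm.P)
    idx = np.arange(glcm.levels)
    w = (idx[:, None] - idx[None, :]) ** 2
    return float(np.sum(glcm.P / (1.0 + w)))


# ---------------------------------------------------------------------------
# Displacement sweeps

_METRICS = ("contrast", "homogeneity")


@dataclass
class TextureCurve:
    """One texture metric as a function of pixel displacement for one sample."""

    sample_id: str
    metric: str
    dimensionality: str  # "2D" | "3D"
    displacements: np.ndarray
    values: np.ndarray
    slice_index: int | None = None
    angles: tuple[float, ...] = DEFAULT_ANGLES

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.displacements) != len(self.values):
            raise ValueError("displacements and values must have equal length")
        if np.any(np.diff(self.displacements) <= 0):
            raise ValueError("displacements must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")


@dataclass
class PeakEstimate:
    """Location and height of a curve's peak, possibly sub-sample refined."""

    displacement: float
    value: float
    at_boundary: bool = False


def _stream_features(views, metrics: Sequence[str]) -> dict[str, float]:
    """Per-triple (or per-pair) feature means without building the tensor.

    Both features are expectations of a weight function of the grey values,
    so they can be averaged directly over the co-occurring value arrays;
    this is exactly the feature of the normalised (virtual) tensor.
    """
    if len(views) == 3:
        i, j, k = (v.astype(np.int64) for v in views)
        w = (i - j) ** 2 + (i - k) ** 2 + (j - k) ** 2
    else:
        i, j = (v.astype(np.int64) for v in views)
        w = (i - j) ** 2
    out = {}
    if "contrast" in metrics:
        out["contrast"] = float(w.mean())
    if "homogeneity" in metrics:
        out["homogeneity"] = float((1.0 / (1.0 + w)).mean())
    return out


def texture_curves(volume: ImageVolume | np.ndarray,
                   metrics: Sequence[str] = _METRICS,
                   dimensionality: str = "3D",
                   d_range: Sequence[int] = range(1, 41),
                   angles: Sequence[float] = DEFAULT_ANGLES,
                   levels: int = 256,
                   slice_index: int | None = None,
                   sample_id: str = "",
                   convention: str = "round") -> dict[str, TextureCurve]:
    """Sweep displacement and return angle-averaged curves for each metric.

    In 2-D mode a ``slice_index`` selects the x-y slice of a 3-D volume
    (a 2-D input is used directly). Features are computed per angle by
    streaming over co-occurring value arrays and then averaged, which equals
    computing them on the angle-averaged matrix because both features are
    linear in P.
    """
    d_range = list(d_range)
    if not d_range or any(np.diff(d_range) <= 0):
        raise ValueError("d_range must be a non-empty increasing sequence")
    for m in metrics:
        if m not in _METRICS:
            raise ValueError(f"unknown metric {m!r}")
    arr = _as_level_array(volume, levels)
    if dimensionality == "2D":
        if arr.ndim == 3:
            if slice_index is None:
                raise ValueError("2-D mode on a volume requires slice_index")
            arr = arr[slice_index]
        view_fn = lambda off: _pair_views(arr, off.dx, off.dy)
    elif dimensionality == "3D":
        if arr.ndim != 3:
            raise ValueError("3-D mode requires a 3-D volume")
        view_fn = lambda off: _triple_views(arr, off.dx, off.dy, off.dz)
    else:
        raise ValueError(f"dimensionality must be '2D' or '3D'")

    values: dict[str, list[float]] = {m: [] for m in metrics}
    for d in d_range:
        per_angle: dict[str, list[float]] = {m: [] for m in metrics}
        for theta in angles:
            off = displacement_offsets(d, theta, convention)
            views = view_fn(off)
            if views is None:
                logger.warning("angle %s excluded at d=%d (no valid positions)",
                               theta, d)
                continue
            feats = _stream_features(views, metrics)
            for m in metrics:
                per_angle[m].append(feats[m])
        if not per_angle[metrics[0]]:
            raise ValueError(f"no angle yields valid co-occurrences at d={d}")
        for m in metrics:
            values[m].append(float(np.mean(per_angle[m])))

    return {m: TextureCurve(sample_id=sample_id, metric=m,
                            dimensionality=dimensionality,
                            displacements=np.asarray(d_range),
                            values=np.asarray(values[m]),
                            slice_index=slice_index,
                            angles=tuple(angles))
            for m in metrics}


def texture_curve(volume: ImageVolume | np.ndarray, metric: str = "contrast",
                  **kwargs) -> TextureCurve:
    """Single-metric convenience wrapper around :func:`texture_curves`."""
    return texture_curves(volume, metrics=(metric,), **kwargs)[metric]


def find_peak(curve: TextureCurve) -> PeakEstimate:
    """Locate the curve's maximum with quadratic sub-sample refinement.

    The sampled argmax is refined by the vertex of the parabola through the
    three surrounding points when the maximum is interior; a maximum at
    either end of the sweep is returned unrefined with ``at_boundary=True``.
    """
    y = curve.values
    x = np.asarray(curve.displacements, dtype=np.float64)
    if len(y) == 0:
        raise ValueError("empty curve")
    if np.allclose(y, y[0]):
        raise ValueError("no unique peak: curve is constant")
    idx = int(np.argmax(y))
    if idx == 0 or idx == len(y) - 1:
        return PeakEstimate(displacement=float(x[idx]), value=float(y[idx]),
                            at_boundary=True)
    x3, y3 = x[idx - 1:idx + 2], y[idx - 1:idx + 2]
    a, b, c = np.polyfit(x3, y3, 2)
    if a >= 0:  # degenerate (flat or upward) parabola; keep sampled argmax
        return PeakEstimate(displacement=float(x[idx]), value=float(y[idx]))
    xv = -b / (2 * a)
    xv = float(np.clip(xv, x3[0], x3[2]))
    yv = float(a * xv * xv + b * xv + c)
    return PeakEstimate(displacement=xv, value=yv)
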