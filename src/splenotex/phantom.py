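"""Synthetic spleen phantoms with known ground truth.

Two generators live here:

* :func:`generate_feature_image` — the 2-D "spleen feature" simulation: a
  bright red-pulp (RP) background containing circular white-pulp lymph
  nodes (LN, grey level 0) each wrapped in a marginal-zone (MZ) annulus of
  intermediate grey level. The canonical parameterisation uses grey levels
  0 / 128 / 256, the last clamped to the 8-bit maximum 255 (recorded in
  provenance).

* :func:`generate_spleen_phantom` — a 3-D spleen-like volume in
  reconstructed-image space: an ellipsoid of bright red pulp containing
  dark white-pulp nodules with intermediate marginal-zone shells, bright
  vessel tubes, additive Gaussian noise and optional bright streak
  artifacts. Attenuation ordering is RP > MZ > WP because blood (rich in
  haemoglobin) is the dominant absorber: red pulp traps red blood cells and
  appears bright, white pulp contains almost none and appears dark, and
  the marginal zone is intermediate.

A "treated" cohort is modelled as a globally smaller spleen
(``cohort_scale`` < 1 applied to the whole geometry; the default 0.896
gives a 1 - 0.896^3 ~ 28% volume reduction) whose internal features shrink
by an additional ``feature_scale``, emulating marginal-zone contraction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .volume_io import ImageVolume, QUANTISED_8BIT, RAW_FLOAT

# Ground-truth label codes
LABEL_BACKGROUND = 0
LABEL_RP = 1
LABEL_MZ = 2
LABEL_WP = 3
LABEL_VESSEL = 4
LABEL_ARTIFACT = 5

SPLEEN_LABELS = (LABEL_RP, LABEL_MZ, LABEL_WP, LABEL_VESSEL)


@dataclass(frozen=True)
class FeatureImageSpec:
    """Parameters of one 2-D spleen-feature simulation image.

    Grey levels above 255 are clamped to 255 at render time so the image
    remains a valid 8-bit quantised picture.
    """

    image_size: int = 200
    n_features: int = 4
    ln_radius: float = 12.0
    mz_thickness: float = 4.0
    ln_level: int = 0
    mz_level: int = 128
    rp_level: int = 256  # clamped to 255 when rendered
    feature_centres: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.ln_radius < 0 or self.mz_thickness < 0:
            raise ValueError("radii and thicknesses must be >= 0")
        if self.image_size < 1 or self.n_features < 0:
            raise ValueError("invalid image_size or n_features")
        for lvl in (self.ln_level, self.mz_level, self.rp_level):
            if not (0 <= lvl <= 256):
                raise ValueError(f"grey level {lvl} outside [0, 256]")

    def centres(self) -> tuple[tuple[float, float], ...]:
        """Explicit centres, or a square grid filling the image."""
        if self.feature_centres is not None:
            return self.feature_centres
        side = int(np.ceil(np.sqrt(self.n_features)))
        step = self.image_size / side
        pts = []
        for gy in range(side):
            for gx in range(side):
                if len(pts) < self.n_features:
                    pts.append((step * (gx + 0.5), step * (gy + 0.5)))
        return tuple(pts)


def generate_feature_image(spec: FeatureImageSpec) -> ImageVolume:
    """Render a 2-D feature image: LN discs, MZ annuli, RP background.

    Disc membership uses centre-of-pixel Euclidean distance with inclusive
    boundary (<= r); the MZ occupies the half-open annulus (r, r + t].
    Features that overlap each other or cross the image boundary raise,
    naming the offending centre.
    """
    size = spec.image_size
    centres = spec.centres()
    outer = spec.ln_radius + spec.mz_thickness
    for cx, cy in centres:
        if (cx - outer < -0.5 or cx + outer > size - 0.5
                or cy - outer < -0.5 or cy + outer > size - 0.5):
            raise ValueError(f"feature at centre ({cx}, {cy}) exceeds image bounds")
    for a in range(len(centres)):
        for b in range(a + 1, len(centres)):
            dist = float(np.hypot(centres[a][0] - centres[b][0],
                                  centres[a][1] - centres[b][1]))
            if dist <= 2 * outer:
                raise ValueError(
                    f"features at centres {centres[a]} and {centres[b]} overlap")

    rp = min(spec.rp_level, 255)
    mz = min(spec.mz_level, 255)
    ln = min(spec.ln_level, 255)
    img = np.full((size, size), rp, dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    for cx, cy in centres:
        r = np.hypot(xx - cx, yy - cy)
        img[(r > spec.ln_radius) & (r <= outer)] = mz
        img[r <= spec.ln_radius] = ln
    notes = [f"feature image: {len(centres)} features, ln_radius={spec.ln_radius}, "
             f"mz_thickness={spec.mz_thickness}"]
    if spec.rp_level > 255 or spec.mz_level > 255 or spec.ln_level > 255:
        notes.append("grey level(s) > 255 clamped to 255")
    return ImageVolume(img, dtype_role=QUANTISED_8BIT, voxel_size_um=1.0,
                       provenance="; ".join(notes))


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of a 3-D spleen phantom.

    Intensities are in arbitrary attenuation units with the required tissue
    ordering rp > mz > wp (bright red pulp, dark white pulp). Geometry is
    in voxels; ``cohort_scale`` multiplies the spleen semi-axes and (with
    ``feature_scale``) the internal feature sizes, modelling drug-induced
    shrinkage.
    """

    grid_shape: tuple[int, int, int] = (224, 96, 96)  # (nz, ny, nx)
    voxel_size_um: float = 26.0
    spleen_semi_axes: tuple[float, float, float] = (40.0, 34.0, 100.0)  # (x, y, z)
    nodule_count: int = 55
    nodule_radius_mean: float = 5.5
    nodule_radius_sd: float = 0.7
    mz_thickness: float = 2.5
    rp_intensity: float = 1.0
    mz_intensity: float = 0.55
    wp_intensity: float = 0.2
    background_intensity: float = 0.05
    vessel_count: int = 3
    vessel_radius: float = 1.2
    vessel_intensity: float = 1.25
    noise_sd: float = 0.04
    artifact_count: int = 1
    artifact_intensity: float = 2.5
    cohort_scale: float = 1.0
    feature_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cohort_scale <= 1.0):
            raise ValueError("cohort_scale must be in (0, 1]")
        if not (self.rp_intensity > self.mz_intensity > self.wp_intensity):
            raise ValueError("tissue intensities must satisfy rp > mz > wp")
        for name in ("nodule_radius_mean", "nodule_radius_sd", "mz_thickness",
                     "vessel_radius", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nodule_count < 0 or self.vessel_count < 0 or self.artifact_count < 0:
            raise ValueError("counts must be >= 0")


def treated_spec(vehicle: PhantomSpec, cohort_scale: float = 0.896,
                 feature_scale: float = 0.9, seed: int | None = None) -> PhantomSpec:
    """Derive a treated-cohort spec: globally smaller with smaller features."""
    return dataclasses.replace(
        vehicle, cohort_scale=vehicle.cohort_scale * cohort_scale,
        feature_scale=vehicle.feature_scale * feature_scale,
        seed=vehicle.seed if seed is None else seed)


@dataclass
class GroundTruth:
    """Noiseless tissue geometry of a phantom.

    ``label_volume`` records tissue classes; artifact streaks are labelled
    only where they fall outside the spleen (inside, they corrupt intensity
    but the underlying tissue label is kept, mirroring how reconstruction
    artifacts overlie real anatomy). ``artifact_mask`` marks every artifact
    voxel. ``spleen_voxel_count`` counts all spleen-tissue labels.
    """

    label_volume: np.ndarray
    spleen_voxel_count: int
    nodule_centres_radii: list[tuple[tuple[float, float, float], float]]
    artifact_mask: np.ndarray | None = None

    @property
    def spleen_mask(self) -> np.ndarray:
        return np.isin(self.label_volume, SPLEEN_LABELS)


def _place_nodules(rng: np.random.Generator, spec: PhantomSpec,
                   semi: np.ndarray, centre: np.ndarray,
                   max_tries: int = 2000):
    """Sample non-merging nodule centres/radii inside the scaled ellipsoid."""
    scale = spec.cohort_scale * spec.feature_scale
    mz = spec.mz_thickness * scale
    placed: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.nodule_count):
        ok = False
        for _try in range(max_tries):
            r = max(1.0, rng.normal(spec.nodule_radius_mean, spec.nodule_radius_sd)
                    * scale)
            # uniform direction, radius biased to the interior
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rho = rng.uniform(0, 1) ** (1 / 3)
            pos = centre + u * rho * (semi - (r + mz + 1.0))
            # reject if the shell would poke out of the ellipsoid
            if np.any(semi - (r + mz + 1.0) <= 0):
                break
            sep_ok = all(
                np.linalg.norm(pos - p) > r + pr + 2 * mz + 1.0
                for p, pr in placed)
            if sep_ok:
                placed.append((pos, r))
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place nodule {len(placed) + 1} of "
                f"{spec.nodule_count} without merging marginal zones "
                f"(achieved {len(placed)})")
    return placed, mz


def generate_spleen_phantom(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Build one phantom volume and its ground truth, deterministically.

    The same spec (including seed) always produces bitwise-identical output.
    With ``noise_sd=0`` and ``artifact_count=0`` every spleen voxel takes
    exactly one of the four tissue intensities.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float64)
    centre = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    semi = np.array(spec.spleen_semi_axes, dtype=np.float64) * spec.cohort_scale

    norm = (((xx - centre[0]) / semi[0]) ** 2
            + ((yy - centre[1]) / semi[1]) ** 2
            + ((zz - centre[2]) / semi[2]) ** 2)
    spleen = norm <= 1.0
    labels = np.where(spleen, LABEL_RP, LABEL_BACKGROUND).astype(np.uint8)

    placed, mz = _place_nodules(rng, spec, semi, centre)
    for pos, r in placed:
        # rasterise within the shell's bounding box only
        outer = r + mz
        x0, x1 = max(0, int(pos[0] - outer) - 1), min(nx, int(pos[0] + outer) + 2)
        y0, y1 = max(0, int(pos[1] - outer) - 1), min(ny, int(pos[1] + outer) + 2)
        z0, z1 = max(0, int(pos[2] - outer) - 1), min(nz, int(pos[2] + outer) + 2)
        box = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
        dist = np.sqrt((xx[box] - pos[0]) ** 2 + (yy[box] - pos[1]) ** 2
                       + (zz[box] - pos[2]) ** 2)
        sub = labels[box]
        sub[(dist > r) & (dist <= outer) & spleen[box]] = LABEL_MZ
        sub[(dist <= r) & spleen[box]] = LABEL_WP

    # vessels: straight tubes through the spleen interior, replacing red pulp
    pts = np.stack([xx, yy, zz], axis=-1)
    for _ in range(spec.vessel_count):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rho = rng.uniform(0, 0.5) ** (1 / 3)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        c = centre + v * rho * semi
        rel = pts - c
        along = rel @ u
        perp = np.linalg.norm(rel - along[..., None] * u, axis=-1)
        tube = (perp <= spec.vessel_radius * spec.cohort_scale) & spleen
        labels[tube & (labels == LABEL_RP)] = LABEL_VESSEL

    # bright streak artifacts: thin rods along x at a random (z, y)
    artifact = np.zeros_like(spleen)
    for _ in range(spec.artifact_count):
        az = rng.integers(nz // 4, 3 * nz // 4)
        ay = rng.integers(ny // 4, 3 * ny // 4)
        rod = (np.abs(zz - az) <= 0.5) & (np.abs(yy - ay) <= 1.0)
        artifact |= rod

    intens_map = {
        LABEL_BACKGROUND: spec.background_intensity,
        LABEL_RP: spec.rp_intensity,
        LABEL_MZ: spec.mz_intensity,
        LABEL_WP: spec.wp_intensity,
        LABEL_VESSEL: spec.vessel_intensity,
    }
    lut = np.zeros(6, dtype=np.float64)
    for lab, val in intens_map.items():
        lut[lab] = val
    intensity = lut[labels]
    intensity[artifact] = spec.artifact_intensity
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, intensity.shape)

    # ground-truth labels keep tissue identity under artifacts inside the spleen
    gt_labels = labels.copy()
    gt_labels[artifact & ~spleen] = LABEL_ARTIFACT
    count = int(np.isin(gt_labels, SPLEEN_LABELS).sum())
    gt = GroundTruth(
        label_volume=gt_labels, spleen_voxel_count=count,
        nodule_centres_radii=[(tuple(map(float, p)), float(r)) for p, r in placed],
        artifact_mask=artifact)
    vol = ImageVolume(intensity.astype(np.float32), dtype_role=RAW_FLOAT,
                      voxel_size_um=spec.voxel_size_um,
                      provenance=f"spleen phantom seed={spec.seed} "
                                 f"cohort_scale={spec.cohort_scale}")
    return vol, gt


def generate_cohort(vehicle_spec: PhantomSpec, treated_spec: PhantomSpec,
                    n_per_group: int, base_seed: int
                    ) -> list[tuple[str, ImageVolume, GroundTruth]]:
    """Generate 2 * n_per_group phantoms with per-sample seeds from base_seed.

    Per-sample seeds come from ``numpy.random.SeedSequence(base_seed)`` so
    the whole cohort is reproducible bitwise from one integer.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * n_per_group)
    seeds = [int(s % (2 ** 31)) for s in seeds]
    out = []
    for idx in range(n_per_group):
        spec = dataclasses.replace(vehicle_spec, seed=seeds[idx])
        vol, gt = generate_spleen_phantom(spec)
        out.append((f"vehicle", vol, gt))
    for idx in range(n_per_group):
        spec = dataclasses.replace(treated_spec, seed=seeds[n_per_group + idx])
        vol, gt = generate_spleen_phantom(spec)
        out.append((f"treated", vol, gt))
    return out
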