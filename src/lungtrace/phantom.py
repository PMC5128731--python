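"""Synthetic chest-CT phantoms with exact ground-truth masks.

A phantom slice is an elliptical soft-tissue body on an air background,
containing two low-attenuation elliptical lungs, a few bone-density blobs
(spine and ribs, which anchor the orientation estimate), and optional
juxta-pleural nodules: soft-tissue disks straddling the pleural boundary so
that density-based thresholding excludes them from the lung, leaving a
concave notch for the correction stage to repair.

Geometry is painted analytically in the *tilted* frame: each output pixel is
mapped through the inverse in-plane rotation and tested against the untilted
primitives.  Truth masks are therefore exact at every tilt and, before noise,
the image contains exactly the configured intensity levels.

The nodule model: a disk of radius ``r = diameter_mm / (2 * pixel_spacing)``
pixels whose center sits *inside* the lung at depth ``depth_frac * r`` from
the pleural boundary along the inward normal.  ``depth_frac in (0, 1)``
guarantees the disk crosses the boundary (juxta-pleural by construction);
the default 0.95 emulates a nodule embedded in the parenchyma that just
breaks the pleural surface.  The resulting thresholding notch is deeper
than wide (depth/width ~1.2-1.9 across the 6-17 mm diameter range); a more
protruding nodule erases the pleural line over a stretch comparable to its
diameter and the notch degenerates into a wide shallow bay.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .core import CTVolume
from .errors import InvalidSpec

__all__ = [
    "Ellipse",
    "BoneBlob",
    "Nodule",
    "IntensityLevels",
    "PhantomSpec",
    "PhantomOutput",
    "PhantomVolumeOutput",
    "default_spec",
    "generate_phantom",
    "generate_phantom_volume",
    "spec_to_yaml",
    "spec_from_yaml",
]


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in the untilted frame, pixel units."""

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a_row, a_col)

    def contains(self, r: np.ndarray, c: np.ndarray, scale: float = 1.0) -> np.ndarray:
        ar = self.semi_axes[0] * scale
        ac = self.semi_axes[1] * scale
        return ((r - self.center[0]) / ar) ** 2 + ((c - self.center[1]) / ac) ** 2 <= 1.0

    def boundary_point(self, angle_deg: float, scale: float = 1.0) -> tuple[float, float]:
        """Point on the ellipse; angle 0 points toward +col, 90 toward -row."""
        th = np.deg2rad(angle_deg)
        return (
            self.center[0] - self.semi_axes[0] * scale * np.sin(th),
            self.center[1] + self.semi_axes[1] * scale * np.cos(th),
        )


@dataclass(frozen=True)
class BoneBlob:
    center: tuple[float, float]  # (row, col)
    radius: float  # pixels


@dataclass(frozen=True)
class Nodule:
    """Juxta-pleural nodule attached to one lung's pleural boundary."""

    lung: int  # 0 = image-left lung, 1 = image-right lung
    angle_deg: float  # attachment angle on the lung ellipse
    diameter_mm: float  # must lie in [6, 17]
    intensity: float | None = None  # defaults to IntensityLevels.nodule
    depth_frac: float = 0.95  # center depth inside the lung, fraction of radius


@dataclass(frozen=True)
class IntensityLevels:
    """Hounsfield-like intensity levels for the painted materials."""

    background: float = -1000.0
    lung: float = -800.0
    body: float = 40.0
    bone: float = 400.0
    nodule: float = 20.0


@dataclass(frozen=True)
class PhantomSpec:
    image_shape: tuple[int, int] = (256, 256)
    pixel_spacing_mm: float = 0.7
    body_ellipse: Ellipse = field(
        default_factory=lambda: Ellipse((130.0, 128.0), (95.0, 115.0))
    )
    lung_ellipses: tuple[Ellipse, Ellipse] = field(
        default_factory=lambda: (
            Ellipse((132.0, 85.0), (62.0, 38.0)),
            Ellipse((132.0, 171.0), (62.0, 38.0)),
        )
    )
    # Spine at the posterior midline plus mirror-symmetric rib pairs.  The
    # lateral (column) spread dominates the row spread so the first principal
    # component of the bone pixels is horizontal in an untilted scan.
    bone_blobs: tuple[BoneBlob, ...] = field(
        default_factory=lambda: (
            BoneBlob((196.0, 128.0), 8.0),  # spine
            BoneBlob((64.0, 90.0), 5.0),
            BoneBlob((64.0, 166.0), 5.0),
            BoneBlob((80.0, 52.0), 5.0),
            BoneBlob((80.0, 204.0), 5.0),
            BoneBlob((100.0, 24.0), 5.0),
            BoneBlob((100.0, 232.0), 5.0),
            BoneBlob((130.0, 20.0), 5.0),
            BoneBlob((130.0, 236.0), 5.0),
        )
    )
    nodules: tuple[Nodule, ...] = ()
    tilt_deg: float = 0.0
    noise_sd: float = 0.0
    intensity_levels: IntensityLevels = field(default_factory=IntensityLevels)
    fused_lungs: bool = False
    fused_bridge_px: float = 3.0  # height of the anterior junction bar
    seed: int = 0


@dataclass
class PhantomOutput:
    image: np.ndarray  # (rows, cols) float
    truth_lung_mask: np.ndarray  # lungs including nodule disks
    truth_parenchyma_mask: np.ndarray  # lungs excluding nodule disks
    truth_left_mask: np.ndarray
    truth_right_mask: np.ndarray
    applied_tilt_deg: float
    spec: PhantomSpec


@dataclass
class PhantomVolumeOutput:
    volume: CTVolume
    truth_lung_mask: np.ndarray
    truth_parenchyma_mask: np.ndarray
    truth_left_mask: np.ndarray
    truth_right_mask: np.ndarray
    applied_tilt_deg: float


def default_spec(**overrides) -> PhantomSpec:
    """The standard 256x256 phantom; keyword overrides replace fields."""
    return replace(PhantomSpec(), **overrides)


# ---------------------------------------------------------------------------
# validation

def validate_spec(spec: PhantomSpec) -> None:
    if spec.pixel_spacing_mm <= 0:
        raise InvalidSpec("pixel_spacing_mm must be positive")
    if not -45.0 <= spec.tilt_deg <= 45.0:
        raise InvalidSpec("tilt_deg must lie in [-45, 45]")
    if spec.noise_sd < 0:
        raise InvalidSpec("noise_sd must be non-negative")
    if len(spec.lung_ellipses) != 2:
        raise InvalidSpec("exactly two lung ellipses are required")

    angles = np.arange(0.0, 360.0, 0.5)
    body = spec.body_ellipse
    for lung in spec.lung_ellipses:
        pts = np.array([lung.boundary_point(a) for a in angles])
        inside = body.contains(pts[:, 0], pts[:, 1], scale=0.999)
        if not inside.all():
            raise InvalidSpec("lung ellipse not strictly inside body ellipse")
    if not spec.fused_lungs:
        l0, l1 = spec.lung_ellipses
        pts0 = np.array([l0.boundary_point(a) for a in angles])
        if l1.contains(pts0[:, 0], pts0[:, 1]).any() or l1.contains(
            *np.array(l0.center)[:, None]
        ):
            raise InvalidSpec("lung ellipses overlap without fused_lungs flag")

    for nod in spec.nodules:
        if not 6.0 <= nod.diameter_mm <= 17.0:
            raise InvalidSpec(f"nodule diameter {nod.diameter_mm} mm outside [6, 17]")
        if nod.lung not in (0, 1):
            raise InvalidSpec("nodule.lung must be 0 (left) or 1 (right)")
        if not 0.0 < nod.depth_frac < 1.0:
            raise InvalidSpec(
                "nodule.depth_frac must lie in (0, 1) so the disk crosses the pleura"
            )


def _nodule_center_radius(spec: PhantomSpec, nod: Nodule) -> tuple[tuple[float, float], float]:
    lung = spec.lung_ellipses[nod.lung]
    r_px = nod.diameter_mm / (2.0 * spec.pixel_spacing_mm)
    bp = np.array(lung.boundary_point(nod.angle_deg))
    inward = np.array(lung.center) - bp
    inward = inward / np.linalg.norm(inward)
    center = bp + inward * nod.depth_frac * r_px
    return (float(center[0]), float(center[1])), r_px


# ---------------------------------------------------------------------------
# rendering

def _untilted_coords(shape: tuple[int, int], tilt_deg: float):
    """Map output pixel grid back to the untilted frame (rotation about center)."""
    rr, cc = np.indices(shape, dtype=float)
    cr = (shape[0] - 1) / 2.0
    ccen = (shape[1] - 1) / 2.0
    th = np.deg2rad(tilt_deg)
    dr, dc = rr - cr, cc - ccen
    r0 = cr + np.cos(th) * dr - np.sin(th) * dc
    c0 = ccen + np.sin(th) * dr + np.cos(th) * dc
    return r0, c0


def _bridge_mask(spec: PhantomSpec, r0: np.ndarray, c0: np.ndarray) -> np.ndarray:
    """Lung-density bar joining the two lungs near the anterior midline."""
    l0, l1 = spec.lung_ellipses
    row_c = 0.5 * (l0.center[0] + l1.center[0]) - 0.55 * min(
        l0.semi_axes[0], l1.semi_axes[0]
    )
    h = spec.fused_bridge_px / 2.0
    c_lo = min(l0.center[1], l1.center[1])
    c_hi = max(l0.center[1], l1.center[1])
    return (
        (np.abs(r0 - row_c) <= h) & (c0 >= c_lo) & (c0 <= c_hi)
    )


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render one phantom slice and its exact ground-truth masks.

    Deterministic for a fixed ``spec`` (the noise generator is seeded by
    ``spec.seed``).
    """
    validate_spec(spec)
    lv = spec.intensity_levels
    r0, c0 = _untilted_coords(spec.image_shape, spec.tilt_deg)

    body = spec.body_ellipse.contains(r0, c0)
    lung_l = spec.lung_ellipses[0].contains(r0, c0) & body
    lung_r = spec.lung_ellipses[1].contains(r0, c0) & body

    if spec.fused_lungs:
        bridge = _bridge_mask(spec, r0, c0) & body
        mid = 0.5 * (spec.lung_ellipses[0].center[1] + spec.lung_ellipses[1].center[1])
        lung_l |= bridge & (c0 <= mid)
        lung_r |= bridge & (c0 > mid)
    lungs = lung_l | lung_r

    image = np.full(spec.image_shape, lv.background, dtype=float)
    image[body] = lv.body
    image[lungs] = lv.lung

    for blob in spec.bone_blobs:
        disk = (r0 - blob.center[0]) ** 2 + (c0 - blob.center[1]) ** 2 <= blob.radius**2
        image[disk & body & ~lungs] = lv.bone

    nodule_union = np.zeros(spec.image_shape, dtype=bool)
    nodule_left = np.zeros(spec.image_shape, dtype=bool)
    nodule_right = np.zeros(spec.image_shape, dtype=bool)
    for nod in spec.nodules:
        center, r_px = _nodule_center_radius(spec, nod)
        disk = (r0 - center[0]) ** 2 + (c0 - center[1]) ** 2 <= r_px**2
        disk &= body
        image[disk] = lv.nodule if nod.intensity is None else nod.intensity
        nodule_union |= disk
        if nod.lung == 0:
            nodule_left |= disk
        else:
            nodule_right |= disk

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)

    return PhantomOutput(
        image=image,
        truth_lung_mask=lungs | nodule_union,
        truth_parenchyma_mask=lungs & ~nodule_union,
        truth_left_mask=lung_l | nodule_left,
        truth_right_mask=lung_r | nodule_right,
        applied_tilt_deg=spec.tilt_deg,
        spec=spec,
    )


def generate_phantom_volume(
    spec: PhantomSpec,
    n_slices: int = 20,
    scale_min: float = 0.75,
    slice_thickness_mm: float = 1.0,
) -> PhantomVolumeOutput:
    """Stack per-slice phantoms into a volume with a lung-size profile.

    Lung semi-axes follow a sinusoidal apex-to-base profile between
    ``scale_min`` and 1; nodules are rendered only on the central half of
    slices so their attachment geometry stays valid as the lungs shrink.
    """
    if n_slices < 1:
        raise InvalidSpec("n_slices must be >= 1")
    slices, lungs, pars, lefts, rights = [], [], [], [], []
    for i in range(n_slices):
        f = scale_min + (1.0 - scale_min) * np.sin(np.pi * (i + 0.5) / n_slices)
        central = abs(i - (n_slices - 1) / 2.0) <= n_slices / 4.0
        sl_spec = replace(
            spec,
            lung_ellipses=tuple(
                Ellipse(e.center, (e.semi_axes[0] * f, e.semi_axes[1] * f))
                for e in spec.lung_ellipses
            ),
            nodules=spec.nodules if central else (),
            seed=spec.seed + i,
        )
        out = generate_phantom(sl_spec)
        slices.append(out.image)
        lungs.append(out.truth_lung_mask)
        pars.append(out.truth_parenchyma_mask)
        lefts.append(out.truth_left_mask)
        rights.append(out.truth_right_mask)
    vol = CTVolume(
        np.stack(slices),
        spacing=(slice_thickness_mm, spec.pixel_spacing_mm, spec.pixel_spacing_mm),
    )
    return PhantomVolumeOutput(
        volume=vol,
        truth_lung_mask=np.stack(lungs),
        truth_parenchyma_mask=np.stack(pars),
        truth_left_mask=np.stack(lefts),
        truth_right_mask=np.stack(rights),
        applied_tilt_deg=spec.tilt_deg,
    )


# ---------------------------------------------------------------------------
# (de)serialization

def spec_to_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    d["body_ellipse"] = _ellipse_from(d["body_ellipse"])
    d["lung_ellipses"] = tuple(_ellipse_from(e) for e in d["lung_ellipses"])
    d["bone_blobs"] = tuple(
        BoneBlob(tuple(b["center"]), b["radius"]) for b in d.get("bone_blobs", ())
    )
    d["nodules"] = tuple(Nodule(**n) for n in d.get("nodules", ()))
    d["intensity_levels"] = IntensityLevels(**d.get("intensity_levels", {}))
    d["image_shape"] = tuple(d["image_shape"])
    return PhantomSpec(**d)


def _ellipse_from(e: dict) -> Ellipse:
    return Ellipse(tuple(e["center"]), tuple(e["semi_axes"]))


def spec_to_yaml(spec: PhantomSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(spec_to_dict(spec))), fh)


def spec_from_yaml(path) -> PhantomSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
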