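"""Synthetic Hounsfield-unit phantoms of an instrumented vertebral body.

The phantom approximates a vertebral body as an elliptic cylinder with a
cortical shell and a trabecular core, optionally instrumented with two
transpedicular screw cylinders.  It produces a labelled HU volume on a
regular voxel grid so that every downstream stage (calibration, lesion
blending, meshing, fracture simulation) can be exercised without any
imaging data.

Axes: x mediolateral (+x = patient left), y anteroposterior (+y =
anterior), z craniocaudal (+z = cranial); the world origin is the body
centroid.

Lesions are *not* burned into the HU values: metastases enter the model
through the material field (see :mod:`vertfrac.lesions`), mirroring how a
lesion alters constitutive properties rather than the reconstructed
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lesions import Lesion
from .regions import CORTICAL, HU_CORTICAL_THRESHOLD, OUTSIDE, SCREW, TRABECULAR
from .volume import HUVolume

__all__ = [
    "ScrewSpec",
    "PhantomSpec",
    "HUVolume",
    "build_vertebra_phantom",
    "build_block_phantom",
    "default_lesion_positions",
]


@dataclass(frozen=True)
class ScrewSpec:
    """A pair of cylindrical pedicle-screw analogues.

    Screws enter from the posterior surface, converge toward the midline
    by ``mediolateral_angle_deg``, tilt caudally by
    ``craniocaudal_angle_deg`` and run ``depth_mm`` into the body.  The
    bone-screw interface is bonded (shared mesh nodes downstream).
    """

    radius_mm: float = 2.5
    depth_mm: float = 30.0
    craniocaudal_angle_deg: float = 5.0
    mediolateral_angle_deg: float = 5.0
    entry_offset_x_mm: float = 8.0  # lateral offset of each entry point


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic vertebral-body volume."""

    semi_axis_x_mm: float = 24.0
    semi_axis_y_mm: float = 18.0
    height_mm: float = 30.0
    shell_thickness_mm: float = 2.0
    hu_cortical_mean: float = 923.0
    hu_trabecular_mean: float = 200.0
    hu_noise_sd: float = 25.0
    hu_outside: float = -1000.0
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    screw_spec: ScrewSpec | None = ScrewSpec()
    lesion_specs: tuple[Lesion, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.semi_axis_x_mm, self.semi_axis_y_mm, self.height_mm) <= 0:
            raise ValueError("body dimensions must be positive")
        if self.shell_thickness_mm <= 0:
            raise ValueError("shell_thickness_mm must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be strictly positive")
        if self.hu_cortical_mean < HU_CORTICAL_THRESHOLD:
            raise ValueError(
                f"hu_cortical_mean must be >= {HU_CORTICAL_THRESHOLD} so that "
                "cortical voxels classify as cortical before noise"
            )
        if self.hu_trabecular_mean >= HU_CORTICAL_THRESHOLD:
            raise ValueError(
                f"hu_trabecular_mean must be < {HU_CORTICAL_THRESHOLD}"
            )
        if self.hu_noise_sd < 0:
            raise ValueError("hu_noise_sd must be non-negative")


def _grid(spec: PhantomSpec):
    sx, sy, sz = spec.voxel_spacing_mm
    # one voxel of margin around the body keeps surfaces well defined
    nx = int(np.ceil(2 * spec.semi_axis_x_mm / sx)) + 2
    ny = int(np.ceil(2 * spec.semi_axis_y_mm / sy)) + 2
    nz = int(np.ceil(spec.height_mm / sz)) + 2
    origin = (-nx * sx / 2.0, -ny * sy / 2.0, -nz * sz / 2.0)
    axes = [
        origin[a] + (np.arange(n) + 0.5) * s
        for a, (n, s) in enumerate(zip((nx, ny, nz), (sx, sy, sz)))
    ]
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return centers, (nx, ny, nz), origin


def _in_ellipse(x, y, a, b):
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def _screw_axes(spec: PhantomSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Entry point and unit direction of each screw (left/right pair)."""
    sc = spec.screw_spec
    assert sc is not None
    out = []
    cc = np.deg2rad(sc.craniocaudal_angle_deg)
    ml = np.deg2rad(sc.mediolateral_angle_deg)
    for side in (+1.0, -1.0):
        x0 = side * sc.entry_offset_x_mm
        if abs(x0) >= spec.semi_axis_x_mm:
            raise ValueError("screw entry offset outside body")
        # posterior surface of the ellipse at that lateral offset
        y0 = -spec.semi_axis_y_mm * np.sqrt(
            1.0 - (x0 / spec.semi_axis_x_mm) ** 2
        )
        entry = np.array([x0, y0, 0.0])
        # anteriorly directed, converging toward the midline, tilting caudally
        direction = np.array(
            [-side * np.sin(ml), np.cos(ml) * np.cos(cc), -np.sin(cc)]
        )
        direction /= np.linalg.norm(direction)
        tip = entry + sc.depth_mm * direction
        if not (
            _in_ellipse(tip[0], tip[1], spec.semi_axis_x_mm, spec.semi_axis_y_mm)
            and abs(tip[2]) <= spec.height_mm / 2.0
        ):
            raise ValueError("screw depth exceeds body extent")
        out.append((entry, direction))
    return out


def build_vertebra_phantom(spec: PhantomSpec) -> HUVolume:
    """Generate the labelled HU volume of the vertebral-body phantom.

    Deterministic for a fixed ``spec.rng_seed``.  Labels are assigned from
    the noise-free geometry; Gaussian HU noise (truncated at +-4 SD) is
    added afterwards so labels stay consistent with expected HU values.
    """
    centers, shape, origin = _grid(spec)
    x, y, z = centers[..., 0], centers[..., 1], centers[..., 2]
    a, b, h2 = spec.semi_axis_x_mm, spec.semi_axis_y_mm, spec.height_mm / 2.0
    t = spec.shell_thickness_mm

    in_body = _in_ellipse(x, y, a, b) & (np.abs(z) <= h2)
    inner_a, inner_b, inner_h2 = a - t, b - t, h2 - t
    if min(inner_a, inner_b, inner_h2) <= 0:
        raise ValueError("shell thickness exceeds body semi-extent")
    in_core = _in_ellipse(x, y, inner_a, inner_b) & (np.abs(z) <= inner_h2)

    labels = np.full(shape, OUTSIDE, dtype=np.int8)
    labels[in_body] = CORTICAL
    labels[in_body & in_core] = TRABECULAR

    if spec.screw_spec is not None:
        pts = centers.reshape(-1, 3)
        screw_mask = np.zeros(pts.shape[0], dtype=bool)
        for entry, direction in _screw_axes(spec):
            rel = pts - entry
            s = np.clip(rel @ direction, 0.0, spec.screw_spec.depth_mm)
            closest = entry + s[:, None] * direction
            d2 = np.sum((pts - closest) ** 2, axis=1)
            screw_mask |= d2 <= spec.screw_spec.radius_mm**2
        labels[screw_mask.reshape(shape) & in_body] = SCREW

    for j, lesion in enumerate(spec.lesion_specs):
        c = np.asarray(lesion.center)
        d2 = np.sum((centers - c) ** 2, axis=-1)
        if not np.any((d2 <= lesion.radius**2) & in_body):
            raise ValueError(
                f"lesion {j} at {tuple(c)} R={lesion.radius} mm lies entirely "
                "outside the phantom body"
            )

    values = np.full(shape, spec.hu_outside, dtype=float)
    values[labels == CORTICAL] = spec.hu_cortical_mean
    values[labels == TRABECULAR] = spec.hu_trabecular_mean
    # metal fill-in; screw material properties come from the label, not HU
    values[labels == SCREW] = spec.hu_cortical_mean

    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        noise = rng.standard_normal(shape)
        np.clip(noise, -4.0, 4.0, out=noise)
        values[in_body] += spec.hu_noise_sd * noise[in_body]

    return HUVolume(values, labels, spec.voxel_spacing_mm, origin)


def build_block_phantom(
    dimensions_mm: tuple[float, float, float],
    hu_value: float,
    spacing_mm: float | tuple[float, float, float] = 1.0,
) -> HUVolume:
    """Homogeneous rectangular block, used for solver verification.

    Every voxel is in-body; the label follows the HU threshold (trabecular
    below 700 HU, cortical at or above).
    """
    if np.isscalar(spacing_mm):
        spacing = (float(spacing_mm),) * 3
    else:
        spacing = tuple(float(s) for s in spacing_mm)
    dims = tuple(float(d) for d in dimensions_mm)
    if any(d <= 0 for d in dims):
        raise ValueError("block dimensions must be positive")
    shape = tuple(max(1, int(round(d / s))) for d, s in zip(dims, spacing))
    label = CORTICAL if hu_value >= HU_CORTICAL_THRESHOLD else TRABECULAR
    values = np.full(shape, float(hu_value))
    labels = np.full(shape, label, dtype=np.int8)
    origin = tuple(-n * s / 2.0 for n, s in zip(shape, spacing))
    return HUVolume(values, labels, spacing, origin)


def default_lesion_positions(
    spec: PhantomSpec,
) -> dict[str, tuple[float, float, float]]:
    """Canonical lesion centers scaled to the phantom semi-axes.

    P1 lateral right, P2 anterior right, P3 anterior, all at mid-height
    (+x is patient left, so "right" is -x).
    """
    a, b = spec.semi_axis_x_mm, spec.semi_axis_y_mm
    return {
        "P1": (-0.50 * a, 0.0, 0.0),
        "P2": (-0.35 * a, 0.40 * b, 0.0),
        "P3": (0.0, 0.45 * b, 0.0),
    }
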