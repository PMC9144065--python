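"""Phantomless CT calibration: HU correction and the density chain.

The conversion chain is HU -> apparent density -> Young's modulus, with a
separate affine map to ash density for the stress failure limits:

* HU correction: the cortical mean HU is computed over voxels at or above
  the 700 HU threshold, voxels outside the bone domain are replaced by
  that mean (suppressing partial-volume artefacts at the surface), and the
  whole grid is smoothed with a moving-average filter.
* ``rho_app = rho_max * HU / hu_max`` — a linear phantomless calibration
  anchored at (0 HU, 0 g/cm3) and (hu_max, 1.9 g/cm3), the maximum
  apparent density of cortical bone.
* Trabecular modulus ``E_T = 4730 * rho_app^1.56`` (MPa); cortical modulus
  ``E_C = -892.5 * rho_app^-2.491 + 14360`` (MPa).  The branch is selected
  by the element's region label, which is frozen from the *raw* HU
  threshold before smoothing.
* Ash density ``rho_ash = 0.551 * rho_app - 0.00478`` (g/cm3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .regions import CORTICAL, HU_CORTICAL_THRESHOLD, SCREW, TRABECULAR
from .volume import HUVolume

#: Titanium-alloy screw elastic constants.
SCREW_E_MPA = 110_000.0
SCREW_NU = 0.4

#: Floor on bone Young's modulus before lesion blending (MPa); guards the
#: stiffness matrix against near-zero-density voxels.  Lesion and failed
#: elements may go below it by design.
E_FLOOR_BONE_MPA = 1.0

#: Young's modulus assigned to failed (killed) elements, MPa.
E_KILLED_MPA = 1e-6


@dataclass(frozen=True)
class CalibrationParams:
    """Parameters of the HU-correction and density-calibration chain."""

    hu_cortical_threshold: float = HU_CORTICAL_THRESHOLD
    rho_max: float = 1.9  # g/cm3, apparent density at hu_max
    hu_max: float = 1109.0  # HU mapped to rho_max
    hu_max_from_volume: bool = False  # recompute hu_max as the volume max
    smoothing_kernel: int = 3  # odd, voxels per axis
    poisson_bone: float = 0.3

    def __post_init__(self) -> None:
        if self.hu_max <= 0:
            raise ValueError("hu_max must be positive")
        if self.rho_max <= 0:
            raise ValueError("rho_max must be positive")
        if self.smoothing_kernel < 1 or self.smoothing_kernel % 2 == 0:
            raise ValueError("smoothing_kernel must be odd and >= 1")

    def resolve_hu_max(self, volume: HUVolume) -> float:
        if self.hu_max_from_volume:
            return float(volume.values[volume.in_body_mask()].max())
        return self.hu_max


@dataclass
class MaterialField:
    """Per-element elastic constants and densities.

    Arrays are aligned with the canonical element ordering of the source
    volume (C-order over in-body voxels).  ``region`` uses the shared
    label codes, with ``FAILED`` marking killed elements (E = 1e-6 MPa
    exactly).
    """

    E: np.ndarray  # MPa
    nu: np.ndarray
    rho_app: np.ndarray  # g/cm3
    rho_ash: np.ndarray  # g/cm3
    region: np.ndarray  # int codes

    def __post_init__(self) -> None:
        n = len(self.E)
        for name in ("nu", "rho_app", "rho_ash", "region"):
            if len(getattr(self, name)) != n:
                raise ValueError("material arrays must be aligned")
        if np.any(self.E <= 0):
            raise ValueError("E must be strictly positive everywhere")

    @property
    def n_elements(self) -> int:
        return len(self.E)

    def copy(self) -> "MaterialField":
        return MaterialField(
            self.E.copy(),
            self.nu.copy(),
            self.rho_app.copy(),
            self.rho_ash.copy(),
            self.region.copy(),
        )


def cortical_mean_hu(volume: HUVolume, params: CalibrationParams) -> float:
    """Mean HU over cortical-range voxels (HU >= threshold) in the body."""
    mask = volume.in_body_mask() & (
        volume.values >= params.hu_cortical_threshold
    )
    if not np.any(mask):
        raise ValueError("no cortical voxels: cortical mean HU is undefined")
    return float(volume.values[mask].mean())


def correct_hu(volume: HUVolume, params: CalibrationParams) -> HUVolume:
    """HU correction: outside fill with the cortical mean, then smoothing.

    Returns a new volume; labels are carried over unchanged (regions are
    frozen from raw HU before smoothing).
    """
    values = volume.values.copy()
    outside = ~volume.in_body_mask()
    if np.any(outside):
        values[outside] = cortical_mean_hu(volume, params)
    k = params.smoothing_kernel
    if k > 1:
        values = ndimage.uniform_filter(values, size=k, mode="nearest")
    return HUVolume(values, volume.labels.copy(), volume.spacing, volume.origin)


def hu_to_density(hu, params: CalibrationParams | None = None):
    """Apparent density (g/cm3) from HU; negative HU clamps to zero."""
    p = params or CalibrationParams()
    rho = p.rho_max * np.asarray(hu, dtype=float) / p.hu_max
    return np.maximum(rho, 0.0)[()]


def density_to_modulus(rho_app, region):
    """Young's modulus (MPa) from apparent density.

    ``region`` is ``"trabecular"``/``"cortical"`` (applied uniformly) or an
    array of region codes aligned with ``rho_app``.  Results are floored
    at ``E_FLOOR_BONE_MPA``; the cortical law is singular at zero density.
    """
    rho = np.asarray(rho_app, dtype=float)
    if isinstance(region, str):
        if region == "trabecular":
            E = 4730.0 * rho**1.56
        elif region == "cortical":
            if np.any(rho <= 0):
                raise ValueError(
                    "cortical modulus law is singular at zero density"
                )
            E = -892.5 * rho**-2.491 + 14360.0
        else:
            raise ValueError(f"unknown region {region!r}")
        return np.maximum(E, E_FLOOR_BONE_MPA)[()]
    region = np.asarray(region)
    E = np.empty_like(rho)
    trab = region == TRABECULAR
    cort = region == CORTICAL
    if not np.all(trab | cort):
        raise ValueError("region codes must be trabecular or cortical")
    E[trab] = 4730.0 * rho[trab] ** 1.56
    if np.any(rho[cort] <= 0):
        raise ValueError("cortical modulus law is singular at zero density")
    E[cort] = -892.5 * rho[cort] ** -2.491 + 14360.0
    return np.maximum(E, E_FLOOR_BONE_MPA)


def density_to_ash(rho_app):
    """Ash density (g/cm3) from apparent density; floored at zero."""
    rho_ash = 0.551 * np.asarray(rho_app, dtype=float) - 0.00478
    return np.maximum(rho_ash, 0.0)[()]


def calibrate(
    volume: HUVolume, params: CalibrationParams | None = None
) -> MaterialField:
    """Run the full correction + conversion chain on a labelled volume.

    Produces the lesion-free per-element material field: bone moduli from
    the region-specific density laws, screw elements at 110 GPa / nu 0.4.
    Lesions are blended in afterwards (:func:`vertfrac.lesions.build_material_field`).
    """
    params = params or CalibrationParams()
    if params.hu_max_from_volume:
        params = replace(
            params,
            hu_max=params.resolve_hu_max(volume),
            hu_max_from_volume=False,
        )
    corrected = correct_hu(volume, params)
    order = volume.element_order()
    hu = corrected.values.ravel()[order]
    region = volume.labels.ravel()[order].astype(np.int8)

    rho_app = np.asarray(hu_to_density(hu, params))
    rho_ash = np.asarray(density_to_ash(rho_app))
    E = np.full(len(order), SCREW_E_MPA)
    nu = np.full(len(order), params.poisson_bone)
    bone = region != SCREW
    E[bone] = density_to_modulus(rho_app[bone], region[bone])
    nu[~bone] = SCREW_NU
    # densities are reported for bone only; screws carry placeholders
    rho_app[~bone] = 0.0
    rho_ash[~bone] = 0.0
    return MaterialField(E, nu, rho_app, rho_ash, region)


def material_table(field: MaterialField):
    """Material field as a pandas DataFrame (element id, E, nu, densities)."""
    import pandas as pd

    from .regions import REGION_NAMES

    return pd.DataFrame(
        {
            "element": np.arange(field.n_elements),
            "E_MPa": field.E,
            "nu": field.nu,
            "rho_app_g_cm3": field.rho_app,
            "rho_ash_g_cm3": field.rho_ash,
            "region": [REGION_NAMES[int(r)] for r in field.region],
        }
    )
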