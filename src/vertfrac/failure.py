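"""Principal-stress / principal-strain failure criteria and element kill.

An element fails when its tensile OR compressive condition holds with
strict inequality:

* stress criterion — ``sigma+ > sigma_bar+`` or ``sigma- > sigma_bar-``,
  where ``sigma+ = max{0, s1, s2, s3}`` and ``sigma- = -min{0, s1, s2, s3}``
  are local stress measures from the principal stresses, and the limits
  are ash-density power laws: compressive ``137 * rho_ash^1.88`` MPa for
  trabecular and ``114 * rho_ash^1.72`` MPa for cortical bone, with a
  unique tensile limit of 0.8x the compressive one.  The trabecular /
  cortical branch follows the element's original region label (frozen at
  calibration from the raw-HU threshold).
* strain criterion — density-independent limits: 0.73% in tension and
  1.04% in compression, on the analogous principal-strain measures.

Failed elements have their Young's modulus set to 1e-6 MPa exactly
(element kill); Poisson's ratio is untouched.  Screw elements and
already-failed elements are never tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import E_KILLED_MPA, MaterialField
from .regions import CORTICAL, FAILED, SCREW, TRABECULAR

#: Density-independent strain limits (dimensionless).
STRAIN_LIMIT_TENSION = 0.73e-2
STRAIN_LIMIT_COMPRESSION = 1.04e-2

#: Compressive stress-limit power laws (MPa vs ash density in g/cm3).
STRESS_COEFF_TRABECULAR = (137.0, 1.88)
STRESS_COEFF_CORTICAL = (114.0, 1.72)
TENSILE_FACTOR = 0.8


@dataclass(frozen=True)
class FailureCriterion:
    """Failure-rule configuration: ``kind`` is ``"stress"`` or ``"strain"``."""

    kind: str = "strain"
    strain_limit_tension: float = STRAIN_LIMIT_TENSION
    strain_limit_compression: float = STRAIN_LIMIT_COMPRESSION
    trabecular_coeff: tuple[float, float] = STRESS_COEFF_TRABECULAR
    cortical_coeff: tuple[float, float] = STRESS_COEFF_CORTICAL
    tensile_factor: float = TENSILE_FACTOR
    killed_modulus: float = E_KILLED_MPA

    def __post_init__(self) -> None:
        if self.kind not in ("stress", "strain"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if min(self.strain_limit_tension, self.strain_limit_compression) <= 0:
            raise ValueError("strain limits must be strictly positive")
        if not 0.0 < self.tensile_factor <= 1.0:
            raise ValueError("tensile_factor must be in (0, 1]")


def local_stress_measures(principal_stresses) -> tuple:
    """Tensile/compressive local measures (both >= 0) from principals.

    Works on a single triple or an (n, 3) array; for strains identically.
    """
    p = np.asarray(principal_stresses, dtype=float)
    plus = np.maximum(p.max(axis=-1), 0.0)
    minus = -np.minimum(p.min(axis=-1), 0.0)
    return plus[()], minus[()]


def stress_limits(
    rho_ash, region, criterion: FailureCriterion | None = None
) -> tuple:
    """(tensile, compressive) stress limits in MPa.

    ``region`` is ``"trabecular"``/``"cortical"`` or an array of region
    codes aligned with ``rho_ash``.
    """
    c = criterion or FailureCriterion(kind="stress")
    rho = np.asarray(rho_ash, dtype=float)
    if isinstance(region, str):
        a, b = (
            c.trabecular_coeff if region == "trabecular" else c.cortical_coeff
        )
        if region not in ("trabecular", "cortical"):
            raise ValueError(f"unknown region {region!r}")
        minus = a * rho**b
    else:
        region = np.asarray(region)
        minus = np.empty_like(rho)
        trab = region == TRABECULAR
        at, bt = c.trabecular_coeff
        ac, bc = c.cortical_coeff
        minus[trab] = at * rho[trab] ** bt
        minus[~trab] = ac * rho[~trab] ** bc
    return (c.tensile_factor * minus)[()], minus[()]


def evaluate_failure(
    solution, field: MaterialField, criterion: FailureCriterion
) -> np.ndarray:
    """Element indices newly failing under the criterion (strict ``>``).

    Screw and already-failed elements are never re-tested.
    """
    candidates = (field.region == TRABECULAR) | (field.region == CORTICAL)
    if criterion.kind == "strain":
        plus, minus = local_stress_measures(solution.principal_strains)
        fails = (plus > criterion.strain_limit_tension) | (
            minus > criterion.strain_limit_compression
        )
    else:
        plus, minus = local_stress_measures(solution.principal_stresses)
        lim_plus = np.empty(field.n_elements)
        lim_minus = np.empty(field.n_elements)
        lim_plus[candidates], lim_minus[candidates] = stress_limits(
            field.rho_ash[candidates], field.region[candidates], criterion
        )
        lim_plus[~candidates] = lim_minus[~candidates] = np.inf
        fails = (plus > lim_plus) | (minus > lim_minus)
    return np.flatnonzero(fails & candidates)


def kill_elements(field: MaterialField, failed) -> MaterialField:
    """Return a copy with failed elements' E set to the kill modulus.

    Idempotent; killing a screw element is an error.
    """
    failed = np.asarray(failed, dtype=int)
    out = field.copy()
    if len(failed) == 0:
        return out
    if np.any(field.region[failed] == SCREW):
        raise ValueError("cannot kill screw elements")
    out.E[failed] = E_KILLED_MPA
    out.region[failed] = FAILED
    return out
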