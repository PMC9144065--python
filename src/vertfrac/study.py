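"""Parametric study runner: the full lesion / load / criterion grid.

The default design crosses 2 load cases (extension EXT, left lateral
bending LLB) x 2 failure criteria (stress, strain) x 2 lesion types
(osteolytic, osteoblastic) x 3 positions (P1 lateral right, P2 anterior
right, P3 anterior) x 2 radii (R1 = 5 mm, R2 = 10 mm) = 48 single-lesion
runs, plus 4 multiple-lesion combinations (P1+P2, P1+P3, P2+P3,
P1+P2+P3, all osteolytic R2 under LLB with the strain criterion), for 52
runs in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .calibration import CalibrationParams
from .failure import FailureCriterion
from .fe import LoadCase, extension_load, lateral_bending_load, mesh_from_volume
from .fracture import LoadSchedule, run_fracture
from .lesions import Lesion, build_material_field
from .phantom import PhantomSpec, build_vertebra_phantom, default_lesion_positions

logger = logging.getLogger(__name__)

DEFAULT_RADII = {"R1": 5.0, "R2": 10.0}
DEFAULT_MULTI_CASES = (("P1", "P2"), ("P1", "P3"), ("P2", "P3"), ("P1", "P2", "P3"))


@dataclass(frozen=True)
class RunSpec:
    """One cell of the parametric grid."""

    load_case: str
    criterion: str
    lesion_type: str
    positions: tuple[str, ...]
    radius_label: str

    @property
    def key(self) -> str:
        return "_".join(
            [
                self.load_case,
                self.criterion,
                self.lesion_type,
                "+".join(self.positions),
                self.radius_label,
            ]
        )


@dataclass
class StudyConfig:
    """The study design: phantom, grid axes and numerical controls."""

    phantom: PhantomSpec = dc_field(default_factory=PhantomSpec)
    load_cases: tuple[str, ...] = ("EXT", "LLB")
    criteria: tuple[str, ...] = ("stress", "strain")
    lesion_types: tuple[str, ...] = ("osteolytic", "osteoblastic")
    positions: dict | None = None  # name -> center (mm); default: phantom-scaled
    radii: dict = dc_field(default_factory=lambda: dict(DEFAULT_RADII))
    multi_lesion_cases: tuple = DEFAULT_MULTI_CASES
    multi_lesion_radius: str = "R2"
    multi_lesion_load_case: str = "LLB"
    multi_lesion_criterion: str = "strain"
    multi_lesion_type: str = "osteolytic"
    moment_nmm: float = 4700.0
    body_fraction: float = 0.8
    facet_fraction_of_body: float = 0.3
    calibration: CalibrationParams = dc_field(default_factory=CalibrationParams)
    schedule: LoadSchedule = dc_field(default_factory=LoadSchedule)

    def __post_init__(self) -> None:
        if self.positions is None:
            self.positions = default_lesion_positions(self.phantom)
        if len(set(map(tuple, self.positions.values()))) != len(self.positions):
            raise ValueError("lesion positions must be distinct")
        if not self.radii:
            raise ValueError("radii must be non-empty")
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("radii must be positive")
        for combo in self.multi_lesion_cases:
            for p in combo:
                if p not in self.positions:
                    raise ValueError(f"multi-lesion case references unknown position {p!r}")

    def load_case_for(self, name: str) -> LoadCase:
        kw = dict(
            moment_nmm=self.moment_nmm,
            body_fraction=self.body_fraction,
            facet_fraction_of_body=self.facet_fraction_of_body,
        )
        if name == "EXT":
            return extension_load(**kw)
        if name == "LLB":
            return lateral_bending_load(**kw)
        raise ValueError(f"unknown load case {name!r}")

    def lesions_for(self, run: RunSpec) -> list[Lesion]:
        radius = self.radii[run.radius_label]
        return [
            Lesion(center=tuple(self.positions[p]), radius=radius, type=run.lesion_type)
            for p in run.positions
        ]


def enumerate_runs(config: StudyConfig) -> list[RunSpec]:
    """Deterministically ordered run list: grid product plus multi-lesion
    combinations.  Duplicate run keys are an error."""
    runs = [
        RunSpec(lc, cr, lt, (pos,), rl)
        for lc in sorted(config.load_cases)
        for cr in sorted(config.criteria)
        for lt in sorted(config.lesion_types)
        for pos in sorted(config.positions)
        for rl in sorted(config.radii)
    ]
    for combo in config.multi_lesion_cases:
        runs.append(
            RunSpec(
                config.multi_lesion_load_case,
                config.multi_lesion_criterion,
                config.multi_lesion_type,
                tuple(combo),
                config.multi_lesion_radius,
            )
        )
    keys = [r.key for r in runs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate run keys in study design")
    return runs


def run_single(
    config: StudyConfig,
    run: RunSpec | None = None,
    lesions: list[Lesion] | None = None,
    load_case: LoadCase | None = None,
    criterion: FailureCriterion | None = None,
):
    """Run one fracture simulation; ``run`` or explicit pieces may be given."""
    volume = build_vertebra_phantom(config.phantom)
    if run is not None:
        lesions = config.lesions_for(run)
        load_case = config.load_case_for(run.load_case)
        criterion = FailureCriterion(kind=run.criterion)
    field = build_material_field(volume, config.calibration, lesions or [])
    model = mesh_from_volume(volume, field, load_case=load_case)
    return run_fracture(model, field, criterion or FailureCriterion(), config.schedule)


def run_study(config: StudyConfig, runs: list[RunSpec] | None = None) -> pd.DataFrame:
    """Execute the (possibly restricted) grid and tabulate fracture loads.

    Failures of individual runs are recorded in the ``status`` column and
    never abort the study.  The phantom volume and mesh are built once
    and shared; each run swaps in its own material field and load case.
    """
    runs = enumerate_runs(config) if runs is None else runs
    volume = build_vertebra_phantom(config.phantom)
    base_field = build_material_field(volume, config.calibration, [])
    model = mesh_from_volume(volume, base_field)
    rows = []
    for run in runs:
        logger.info("run %s", run.key)
        try:
            field = build_material_field(
                volume, config.calibration, config.lesions_for(run)
            )
            model.load_case = config.load_case_for(run.load_case)
            result = run_fracture(
                model, field, FailureCriterion(kind=run.criterion), config.schedule
            )
            rows.append(
                {
                    "run": run.key,
                    "load_case": run.load_case,
                    "criterion": run.criterion,
                    "lesion_type": run.lesion_type,
                    "positions": "+".join(run.positions),
                    "radius": run.radius_label,
                    "radius_mm": config.radii[run.radius_label],
                    "fracture_load_N": result.fracture_load,
                    "status": result.status,
                    "n_failed": result.n_failed,
                    "n_steps": len(result.curve),
                }
            )
        except Exception as exc:  # noqa: BLE001 — per-run isolation
            logger.warning("run %s failed: %s", run.key, exc)
            rows.append(
                {
                    "run": run.key,
                    "load_case": run.load_case,
                    "criterion": run.criterion,
                    "lesion_type": run.lesion_type,
                    "positions": "+".join(run.positions),
                    "radius": run.radius_label,
                    "radius_mm": config.radii.get(run.radius_label, np.nan),
                    "fracture_load_N": np.nan,
                    "status": f"error: {exc}",
                    "n_failed": 0,
                    "n_steps": 0,
                }
            )
    return pd.DataFrame(rows)


def fracture_load_table(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot results in the criterion x load-case x position layout."""
    single = results[~results["positions"].str.contains(r"\+")]
    return single.pivot_table(
        index=["lesion_type", "radius"],
        columns=["load_case", "criterion", "positions"],
        values="fracture_load_N",
    )
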