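"""Quasi-static force-incremental progressive-damage simulation.

The load ramps in increments ``f_{k+1} = f_k + gamma * df``.  At each
step the elastic problem is solved and the failure criterion evaluated;
failing elements are killed (E -> 1e-6 MPa) and the *same* load step is
re-solved until no further element fails.  The converged reaction and
mean top-plate displacement are appended to the load-displacement curve.
The fracture load ``f_u`` is the maximum converged reaction before the
structure loses its load path — detected as a solver non-convergence, an
exhausted inner kill loop, or an abrupt increase of the incremental
compliance relative to the curve history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .failure import FailureCriterion, evaluate_failure, kill_elements
from .fe import FEModel, NonConvergenceError, reaction_and_displacement, solve_elastic

logger = logging.getLogger(__name__)

STATUS_COMPLETED = "completed"
STATUS_NON_CONVERGED = "non_converged_at_step"
STATUS_STEP_BUDGET = "step_budget_exhausted"


@dataclass(frozen=True)
class LoadSchedule:
    """Incremental-loading controls.

    ``gamma_mode="fixed"`` keeps the load rate at 1 (each increment is
    ``delta_f``).  ``"adaptive"`` sets gamma to the ratio of total to
    newly fractured elements whenever the previous step fractured at
    least one element (capped at ``gamma_cap``), and 1 otherwise.
    """

    delta_f: float = 100.0  # N per increment
    gamma_mode: str = "fixed"
    gamma_cap: float = 10.0
    max_inner_iterations: int = 50
    max_steps: int = 200
    abrupt_factor: float = 10.0
    f_max: float | None = None  # optional stop load (status "completed")

    def __post_init__(self) -> None:
        if self.delta_f <= 0:
            raise ValueError("delta_f must be positive")
        if self.gamma_mode not in ("fixed", "adaptive"):
            raise ValueError("gamma_mode must be 'fixed' or 'adaptive'")
        if self.gamma_cap <= 0 or self.max_inner_iterations <= 0:
            raise ValueError("caps must be positive")
        if self.abrupt_factor <= 0:
            raise ValueError("abrupt_factor must be positive")


@dataclass
class FractureResult:
    """Outcome of a progressive-damage run."""

    curve: np.ndarray  # (n_steps, 2): reaction force N, top displacement mm
    fracture_load: float  # N
    pattern_elements: np.ndarray  # failed element ids, in failure order
    pattern_steps: np.ndarray  # load step index at which each element failed
    status: str
    final_step: int
    applied_loads: np.ndarray  # (n_steps,) total applied load per curve point

    @property
    def n_failed(self) -> int:
        return len(self.pattern_elements)


def detect_abrupt_displacement(curve, new_point, factor: float) -> bool:
    """Flag an abrupt displacement increase per unit incremental load.

    ``curve`` holds prior converged (force, displacement) pairs; origin
    (0, 0) is prepended for the incremental-compliance history.  Returns
    True when the new point's incremental compliance exceeds ``factor``
    times the median of prior incremental compliances.  With no prior
    point the check is vacuously False.
    """
    pts = np.asarray(curve, dtype=float).reshape(-1, 2)
    if len(pts) < 1:
        return False
    hist = np.vstack([[0.0, 0.0], pts])
    df = np.diff(hist[:, 0])
    du = np.diff(hist[:, 1])
    valid = df > 0
    if not np.any(valid):
        return False
    median_c = float(np.median(du[valid] / df[valid]))
    if median_c <= 0:
        return False
    dff = float(new_point[0]) - float(hist[-1, 0])
    duu = float(new_point[1]) - float(hist[-1, 1])
    if dff <= 0:
        return duu > 0  # displacement grew at non-increasing load
    return (duu / dff) > factor * median_c


def _gamma(schedule: LoadSchedule, n_total: int, n_failed_prev: int) -> float:
    if schedule.gamma_mode == "fixed" or n_failed_prev < 1:
        return 1.0
    return min(n_total / n_failed_prev, schedule.gamma_cap)


def run_fracture(
    model: FEModel,
    field,
    criterion: FailureCriterion,
    schedule: LoadSchedule | None = None,
) -> FractureResult:
    """Run the force-incremental damage loop and extract the fracture load.

    The model's load case supplies the nodal force distribution; ``field``
    is the starting material field (the model's field is replaced by
    progressively killed copies and left in its final state).
    """
    schedule = schedule or LoadSchedule()
    model.material = field
    curve: list[tuple[float, float]] = []
    applied: list[float] = []
    pat_el: list[int] = []
    pat_step: list[int] = []
    failed_seen = np.zeros(field.n_elements, dtype=bool)

    # the model must be well-posed before any damage
    try:
        solve_elastic(model, schedule.delta_f)
    except NonConvergenceError as exc:
        raise ValueError(f"initial model is not solvable: {exc}") from exc

    f_k = schedule.delta_f
    n_total = field.n_elements
    n_failed_prev = 0
    u_prev: np.ndarray | None = None
    status = STATUS_STEP_BUDGET
    step = 0
    for step in range(1, schedule.max_steps + 1):
        new_this_step = 0
        converged = True
        for inner in range(schedule.max_inner_iterations + 1):
            try:
                sol = solve_elastic(model, f_k, x0=u_prev)
                u_prev = sol.displacement.ravel()
            except NonConvergenceError:
                logger.info("step %d: solver non-convergence", step)
                status = STATUS_NON_CONVERGED
                converged = False
                break
            failing = evaluate_failure(sol, model.material, criterion)
            failing = failing[~failed_seen[failing]]
            if len(failing) == 0:
                break
            if inner == schedule.max_inner_iterations:
                logger.info("step %d: inner kill loop exhausted", step)
                status = STATUS_NON_CONVERGED
                converged = False
                break
            failed_seen[failing] = True
            pat_el.extend(int(e) for e in failing)
            pat_step.extend([step] * len(failing))
            new_this_step += len(failing)
            model.material = kill_elements(model.material, failing)
        if not converged:
            break

        f_r, u_top = reaction_and_displacement(model, sol)
        if detect_abrupt_displacement(curve, (f_r, u_top), schedule.abrupt_factor):
            logger.info("step %d: abrupt displacement increase", step)
            status = STATUS_NON_CONVERGED
            break
        curve.append((f_r, u_top))
        applied.append(f_k)
        logger.debug(
            "step %d: f=%.1f N f_r=%.1f N u=%.4g mm failed+%d",
            step,
            f_k,
            f_r,
            u_top,
            new_this_step,
        )
        if schedule.f_max is not None and f_k >= schedule.f_max:
            status = STATUS_COMPLETED
            break
        n_failed_prev = new_this_step
        f_next = f_k + _gamma(schedule, n_total, n_failed_prev) * schedule.delta_f
        if u_prev is not None and f_k > 0:
            u_prev = u_prev * (f_next / f_k)  # linear warm start
        f_k = f_next

    curve_arr = np.asarray(curve, dtype=float).reshape(-1, 2)
    f_u = float(curve_arr[-1, 0]) if len(curve_arr) else 0.0
    return FractureResult(
        curve=curve_arr,
        fracture_load=f_u,
        pattern_elements=np.asarray(pat_el, dtype=int),
        pattern_steps=np.asarray(pat_step, dtype=int),
        status=status,
        final_step=step,
        applied_loads=np.asarray(applied, dtype=float),
    )
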