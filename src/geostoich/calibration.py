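"""Per-feed calibration of the consumer model against observed intakes.

Each feeding trial gives one observation pair (protein intake, non-protein
intake) at an observed growth rate.  Calibration runs the model in reverse
mode at that growth rate and finds the feed parameters — among
``f_V`` (protein share of energetic costs), ``k_N`` (net protein synthesis
efficiency), ``phi`` (penalty on protein used for energy) and, where
digestibilities were not measured, the absorption efficiencies ``beta_V``
and ``beta_H`` — that minimise the summed squared *relative* intake errors

    L = ((IV_pred - IV_obs)/IV_obs)^2 + ((IH_pred - IH_obs)/IH_obs)^2.

Relative errors keep the two currencies (an order of magnitude apart)
comparable; growth enters as a hard constraint because prediction is always
at the observed growth rate.

The search is fully deterministic: a coarse parameter grid (vectorised),
a documented tie-break on flat objective sets, then cyclic per-coordinate
golden-section refinement.  With more free parameters than the two
observations the optimum is a manifold; the result records that
non-uniqueness instead of pretending the tie-broken point is identified.

Estimation is staged: ``phi`` is frozen at its fixed value (normally 0)
first, and freed only when the stage-1 fit leaves residual misfit and
``f_V > 0`` — the penalty is physiologically inert when no protein is
catabolised, so freeing it earlier would only manufacture spurious values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .conversions import TrialRecord
from .errors import (
    InvalidArgumentError,
    NoSolutionError,
    UndefinedStatisticError,
)
from .model import GSParameters, IntakePair, reverse_mode, reverse_intakes_grid

__all__ = [
    "CalibrationResult",
    "DEFAULT_BOUNDS",
    "calibrate_feed",
    "calibrate_experiment",
    "default_estimate_plan",
    "goodness_of_fit",
    "results_to_frame",
]

#: Canonical ordering of estimable parameters (also the tie-break ordering).
ESTIMABLE = ("f_V", "k_N", "phi", "beta_V", "beta_H")

#: Bounded search box; k_N floored at a physiologically broad 0.3, phi capped
#: at 1 (reported penalties stay below 0.7).  All overridable per call.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "f_V": (0.0, 1.0),
    "k_N": (0.3, 1.0),
    "phi": (0.0, 1.0),
    "beta_V": (0.3, 1.0),
    "beta_H": (0.3, 1.0),
}

#: Parameters preferred small on flat sets, per the documented tie-break
#: (smallest f_V, then smallest phi, then largest k_N; the absorption
#: efficiencies are preferred large for determinism in 4-5 parameter fits).
_TIEBREAK_SIGN = {"f_V": +1.0, "phi": +1.0, "k_N": -1.0, "beta_V": -1.0, "beta_H": -1.0}

_STAGE2_THRESHOLD = 1e-6
_FLAT_TOL = 1e-9


@dataclass
class CalibrationResult:
    """Outcome of calibrating one feed.

    ``fitted`` holds only the estimated fields; ``params`` is the complete
    parameter set actually used (fixed + measured digestibilities + fitted).
    ``nonunique`` flags a flat optimum manifold (more free parameters than
    the two intake observations can pin down); the reported point is then
    the documented tie-break choice, not a uniquely identified estimate.
    """

    feed_label: str
    experiment_id: str
    fitted: dict[str, float]
    params: GSParameters
    predicted: IntakePair
    observed: IntakePair
    objective_value: float
    residuals: tuple[float, float]  # relative errors on (I_V, I_H)
    converged: bool
    nonunique: bool
    trace: dict = field(default_factory=dict)


def _grid_step(n_free: int) -> float:
    if n_free <= 2:
        return 0.01
    if n_free == 3:
        return 0.02
    return 0.05


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return np.linspace(lo, hi, n + 1)


def _objective_factory(trial: TrialRecord, base: GSParameters, free: Sequence[str]):
    """Scalar objective over the free-parameter vector (inf when infeasible)."""
    iv_obs, ih_obs = trial.protein_intake_IV, trial.lipid_intake_IH

    def objective(values: Sequence[float]) -> float:
        try:
            p = base.replace(**dict(zip(free, (float(v) for v in values))))
            (iv, ih), _ = reverse_mode(trial.growth_rate_G, p)
        except (ValueError, ArithmeticError):
            return np.inf
        return ((iv - iv_obs) / iv_obs) ** 2 + ((ih - ih_obs) / ih_obs) ** 2

    return objective


def _grid_search(
    trial: TrialRecord,
    base: GSParameters,
    free: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
):
    """Vectorised coarse grid; returns (best point, best obj, flat-set size, meta)."""
    step = _grid_step(len(free))
    axes = [_axis(*bounds[name], step) for name in free]
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = {name: m.ravel() for name, m in zip(free, mesh)}

    grid_kw = {
        name: flat.get(name, np.asarray(getattr(base, name))) for name in ESTIMABLE
    }
    iv, ih = reverse_intakes_grid(
        trial.growth_rate_G,
        theta_V=base.theta_V,
        theta_Z=base.theta_Z,
        sigma_SDA=base.sigma_SDA,
        r_B=base.r_B,
        xi_basal=base.xi_basal,
        sda_base=base.sda_base,
        **grid_kw,
    )
    iv_obs, ih_obs = trial.protein_intake_IV, trial.lipid_intake_IH
    with np.errstate(invalid="ignore"):
        obj = ((iv - iv_obs) / iv_obs) ** 2 + ((ih - ih_obs) / ih_obs) ** 2
    obj = np.where(np.isnan(obj), np.inf, obj)

    n_feasible = int(np.isfinite(obj).sum())
    if n_feasible == 0:
        raise NoSolutionError(
            f"feed {trial.feed_label}: every grid point is infeasible "
            "(reverse mode has no nonnegative intake solution anywhere in the box)"
        )
    best = float(obj.min())
    flat_idx = np.flatnonzero(obj <= best + _FLAT_TOL)
    # Deterministic tie-break: lexsort minimises f_V, then phi, then -k_N, ...
    priority = [n for n in ("f_V", "phi", "k_N", "beta_V", "beta_H") if n in free]
    keys = [_TIEBREAK_SIGN[name] * flat[name][flat_idx] for name in reversed(priority)]
    pick = flat_idx[np.lexsort(keys)[0]] if keys else flat_idx[0]
    point = [float(flat[name][pick]) for name in free]
    meta = {
        "grid_step": step,
        "n_grid": int(obj.size),
        "n_feasible": n_feasible,
        "grid_best_objective": best,
        "flat_set_size": int(flat_idx.size),
    }
    return point, float(obj[pick]), meta


def _coordinate_refine(
    objective,
    point: list[float],
    free: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    max_cycles: int = 60,
):
    """Cyclic golden-section refinement; only accepts strict improvements.

    On a flat valley the scalar minimiser would happily wander to an
    arbitrary interior point, destroying the tie-break choice, so a move is
    kept only when it genuinely lowers the objective.
    """
    current = list(point)
    f_current = objective(current)
    cycles = 0
    for cycles in range(1, max_cycles + 1):
        f_start = f_current
        for i, name in enumerate(free):
            lo, hi = bounds[name]

            def along(v: float, i: int = i) -> float:
                trial_pt = list(current)
                trial_pt[i] = v
                return objective(trial_pt)

            res = minimize_scalar(
                along, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10, "maxiter": 200},
            )
            if res.fun < f_current - 1e-16:
                current[i] = float(np.clip(res.x, lo, hi))
                f_current = float(res.fun)
        if f_start - f_current <= 1e-15:
            break
    return current, f_current, cycles


def _lex_polish(
    objective,
    point: list[float],
    free: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    tol: float,
):
    """Resolve a flat optimum manifold by the documented tie-break.

    When the fit is numerically exact and under-determined (more free
    parameters than the two observations), push each parameter in turn to
    its preferred extreme — smallest ``f_V``, smallest ``phi``, largest
    ``k_N``, largest absorption efficiencies — as far as the remaining free
    parameters can re-absorb the change while keeping the objective within
    ``tol`` of exact.  Bisection per coordinate; fully deterministic.
    """
    current = list(point)
    order = [n for n in ("f_V", "phi", "k_N", "beta_V", "beta_H") if n in free]
    done: set[str] = set()

    def inner_feasible(idx: int, value: float) -> tuple[bool, list[float]]:
        trial_pt = list(current)
        trial_pt[idx] = value
        rest = [n for n in free if n not in done and n != free[idx]]
        if rest:
            sub_idx = [free.index(n) for n in rest]

            def sub_obj(vals):
                pt = list(trial_pt)
                for j, v in zip(sub_idx, vals):
                    pt[j] = v
                return objective(pt)

            vals, f, _ = _coordinate_refine(
                sub_obj, [trial_pt[j] for j in sub_idx], rest, bounds, max_cycles=20
            )
            for j, v in zip(sub_idx, vals):
                trial_pt[j] = v
        else:
            f = objective(trial_pt)
        return f <= tol, trial_pt

    for name in order:
        idx = free.index(name)
        lo, hi = bounds[name]
        target = lo if _TIEBREAK_SIGN[name] > 0 else hi
        ok, pt = inner_feasible(idx, target)
        if ok:
            current = pt
        else:
            good, bad = current[idx], target
            best_pt = current
            for _ in range(30):
                mid = 0.5 * (good + bad)
                ok, pt = inner_feasible(idx, mid)
                if ok:
                    good, best_pt = mid, pt
                else:
                    bad = mid
            current = best_pt
            current[idx] = good
        done.add(name)
    return current, objective(current)


def _run_stage(trial, base, free, bounds):
    objective = _objective_factory(trial, base, free)
    point, f_grid, meta = _grid_search(trial, base, free, bounds)
    point, f_ref, cycles = _coordinate_refine(objective, point, free, bounds)
    if len(free) > 2 and f_ref < 1e-9:
        tol = max(10.0 * f_ref, 1e-9)
        point, f_ref = _lex_polish(objective, point, free, bounds, tol)
        meta["tie_break_polish"] = True
    meta.update(cycles=cycles, refined_objective=f_ref)
    return point, f_ref, meta


def calibrate_feed(
    trial: TrialRecord,
    fixed: GSParameters | None = None,
    estimate: Iterable[str] = ("f_V", "k_N", "phi"),
    bounds: Mapping[str, tuple[float, float]] | None = None,
    stage2_threshold: float = _STAGE2_THRESHOLD,
) -> CalibrationResult:
    """Calibrate one feed's parameters against its observed intake pair.

    ``estimate`` names the parameters to fit (subset of ``ESTIMABLE``);
    measured digestibilities on the trial always take precedence: they are
    installed as ``beta_V``/``beta_H`` and silently dropped from the
    estimate set.  Everything else comes from ``fixed``.
    """
    fixed = fixed if fixed is not None else GSParameters()
    estimate = set(estimate)
    if not estimate <= set(ESTIMABLE):
        raise InvalidArgumentError(
            f"estimate must be a subset of {ESTIMABLE}, got {sorted(estimate)}"
        )
    if trial.protein_intake_IV <= 0 or trial.lipid_intake_IH <= 0:
        raise InvalidArgumentError(
            f"feed {trial.feed_label}: calibration needs strictly positive "
            "observed intakes"
        )
    if trial.growth_rate_G < 0:
        raise InvalidArgumentError(
            f"feed {trial.feed_label}: observed growth must be >= 0"
        )
    search_bounds = dict(DEFAULT_BOUNDS)
    if bounds:
        search_bounds.update(bounds)

    base = fixed
    if trial.protein_digestibility_ADN is not None:
        base = base.replace(beta_V=trial.protein_digestibility_ADN)
        estimate.discard("beta_V")
    if trial.lipid_digestibility is not None:
        base = base.replace(beta_H=trial.lipid_digestibility)
        estimate.discard("beta_H")

    free1 = [n for n in ESTIMABLE if n in estimate and n != "phi"]
    stage1_base = base.replace(phi=0.0) if "phi" in estimate else base

    if free1:
        point1, f1, meta1 = _run_stage(trial, stage1_base, free1, search_bounds)
    else:  # nothing but phi requested: stage 1 is the fixed-parameter evaluation
        point1, f1 = [], _objective_factory(trial, stage1_base, [])([])
        meta1 = {"grid_step": None, "n_grid": 0, "n_feasible": int(np.isfinite(f1)),
                 "grid_best_objective": f1, "flat_set_size": 1, "cycles": 0,
                 "refined_objective": f1}

    fitted = dict(zip(free1, point1))
    final_base, final_free = stage1_base, free1
    final_point, final_obj = point1, f1
    stage = 1

    f_v_now = fitted.get("f_V", base.f_V)
    if "phi" in estimate and f_v_now > 0 and (f1 > stage2_threshold or not free1):
        free2 = [n for n in ESTIMABLE if n in estimate]
        point2, f2, meta2 = _run_stage(trial, base, free2, search_bounds)
        if f2 < f1:
            final_base, final_free = base, free2
            final_point, final_obj = point2, f2
            fitted = dict(zip(free2, point2))
            stage = 2
            meta1 = {"stage1": meta1, **meta2}

    if "phi" in estimate and "phi" not in fitted:
        fitted["phi"] = 0.0  # stage 2 never ran: the penalty is inert or unneeded

    params = final_base.replace(**{k: v for k, v in fitted.items()})
    (iv, ih), _ = reverse_mode(trial.growth_rate_G, params)
    residuals = (
        (iv - trial.protein_intake_IV) / trial.protein_intake_IV,
        (ih - trial.lipid_intake_IH) / trial.lipid_intake_IH,
    )
    n_free_final = len(final_free)
    nonunique = bool(meta1.get("flat_set_size", 1) > 1) or (
        n_free_final > 2 and final_obj <= stage2_threshold
    )
    meta1["stage"] = stage
    return CalibrationResult(
        feed_label=trial.feed_label,
        experiment_id=trial.experiment_id,
        fitted=fitted,
        params=params,
        predicted=IntakePair(iv, ih),
        observed=IntakePair(trial.protein_intake_IV, trial.lipid_intake_IH),
        objective_value=final_obj,
        residuals=residuals,
        converged=bool(np.isfinite(final_obj)),
        nonunique=nonunique,
        trace=meta1,
    )


def default_estimate_plan(trials: Sequence[TrialRecord]) -> set[str]:
    """Which parameters an experiment's data can support estimating.

    Feed-level energetics (``f_V``, ``k_N``, ``phi``) are always estimated;
    the absorption efficiencies join the estimate set only when *no* feed in
    the experiment has any measured digestibility (fresh-feed style trials).
    When only the protein digestibility is missing the framework default
    ``beta_V`` is used rather than estimated, mirroring how such trials are
    normally handled.
    """
    any_measured = any(
        t.protein_digestibility_ADN is not None or t.lipid_digestibility is not None
        for t in trials
    )
    plan = {"f_V", "k_N", "phi"}
    if not any_measured:
        plan |= {"beta_V", "beta_H"}
    return plan


def calibrate_experiment(
    trials: Sequence[TrialRecord],
    fixed: GSParameters | None = None,
    estimate: Iterable[str] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> list[CalibrationResult]:
    """Calibrate every feed of one experiment (shared experiment id)."""
    trials = list(trials)
    if not trials:
        warnings.warn("calibrate_experiment called with no trials", stacklevel=2)
        return []
    ids = {t.experiment_id for t in trials}
    if len(ids) != 1:
        raise InvalidArgumentError(f"trials mix experiment ids: {sorted(ids)}")
    plan = set(estimate) if estimate is not None else default_estimate_plan(trials)
    return [
        calibrate_feed(t, fixed=fixed, estimate=plan, bounds=bounds) for t in trials
    ]


def results_to_frame(results: Sequence[CalibrationResult]) -> pd.DataFrame:
    """Flatten calibration results into the standard results table."""
    rows = []
    for r in results:
        rows.append(
            {
                "experiment": r.experiment_id,
                "feed": r.feed_label,
                "f_V": r.params.f_V,
                "k_N": r.params.k_N,
                "phi": r.params.phi,
                "beta_V": r.params.beta_V,
                "beta_H": r.params.beta_H,
                "pred_IV": r.predicted.I_V,
                "pred_IH": r.predicted.I_H,
                "obs_IV": r.observed.I_V,
                "obs_IH": r.observed.I_H,
                "objective": r.objective_value,
                "converged": r.converged,
                "nonunique": r.nonunique,
            }
        )
    return pd.DataFrame(rows)


def goodness_of_fit(
    results: Sequence[CalibrationResult],
) -> tuple[float, float, pd.DataFrame]:
    """Pooled fit quality: squared Pearson correlations and residual table.

    Returns ``(r2_IV, r2_IH, table)`` where the correlations pool predicted
    against observed intakes across all supplied feeds.
    """
    if len(results) < 3:
        raise InvalidArgumentError("goodness_of_fit needs at least 3 results")
    pred_iv = np.array([r.predicted.I_V for r in results])
    pred_ih = np.array([r.predicted.I_H for r in results])
    obs_iv = np.array([r.observed.I_V for r in results])
    obs_ih = np.array([r.observed.I_H for r in results])
    for obs, name in ((obs_iv, "protein"), (obs_ih, "lipid")):
        if np.var(obs) == 0:
            raise UndefinedStatisticError(
                f"observed {name} intakes have zero variance; r^2 is undefined"
            )
    r2_iv = float(np.corrcoef(pred_iv, obs_iv)[0, 1] ** 2)
    r2_ih = float(np.corrcoef(pred_ih, obs_ih)[0, 1] ** 2)
    table = pd.DataFrame(
        {
            "experiment": [r.experiment_id for r in results],
            "feed": [r.feed_label for r in results],
            "obs_IV": obs_iv,
            "pred_IV": pred_iv,
            "rel_err_IV": (pred_iv - obs_iv) / obs_iv,
            "obs_IH": obs_ih,
            "pred_IH": pred_ih,
            "rel_err_IH": (pred_ih - obs_ih) / obs_ih,
        }
    )
    return r2_iv, r2_ih, table
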