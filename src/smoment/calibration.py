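"""Fitting the protein pool and turnover numbers against measured fluxes.

Enzyme-constrained models need calibration before their predictions mean
anything: the effective pool P_eff absorbs unknown average enzyme
saturation, and database kcat values carry order-of-magnitude uncertainty.
Both are fitted by minimizing the symmetric relative error between
measured and FBA-predicted fluxes,

    sum_scenarios sum_fluxes  w * max(v_meas / v_pred, v_pred / v_meas),

which equals the total weight exactly when every prediction matches its
measurement.  The pool is fitted by a deterministic bounded scalar search
(coarse grid, then local refinement); the kcat values of a *preselected*
sensitive subset of reactions are then fitted by coordinate descent, each
confined to a multiplicative band around its database value.  Preselection
keeps only reactions whose kcat perturbation moves the predicted growth of
exactly one scenario, so fitting one scenario cannot silently degrade the
others.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import cobra
from scipy.optimize import minimize_scalar

from .core import SMomentModel
from .model_io import find_biomass

logger = logging.getLogger("smoment")

#: Large finite penalty per unit weight for non-positive / failed predictions.
PENALTY = 1.0e6


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """One growth condition: environment overrides plus measured fluxes.

    ``environment`` maps reaction ids to ``(lb, ub)`` bound overrides
    (mmol/gDW/h); ``measurements`` maps reaction ids to measured fluxes
    (growth in 1/h when the reaction is the biomass objective); weights
    default to 1.
    """

    id: str
    environment: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    measurements: Dict[str, float] = field(default_factory=dict)
    weights: Dict[str, float] = field(default_factory=dict)

    def weight(self, rxn_id: str) -> float:
        return self.weights.get(rxn_id, 1.0)


@dataclass
class FluxMeasurementSet:
    scenarios: List[Scenario] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sc in self.scenarios:
            for rid, val in sc.measurements.items():
                if val <= 0:
                    raise ValueError(
                        f"scenario {sc.id}: measured flux for {rid} is "
                        f"{val}; the relative-error objective is undefined "
                        "at 0 — drop the measurement or measure the reverse "
                        "direction as its own reaction"
                    )
            if any(w < 0 for w in sc.weights.values()):
                raise ValueError(f"scenario {sc.id}: weights must be >= 0")

    @property
    def total_weight(self) -> float:
        return sum(sc.weight(r) for sc in self.scenarios for r in sc.measurements)

    @classmethod
    def from_tsv(cls, path: str) -> "FluxMeasurementSet":
        """Columns: scenario, reaction_id, value, weight.  Environment
        overrides use rows with reaction_id prefixed ``bound:`` and value
        ``lb:ub``."""
        by_id: Dict[str, Scenario] = {}
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                sc = by_id.setdefault(row["scenario"], Scenario(row["scenario"]))
                rid = row["reaction_id"]
                if rid.startswith("bound:"):
                    lb, ub = (float(x) for x in row["value"].split(":"))
                    sc.environment[rid[len("bound:"):]] = (lb, ub)
                else:
                    sc.measurements[rid] = float(row["value"])
                    if row.get("weight"):
                        sc.weights[rid] = float(row["weight"])
        return cls(list(by_id.values()))


# ---------------------------------------------------------------------------
# FBA plumbing
# ---------------------------------------------------------------------------

@dataclass
class FBAResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: Optional[float]
    fluxes: Optional[Mapping[str, float]] = None


def fba(
    model: cobra.Model,
    objective: Optional[str] = None,
    direction: str = "max",
) -> FBAResult:
    """One flux-balance LP.  Infeasible or unbounded problems are reported
    through the status field, not raised."""
    with model:
        if objective is not None:
            model.objective = objective
        model.objective_direction = direction
        sol = model.optimize()
        if sol.status == "optimal":
            return FBAResult("optimal", sol.objective_value, dict(sol.fluxes))
        if sol.status == "unbounded":
            logger.warning("FBA unbounded (%s of %s)", direction, objective)
            return FBAResult("unbounded", None)
        return FBAResult(sol.status, None)


def _resolve(sm: SMomentModel, rxn_id: str) -> str:
    """Measurement/environment ids may predate splitting; map to the
    forward column when the raw id is gone."""
    if rxn_id in sm.model.reactions:
        return rxn_id
    if rxn_id in sm.direction_map.pairs:
        return sm.direction_map.pairs[rxn_id][0]
    raise KeyError(f"unknown reaction {rxn_id!r}")


def predict_scenario(
    sm: SMomentModel,
    scenario: Scenario,
    objective: Optional[str] = None,
    growth_only: bool = False,
) -> Dict[str, Optional[float]]:
    """Predicted value for every measured flux of one scenario.

    Growth is the FBA optimum; other measured fluxes are read from the
    parsimonious (minimal-total-flux) optimal solution so they are unique.
    Returns None entries when the scenario is infeasible.
    """
    model = sm.model
    obj_id = objective or (find_biomass(model).id if find_biomass(model) else None)
    if obj_id is None:
        raise ValueError("no objective reaction identified")
    needed = list(scenario.measurements)
    if growth_only:
        needed = [r for r in needed if _resolve(sm, r) == _resolve(sm, obj_id)]
    with model:
        for rid, (lb, ub) in scenario.environment.items():
            model.reactions.get_by_id(_resolve(sm, rid)).bounds = (lb, ub)
        model.objective = _resolve(sm, obj_id)
        only_growth = all(_resolve(sm, r) == _resolve(sm, obj_id) for r in needed)
        if only_growth:
            mu = model.slim_optimize(error_value=None)
            return {r: mu for r in needed}
        try:
            sol = cobra.flux_analysis.pfba(model)
        except Exception:
            return {r: None for r in needed}
        return {r: float(sol.fluxes[_resolve(sm, r)]) for r in needed}


def relative_error_objective(
    predictions: Mapping[str, Optional[float]],
    measurements: Mapping[str, float],
    weights: Optional[Mapping[str, float]] = None,
    penalty: float = PENALTY,
) -> float:
    """Weighted symmetric relative error sum(w * max(m/p, p/m)).

    Equals the total weight iff every prediction matches its measurement.
    Non-positive or missing predictions contribute ``w * penalty`` (large
    finite, keeps scalar optimizers stable) and are logged.
    """
    total = 0.0
    for rid, m in measurements.items():
        w = (weights or {}).get(rid, 1.0)
        p = predictions.get(rid)
        if p is None or p <= 0 or math.isnan(p):
            logger.debug("prediction for %s is %r; penalized", rid, p)
            total += w * penalty
        else:
            total += w * max(m / p, p / m)
    return total


def evaluate_objective(
    sm: SMomentModel,
    measurements: FluxMeasurementSet,
    objective: Optional[str] = None,
    growth_only: bool = False,
) -> float:
    """Eq.-style objective over all scenarios at the model's current
    parameters."""
    total = 0.0
    for sc in measurements.scenarios:
        preds = predict_scenario(sm, sc, objective, growth_only=growth_only)
        meas = {r: v for r, v in sc.measurements.items() if r in preds}
        total += relative_error_objective(preds, meas, sc.weights)
    return total


# ---------------------------------------------------------------------------
# Pool fitting
# ---------------------------------------------------------------------------

def _grid_refine_minimize(fn, lo: float, hi: float, n_grid: int, xatol: float):
    """Deterministic coarse-grid scan followed by bounded local refinement.

    Returns (x_best, f_best).  Robust to the kinks of the ratio objective
    and independent of optimizer randomness.
    """
    xs = [lo + (hi - lo) * i / (n_grid - 1) for i in range(n_grid)]
    fs = [fn(x) for x in xs]
    i = min(range(n_grid), key=lambda j: (fs[j], j))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, n_grid - 1)]
    best_x, best_f = xs[i], fs[i]
    if b > a:
        res = minimize_scalar(fn, bounds=(a, b), method="bounded",
                              options={"xatol": xatol})
        if res.fun < best_f:
            best_x, best_f = float(res.x), float(res.fun)
    return best_x, best_f


def fit_protein_pool(
    sm: SMomentModel,
    measurements: FluxMeasurementSet,
    interval: Tuple[float, float] = (1e-6, 1.0),
    tol: float = 1e-4,
    objective: Optional[str] = None,
    n_grid: int = 25,
) -> float:
    """Fit the effective protein pool P_eff (g/gDW) to measured growth
    rates; the pool bound of ``sm`` is set to the result.

    Only growth-rate terms of the objective are used.  The search is a
    deterministic grid scan over ``interval`` refined by a bounded scalar
    minimization to tolerance ``tol``.  When no interior point improves on
    the interval endpoints, the better endpoint is returned with a warning.
    """
    has_growth = any(sc.measurements for sc in measurements.scenarios)
    if not has_growth:
        raise ValueError("measurements contain no growth-rate scenario")

    def fn(p: float) -> float:
        sm.set_pool_bound(p)
        return evaluate_objective(sm, measurements, objective, growth_only=True)

    lo, hi = interval
    best_p, best_f = _grid_refine_minimize(fn, lo, hi, n_grid, tol)
    f_lo, f_hi = fn(lo), fn(hi)
    if min(f_lo, f_hi) <= best_f:
        best_p, best_f = (lo, f_lo) if f_lo <= f_hi else (hi, f_hi)
        logger.warning(
            "pool fit did not improve inside [%g, %g]; returning boundary "
            "value %g — the optimum may lie outside the search interval",
            lo, hi, best_p,
        )
    sm.set_pool_bound(best_p)
    return best_p


# ---------------------------------------------------------------------------
# kcat preselection and fitting
# ---------------------------------------------------------------------------

def preselect_kcats(
    sm: SMomentModel,
    measurements: FluxMeasurementSet,
    delta: float = 2.0,
    tol: float = 1e-6,
    objective: Optional[str] = None,
) -> List[str]:
    """Reactions whose kcat is fit-safe: perturbing it (x delta and
    / delta) changes the predicted growth of exactly one scenario by more
    than ``tol`` and leaves every other scenario untouched.

    The returned list is deterministic, in model order.
    """
    baseline: Dict[str, Optional[float]] = {}
    for sc in measurements.scenarios:
        preds = predict_scenario(sm, sc, objective, growth_only=True)
        baseline[sc.id] = next(iter(preds.values()), None)
    selected: List[str] = []
    for rid in sm.costed_reactions():
        changed: set = set()
        for factor in (delta, 1.0 / delta):
            if factor == 1.0:
                continue
            originals = {
                d: sm.costs.kcat[sm.direction_map.column_of(rid, d)]
                for d in sm.direction_map.directions_of(rid)
                if sm.costs.cost.get(sm.direction_map.column_of(rid, d), 0.0) > 0
            }
            for d, k in originals.items():
                sm.set_kcat(rid, d, k * factor)
            for sc in measurements.scenarios:
                preds = predict_scenario(sm, sc, objective, growth_only=True)
                mu = next(iter(preds.values()), None)
                base = baseline[sc.id]
                if (mu is None) != (base is None) or (
                    mu is not None and base is not None and abs(mu - base) > tol
                ):
                    changed.add(sc.id)
            for d, k in originals.items():
                sm.set_kcat(rid, d, k)  # restore exactly
        if len(changed) == 1:
            selected.append(rid)
    return selected


@dataclass
class CalibrationResult:
    p_eff: float
    kcat_before: Dict[Tuple[str, str], float]
    kcat_after: Dict[Tuple[str, str], float]
    objective_trace: List[float]
    preselected: List[str]

    def __post_init__(self) -> None:
        if self.objective_trace and (
            self.objective_trace[-1] > self.objective_trace[0] + 1e-9
        ):
            raise ValueError("calibration must not increase the objective")


def calibrate_kcats(
    sm: SMomentModel,
    reactions: Sequence[str],
    measurements: FluxMeasurementSet,
    bounds_factor: float = 100.0,
    sweep_tol: float = 1e-6,
    max_sweeps: int = 10,
    objective: Optional[str] = None,
    n_grid: int = 13,
) -> CalibrationResult:
    """Coordinate-descent fit of the preselected kcat values.

    Each reaction's kcat (all of its directions, scaled jointly) is
    confined to ``[k/bounds_factor, k*bounds_factor]`` around its starting
    value and minimized one at a time, sweeping in model order until a full
    sweep improves the objective by less than ``sweep_tol``.  Only
    improving moves are accepted, so the final objective never exceeds the
    initial one.  An empty reaction list returns the identity result.
    """
    kcat_before: Dict[Tuple[str, str], float] = {}
    for rid in reactions:
        for d in sm.direction_map.directions_of(rid):
            col = sm.direction_map.column_of(rid, d)
            if sm.costs.cost.get(col, 0.0) > 0:
                kcat_before[(rid, d)] = sm.costs.kcat[col]
    current = evaluate_objective(sm, measurements, objective, growth_only=True)
    trace = [current]
    log_bf = math.log(bounds_factor)
    for _sweep in range(max_sweeps if kcat_before else 0):
        sweep_start = current
        for rid in reactions:
            dirs = [d for (r, d) in kcat_before if r == rid]
            if not dirs:
                continue
            start = {d: sm.costs.kcat[sm.direction_map.column_of(rid, d)]
                     for d in dirs}

            def fn(log_factor: float) -> float:
                f = math.exp(log_factor)
                for d in dirs:
                    sm.set_kcat(rid, d, start[d] * f)
                val = evaluate_objective(sm, measurements, objective,
                                         growth_only=True)
                for d in dirs:
                    sm.set_kcat(rid, d, start[d])
                return val

            best_lf, best_f = _grid_refine_minimize(
                fn, -log_bf, log_bf, n_grid, 1e-3
            )
            if best_f < current - 1e-12:
                f = math.exp(best_lf)
                for d in dirs:
                    sm.set_kcat(rid, d, start[d] * f)
                current = best_f
        trace.append(current)
        if sweep_start - current < sweep_tol:
            break
    kcat_after = {
        (rid, d): sm.costs.kcat[sm.direction_map.column_of(rid, d)]
        for (rid, d) in kcat_before
    }
    return CalibrationResult(
        p_eff=sm.pool.P_eff,
        kcat_before=kcat_before,
        kcat_after=kcat_after,
        objective_trace=trace,
        preselected=list(reactions),
    )
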