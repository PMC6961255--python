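"""Comparative analyses: flux variability, substrate-uptake scans, and
range-shrinkage summaries between a plain and an enzyme-constrained model.

The protein-pool row only ever *adds* a constraint, so every flux range of
the augmented model is contained in the corresponding range of the
unconstrained model; the summary here quantifies that shrinkage
(including the count of "practically unbounded" fluxes that hit the
artificial bound).  The uptake scan reproduces the classic
overflow-metabolism readout: growth is maximized at each fixed substrate
uptake rate between the minimal feasible and maximal attainable uptake,
and the exchange fluxes of named products are reported from the
parsimonious optimum so they are unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import cobra
import numpy as np
import pandas as pd
from cobra.flux_analysis import flux_variability_analysis as _cobra_fva

from .model_io import ARTIFICIAL_BOUND, find_biomass

logger = logging.getLogger("smoment")

#: Numerical slack for blocked/containment/unbounded classification.
FLUX_EPS = 1e-6


# ---------------------------------------------------------------------------
# Flux variability
# ---------------------------------------------------------------------------

@dataclass
class FVAResult:
    """Per-reaction flux ranges.  ``table`` columns: minimum, maximum,
    blocked (min = max = 0), unbounded (|bound| reaches the artificial
    maximum)."""

    status: str
    table: Optional[pd.DataFrame] = None

    def widths(self, exclude_blocked: bool = True) -> pd.Series:
        t = self.table
        if exclude_blocked:
            t = t[~t["blocked"]]
        return t["maximum"] - t["minimum"]


def flux_variability(
    model: cobra.Model,
    environment: Optional[Mapping[str, Tuple[float, float]]] = None,
    fraction_of_optimum: Optional[float] = None,
    reactions: Optional[Sequence[str]] = None,
    artificial_bound: float = ARTIFICIAL_BOUND,
) -> FVAResult:
    """Per-reaction min/max flux via paired LPs.

    ``fraction_of_optimum=None`` leaves the objective unconstrained;
    a value (e.g. 1.0) additionally requires that fraction of the optimal
    objective.  An infeasible environment yields status ``infeasible``
    with no partial table.
    """
    with model:
        for rid, (lb, ub) in (environment or {}).items():
            model.reactions.get_by_id(rid).bounds = (lb, ub)
        if not np.isfinite(model.slim_optimize(error_value=np.nan)):
            return FVAResult("infeasible")
        frame = _cobra_fva(
            model,
            reaction_list=list(reactions) if reactions else None,
            fraction_of_optimum=fraction_of_optimum or 0.0,
            processes=1,
        )
    frame = frame.copy()
    frame["blocked"] = (frame["minimum"].abs() < FLUX_EPS) & (
        frame["maximum"].abs() < FLUX_EPS
    )
    frame["unbounded"] = (frame["maximum"] >= artificial_bound - FLUX_EPS) | (
        frame["minimum"] <= -artificial_bound + FLUX_EPS
    )
    return FVAResult("optimal", frame)


def closed_exchange_environment(
    model: cobra.Model, keep: Sequence[str] = ()
) -> Dict[str, Tuple[float, float]]:
    """Environment that disables uptake through every exchange reaction not
    listed in ``keep`` (secretion stays open).  The usual setup for
    FVA comparisons where only the substrate and standard fermentation
    products are allowed to cross the boundary."""
    keep_set = set(keep)
    env: Dict[str, Tuple[float, float]] = {}
    for rxn in model.reactions:
        if len(rxn.metabolites) == 1 and rxn.id not in keep_set:
            env[rxn.id] = (max(rxn.lower_bound, 0.0), rxn.upper_bound)
    return env


# ---------------------------------------------------------------------------
# Substrate-uptake scan
# ---------------------------------------------------------------------------

@dataclass
class UptakeScanResult:
    """Growth and product exchange fluxes over a grid of uptake rates.

    ``table`` columns: uptake (positive magnitude, mmol/gDW/h), growth
    (1/h), feasible flag, and one column per requested product exchange
    (positive = excretion)."""

    substrate: str
    min_uptake: float
    max_uptake: float
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def uptake_scan(
    model: cobra.Model,
    exchange_id: str,
    products: Sequence[str] = (),
    n_points: int = 15,
    grid: Optional[Sequence[float]] = None,
    objective: Optional[str] = None,
) -> UptakeScanResult:
    """Scan substrate uptake from the minimal feasible to the maximal
    attainable rate, maximizing growth at each fixed uptake.

    Uptake follows the exchange convention (negative flux = uptake); the
    scan reports the positive magnitude.  The endpoints are themselves LP
    results: min uptake = the smallest uptake the constraints (e.g.
    maintenance demand) allow, max uptake = the FBA maximum of the uptake
    flux.  Exchange fluxes at each point come from a secondary
    total-flux-minimizing LP at fixed optimal growth, making the reported
    optimum unique.  Grid points below the minimal feasible uptake are
    flagged infeasible.
    """
    ex = model.reactions.get_by_id(exchange_id)
    obj_id = objective or (find_biomass(model).id if find_biomass(model) else None)
    if obj_id is None:
        raise ValueError("no growth objective identified")
    with model:
        model.objective = exchange_id
        model.objective_direction = "max"
        v_max = model.slim_optimize(error_value=np.nan)
        model.objective_direction = "min"
        v_min = model.slim_optimize(error_value=np.nan)
    if not (np.isfinite(v_min) and np.isfinite(v_max)):
        raise ValueError(f"model infeasible while bracketing {exchange_id}")
    min_uptake = max(0.0, -v_max)   # uptake needed even when minimized
    max_uptake = max(0.0, -v_min)   # largest attainable uptake
    if grid is None:
        grid = np.linspace(min_uptake, max_uptake, n_points)
    rows: List[Dict[str, float]] = []
    for u in grid:
        row: Dict[str, float] = {"uptake": float(u)}
        with model:
            ex.bounds = (-u, -u)
            model.objective = obj_id
            mu = model.slim_optimize(error_value=np.nan)
            if not np.isfinite(mu):
                row.update({"growth": np.nan, "feasible": False})
                row.update({p: np.nan for p in products})
                rows.append(row)
                continue
            row.update({"growth": float(mu), "feasible": True})
            if products:
                sol = cobra.flux_analysis.pfba(model)
                row.update({p: float(sol.fluxes[p]) for p in products})
        rows.append(row)
    table = pd.DataFrame(rows)
    return UptakeScanResult(exchange_id, min_uptake, max_uptake, table)


# ---------------------------------------------------------------------------
# Range shrinkage
# ---------------------------------------------------------------------------

@dataclass
class ShrinkageSummary:
    """Comparison of flux-range widths between two FVA results (a = the
    reference/unconstrained model, b = the constrained one)."""

    table: pd.DataFrame            # width_a, width_b per shared reaction
    n_unbounded_a: int
    n_unbounded_b: int
    all_contained: bool            # every width_b <= width_a (within eps)
    n_strictly_shrunk: int

    def cumulative_distribution(self) -> pd.DataFrame:
        """ECDF-style table of sorted widths for both models."""
        wa = np.sort(self.table["width_a"].to_numpy())
        wb = np.sort(self.table["width_b"].to_numpy())
        frac = np.arange(1, len(wa) + 1) / max(len(wa), 1)
        return pd.DataFrame({"fraction": frac, "width_a": wa, "width_b": wb})


def range_shrinkage_summary(
    fva_a: FVAResult,
    fva_b: FVAResult,
    artificial_bound: float = ARTIFICIAL_BOUND,
    exclude_blocked: bool = True,
    eps: float = FLUX_EPS,
) -> ShrinkageSummary:
    """Per-reaction width comparison over the shared reaction set.

    Reactions blocked in *both* models can be excluded (the usual
    convention for cumulative-distribution plots).  Mismatched reaction
    sets are restricted to their intersection with a logged warning.
    """
    ta, tb = fva_a.table, fva_b.table
    shared = ta.index.intersection(tb.index)
    if len(shared) < max(len(ta), len(tb)):
        logger.warning(
            "FVA results cover different reaction sets; restricting to the "
            "%d shared reactions", len(shared),
        )
    if len(shared) == 0:
        logger.warning("empty reaction intersection; empty summary")
        return ShrinkageSummary(
            pd.DataFrame(columns=["width_a", "width_b"]), 0, 0, True, 0
        )
    ta, tb = ta.loc[shared], tb.loc[shared]
    if exclude_blocked:
        keep = ~(ta["blocked"] & tb["blocked"])
        ta, tb = ta[keep], tb[keep]
    widths = pd.DataFrame({
        "width_a": ta["maximum"] - ta["minimum"],
        "width_b": tb["maximum"] - tb["minimum"],
    })
    n_unb_a = int((ta["unbounded"]).sum())
    n_unb_b = int((tb["unbounded"]).sum())
    contained = bool((widths["width_b"] <= widths["width_a"] + eps).all())
    n_shrunk = int((widths["width_b"] < widths["width_a"] - eps).sum())
    return ShrinkageSummary(widths, n_unb_a, n_unb_b, contained, n_shrunk)
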