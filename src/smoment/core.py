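"""Core sMOMENT transformation: embed protein-allocation constraints
directly into the stoichiometric matrix of a constraint-based model.

The method expresses the MOMENT enzyme-mass constraint

    sum_i  v_i * MW_i / kcat_i  <=  P

as one extra row of the stoichiometric matrix (an enzyme-pool
pseudo-metabolite, consumed by every catalyzed reaction with coefficient
-MW_i/kcat_i) plus one extra column (a pool-delivery pseudo-reaction with
upper bound P).  For a reaction catalyzed by several enzymes the *minimal*
enzyme cost min_E MW_E/kcat_E is used; this does not change the feasible
flux space because the cheapest enzyme is the one a pool-limited optimum
would select anyway.

Pipeline order: split reversible reactions -> derive enzymes from GPR rules
-> assign kcat values (see :mod:`smoment.kcat`) -> compute the cost table
-> augment the matrix with the pool row.  Measured enzyme concentrations
can then be layered on top (:func:`integrate_concentrations`); giving every
enzyme a non-limiting concentration yields the fully expanded
GECKO-analogous model (:func:`gecko_expand`).

Units: kcat in 1/h, MW in g/mmol, fluxes in mmol/gDW/h, pool in g/gDW —
so the pool-row coefficients are dimensionless hours-times-mass ratios and
v_Pool is in g/gDW with no runtime conversion anywhere.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Set, Tuple

import cobra
from cobra.core.gene import GPR

from .model_io import ARTIFICIAL_BOUND, is_exchange, find_biomass, validate

logger = logging.getLogger("smoment")

FORWARD = "fwd"
REVERSE = "rev"

#: Default identifiers of the pool pseudo-species / pseudo-reaction.
POOL_MET_ID = "M_prot_pool"
POOL_RXN_ID = "R_prot_pool"

#: Suffixes appended by the transformations (ids are never rewritten).
SPLIT_FWD_SUFFIX = "_fwd"
SPLIT_REV_SUFFIX = "_rev"
ENZ_COPY_SUFFIX = "_enz_"  # concentration-exclusive reaction copy
ARM_MET_PREFIX = "M_arm_"
ARM_RXN_PREFIX = "R_arm_"
ENZ_MET_PREFIX = "M_enz_"
ENZ_RXN_PREFIX = "R_enz_"

#: Effectively non-limiting enzyme concentration (mmol/gDW) used by
#: :func:`gecko_expand`.
NON_LIMITING_CONCENTRATION = 1.0e9


# ---------------------------------------------------------------------------
# Direction bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class DirectionMap:
    """Maps original reaction ids to the columns of the split model.

    ``pairs[orig_id] = (forward_column_id, reverse_column_id or None)``.
    Downstream code never parses id suffixes; it goes through this map.
    """

    pairs: Dict[str, Tuple[str, Optional[str]]] = field(default_factory=dict)

    def column_of(self, rxn_id: str, direction: str = FORWARD) -> Optional[str]:
        fwd, rev = self.pairs[rxn_id]
        return fwd if direction == FORWARD else rev

    def columns(self) -> Iterator[Tuple[str, str, str]]:
        """Yield ``(column_id, original_reaction_id, direction)`` in
        original model order (forward before reverse)."""
        for orig, (fwd, rev) in self.pairs.items():
            yield fwd, orig, FORWARD
            if rev is not None:
                yield rev, orig, REVERSE

    def origin_of(self, column_id: str) -> Tuple[str, str]:
        for col, orig, direction in self.columns():
            if col == column_id:
                return orig, direction
        raise KeyError(column_id)

    def directions_of(self, rxn_id: str) -> Tuple[str, ...]:
        fwd, rev = self.pairs[rxn_id]
        return (FORWARD, REVERSE) if rev is not None else (FORWARD,)


def split_reversible(
    model: cobra.Model, scope: str = "enzymatic"
) -> Tuple[cobra.Model, DirectionMap]:
    """Split reversible reactions into irreversible forward/backward pairs.

    A reaction with bounds ``(a, b)``, ``a < 0``, becomes a forward copy
    (same stoichiometry, bounds ``[0, max(b, 0)]``) and a reverse copy
    (negated stoichiometry, bounds ``[0, -a]``).  With ``scope='enzymatic'``
    only gene-associated reactions are split (the pool row must not touch a
    reversible column); ``scope='all'`` splits every reversible reaction,
    the setting used for flux-variability comparisons.

    Returns a new model plus the :class:`DirectionMap`.
    """
    if scope not in ("enzymatic", "all"):
        raise ValueError(f"unknown split scope {scope!r}")
    out = model.copy()
    dmap = DirectionMap()
    to_remove = []
    to_add = []
    for rxn in out.reactions:
        in_scope = rxn.lower_bound < 0 and (scope == "all" or bool(rxn.genes))
        if not in_scope:
            dmap.pairs[rxn.id] = (rxn.id, None)
            continue
        fwd = cobra.Reaction(
            rxn.id + SPLIT_FWD_SUFFIX,
            name=rxn.name,
            lower_bound=0.0,
            upper_bound=max(rxn.upper_bound, 0.0),
        )
        fwd.add_metabolites(dict(rxn.metabolites))
        rev = cobra.Reaction(
            rxn.id + SPLIT_REV_SUFFIX,
            name=rxn.name,
            lower_bound=0.0,
            upper_bound=-rxn.lower_bound,
        )
        rev.add_metabolites({m: -c for m, c in rxn.metabolites.items()})
        for copy_ in (fwd, rev):
            copy_.gene_reaction_rule = rxn.gene_reaction_rule
            copy_.annotation = dict(rxn.annotation)
        dmap.pairs[rxn.id] = (fwd.id, rev.id)
        to_remove.append(rxn)
        to_add.extend([fwd, rev])
    objective_ids = {r.id for r in cobra.util.solver.linear_reaction_coefficients(out)}
    out.remove_reactions(to_remove)
    out.add_reactions(to_add)
    # restore objective if it was split
    for rid in objective_ids:
        if rid in dmap.pairs and dmap.pairs[rid][1] is not None:
            out.objective = dmap.pairs[rid][0]
    return out, dmap


# ---------------------------------------------------------------------------
# Enzymes from gene-protein-reaction rules
# ---------------------------------------------------------------------------

@dataclass
class Enzyme:
    """An enzyme: a single protein or a complex of several proteins.

    MW is in g/mmol (stoichiometry-weighted sum of subunit masses); kcat
    values, where enzyme-specific ones exist, are in 1/h keyed by
    ``(reaction_id, direction)``; ``concentration`` is a measured abundance
    in mmol/gDW, if available.
    """

    id: str
    subunits: Dict[str, int]
    MW: float
    kcat_by_direction: Dict[Tuple[str, str], float] = field(default_factory=dict)
    concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise ValueError(f"enzyme {self.id}: MW must be positive")
        if any(c < 1 or int(c) != c for c in self.subunits.values()):
            raise ValueError(f"enzyme {self.id}: subunit counts must be integers >= 1")


@dataclass
class ReactionEnzymeMap:
    """Bidirectional reaction <-> enzyme association (E(i) and R(E^k))."""

    enzymes_of: Dict[str, Set[str]] = field(default_factory=dict)
    reactions_of: Dict[str, Set[str]] = field(default_factory=dict)

    def add(self, rxn_id: str, enzyme_id: str) -> None:
        self.enzymes_of.setdefault(rxn_id, set()).add(enzyme_id)
        self.reactions_of.setdefault(enzyme_id, set()).add(rxn_id)

    def check_consistent(self) -> None:
        fwd = {(r, e) for r, es in self.enzymes_of.items() for e in es}
        rev = {(r, e) for e, rs in self.reactions_of.items() for r in rs}
        if fwd != rev:
            raise ValueError("reaction/enzyme maps are not mutual transposes")


def gpr_alternatives(rule: str) -> List[FrozenSet[str]]:
    """Normalize a GPR rule to OR-of-ANDs: a list of protein-id sets, one
    per isozyme alternative (each set is one enzyme, possibly a complex)."""
    rule = (rule or "").strip()
    if not rule:
        return []
    body = GPR.from_string(rule).body

    def walk(node: ast.AST) -> List[FrozenSet[str]]:
        if isinstance(node, ast.Name):
            return [frozenset([node.id])]
        if isinstance(node, ast.BoolOp):
            parts = [walk(v) for v in node.values]
            if isinstance(node.op, ast.Or):
                return [alt for p in parts for alt in p]
            # AND: distribute (cartesian union) into disjunctive normal form
            acc: List[FrozenSet[str]] = [frozenset()]
            for p in parts:
                acc = [a | b for a in acc for b in p]
            return acc
        raise ValueError(f"unsupported GPR element: {ast.dump(node)}")

    seen = set()
    out = []
    for alt in walk(body):
        if alt not in seen:
            seen.add(alt)
            out.append(alt)
    return out


def _enzyme_id(subunits: Iterable[str]) -> str:
    return "_and_".join(sorted(subunits))


def enzymes_from_gene_rules(
    model: cobra.Model,
    mw_table: Mapping[str, float],
    subunit_stoich: Optional[Mapping[str, int]] = None,
) -> Tuple[Dict[str, Enzyme], ReactionEnzymeMap]:
    """Derive the enzyme set and the reaction<->enzyme map from GPR rules.

    Each AND-conjunct becomes one enzyme (complex), each OR-alternative a
    distinct isozyme.  Complex MW is the stoichiometry-weighted sum of
    subunit masses (``subunit_stoich`` gives per-protein copy numbers,
    default 1).  Enzymes with a subunit missing from ``mw_table`` are
    dropped with a warning; a reaction whose enzymes all drop becomes
    enzyme-free (cost 0 downstream).
    """
    stoich = dict(subunit_stoich or {})
    enzymes: Dict[str, Enzyme] = {}
    remap = ReactionEnzymeMap()
    for rxn in model.reactions:
        for subunits in gpr_alternatives(rxn.gene_reaction_rule):
            missing = [p for p in subunits if p not in mw_table]
            if missing:
                logger.warning(
                    "reaction %s: enzyme %s dropped (no molecular weight for %s)",
                    rxn.id, _enzyme_id(subunits), ",".join(sorted(missing)),
                )
                continue
            eid = _enzyme_id(subunits)
            if eid not in enzymes:
                counts = {p: int(stoich.get(p, 1)) for p in sorted(subunits)}
                mw = sum(c * mw_table[p] for p, c in counts.items())
                enzymes[eid] = Enzyme(id=eid, subunits=counts, MW=mw)
            remap.add(rxn.id, eid)
        if rxn.genes and rxn.id not in remap.enzymes_of:
            logger.warning("reaction %s: all enzymes dropped, treated as enzyme-free", rxn.id)
    remap.check_consistent()
    return enzymes, remap


# ---------------------------------------------------------------------------
# Enzyme costs
# ---------------------------------------------------------------------------

@dataclass
class EnzymeCostTable:
    """Minimal enzyme cost c = MW/kcat (g*h/mmol) per model column.

    ``cost[column_id]`` is 0 for enzyme-free or exempted (exchange/biomass)
    columns; ``chosen[column_id]`` records the argmin enzyme (ties broken
    by lexicographically smallest enzyme id), None where cost is 0.
    ``kcat[column_id]`` is the turnover number (1/h) behind the cost.
    """

    cost: Dict[str, float] = field(default_factory=dict)
    chosen: Dict[str, Optional[str]] = field(default_factory=dict)
    kcat: Dict[str, float] = field(default_factory=dict)

    def copy(self) -> "EnzymeCostTable":
        return EnzymeCostTable(dict(self.cost), dict(self.chosen), dict(self.kcat))


def compute_enzyme_costs(
    dmap: DirectionMap,
    rxn_enz_map: ReactionEnzymeMap,
    enzymes: Mapping[str, Enzyme],
    kcat_by_direction: Mapping[Tuple[str, str], float],
    exempt: Optional[Set[str]] = None,
) -> EnzymeCostTable:
    """Select the minimal enzyme cost for every reaction direction.

    For each column (reaction direction) the cost is
    ``min over catalyzing enzymes of MW_E / kcat_E`` where an enzyme's kcat
    is its own direction-specific value if it has one, else the
    direction-level assigned value.  Enzymes with no kcat for the direction
    are excluded from the minimum; if all are excluded, the column is
    treated as enzyme-free (cost 0, warning).  ``exempt`` lists original
    reaction ids (exchanges, biomass) that are pool-exempt by design.
    """
    exempt = exempt or set()
    table = EnzymeCostTable()
    for col, orig, direction in dmap.columns():
        eids = rxn_enz_map.enzymes_of.get(orig, set())
        if not eids or orig in exempt:
            table.cost[col] = 0.0
            table.chosen[col] = None
            continue
        best: Optional[Tuple[float, str, float]] = None
        for eid in sorted(eids):
            enz = enzymes[eid]
            k = enz.kcat_by_direction.get((orig, direction))
            if k is None:
                k = kcat_by_direction.get((orig, direction))
            if k is None or k <= 0:
                continue
            c = enz.MW / k
            # strict < plus sorted iteration keeps the lexicographically
            # smallest enzyme id on cost ties
            if best is None or c < best[0]:
                best = (c, eid, k)
        if best is None:
            logger.warning(
                "reaction %s (%s): no kcat for any enzyme, treated as enzyme-free",
                orig, direction,
            )
            table.cost[col] = 0.0
            table.chosen[col] = None
        else:
            table.cost[col], table.chosen[col], table.kcat[col] = best
    return table


# ---------------------------------------------------------------------------
# Pool augmentation
# ---------------------------------------------------------------------------

@dataclass
class ProteinPool:
    """Total metabolic enzyme pool P (g/gDW) with mean saturation sigma_hat.

    The pool-delivery pseudo-reaction is bounded by the *effective* pool
    P_eff = sigma_hat * P, which is what calibration against flux data
    actually determines (individual saturation levels are not identifiable).
    """

    P: float
    sigma_hat: float = 1.0
    pool_met_id: str = POOL_MET_ID
    pool_rxn_id: str = POOL_RXN_ID

    def __post_init__(self) -> None:
        if not (0 < self.sigma_hat <= 1):
            raise ValueError("sigma_hat must be in (0, 1]")
        if self.P <= 0:
            raise ValueError("P must be positive")

    @property
    def P_eff(self) -> float:
        return self.sigma_hat * self.P


def augment_with_pool(
    model: cobra.Model,
    costs: EnzymeCostTable,
    pool: ProteinPool,
) -> cobra.Model:
    """Add the enzyme-pool row and pool-delivery column to the matrix.

    The pool pseudo-metabolite is consumed with coefficient ``-cost[col]``
    by every costed column and produced (+1) by the pool pseudo-reaction,
    whose upper bound is P_eff.  An (m x r) model becomes (m+1) x (r+1).

    Raises ``ValueError`` if a costed reaction is still reversible — split
    first.
    """
    for col, c in costs.cost.items():
        if c > 0 and model.reactions.get_by_id(col).lower_bound < 0:
            raise ValueError(
                f"reaction {col} is reversible but carries enzyme cost "
                f"{c:g}; run split_reversible first"
            )
    out = model.copy()
    pool_met = cobra.Metabolite(pool.pool_met_id, name="enzyme pool", compartment="c")
    for col, c in costs.cost.items():
        if c != 0.0:
            out.reactions.get_by_id(col).add_metabolites({pool_met: -c})
    delivery = cobra.Reaction(
        pool.pool_rxn_id, name="enzyme pool delivery",
        lower_bound=0.0, upper_bound=pool.P_eff,
    )
    delivery.add_metabolites({pool_met: 1.0})
    out.add_reactions([delivery])
    return out


# ---------------------------------------------------------------------------
# The assembled enzyme-constrained model
# ---------------------------------------------------------------------------

@dataclass
class SMomentModel:
    """Bundle of the augmented model and the bookkeeping around it."""

    model: cobra.Model
    direction_map: DirectionMap
    enzymes: Dict[str, Enzyme]
    rxn_enz_map: ReactionEnzymeMap
    costs: EnzymeCostTable
    pool: ProteinPool

    def copy(self) -> "SMomentModel":
        return SMomentModel(
            model=self.model.copy(),
            direction_map=DirectionMap(dict(self.direction_map.pairs)),
            enzymes=dict(self.enzymes),
            rxn_enz_map=self.rxn_enz_map,
            costs=self.costs.copy(),
            pool=ProteinPool(self.pool.P, self.pool.sigma_hat,
                             self.pool.pool_met_id, self.pool.pool_rxn_id),
        )

    @property
    def pool_metabolite(self) -> cobra.Metabolite:
        return self.model.metabolites.get_by_id(self.pool.pool_met_id)

    def set_pool_bound(self, p_eff: float) -> None:
        """Set the effective pool P_eff (g/gDW); updates the delivery bound."""
        if p_eff <= 0:
            raise ValueError("P_eff must be positive")
        self.pool = ProteinPool(p_eff / self.pool.sigma_hat, self.pool.sigma_hat,
                                self.pool.pool_met_id, self.pool.pool_rxn_id)
        self.model.reactions.get_by_id(self.pool.pool_rxn_id).upper_bound = p_eff

    def kcat_of(self, rxn_id: str, direction: str = FORWARD) -> Optional[float]:
        col = self.direction_map.column_of(rxn_id, direction)
        return self.costs.kcat.get(col)

    def set_kcat(self, rxn_id: str, direction: str, kcat: float) -> None:
        """Re-parameterize one reaction direction's turnover number (1/h).

        Rescales the cost c = MW/kcat and the matching pool-row coefficient
        in place; the chosen enzyme is unchanged (all enzymes of a direction
        share the assigned kcat, so the argmin is decided by MW alone).
        """
        if kcat <= 0:
            raise ValueError("kcat must be positive")
        col = self.direction_map.column_of(rxn_id, direction)
        if col is None or self.costs.cost.get(col, 0.0) == 0.0:
            raise KeyError(f"no enzyme cost on {rxn_id} ({direction})")
        old = self.costs.kcat[col]
        new_cost = self.costs.cost[col] * old / kcat
        self.costs.kcat[col] = kcat
        self.costs.cost[col] = new_cost
        self.model.reactions.get_by_id(col).add_metabolites(
            {self.pool_metabolite: -new_cost}, combine=False
        )

    def scale_kcat(self, rxn_id: str, factor: float) -> None:
        """Scale the kcat of every direction of one reaction by ``factor``."""
        for direction in self.direction_map.directions_of(rxn_id):
            col = self.direction_map.column_of(rxn_id, direction)
            if col is not None and self.costs.cost.get(col, 0.0) > 0:
                self.set_kcat(rxn_id, direction, self.costs.kcat[col] * factor)

    def costed_reactions(self) -> List[str]:
        """Original reaction ids with a positive enzyme cost, model order."""
        out = []
        for rxn_id in self.direction_map.pairs:
            for direction in self.direction_map.directions_of(rxn_id):
                col = self.direction_map.column_of(rxn_id, direction)
                if self.costs.cost.get(col, 0.0) > 0:
                    out.append(rxn_id)
                    break
        return out


def default_exempt(model: cobra.Model) -> Set[str]:
    """Reactions that are pool-exempt by design: exchanges and biomass."""
    exempt = {r.id for r in model.reactions if is_exchange(r)}
    biomass = find_biomass(model)
    if biomass is not None:
        exempt.add(biomass.id)
    return exempt


def build_smoment(
    model: cobra.Model,
    mw_table: Mapping[str, float],
    kcat_db,
    taxonomy,
    organism: str,
    pool: ProteinPool,
    custom_db=None,
    split_scope: str = "enzymatic",
    subunit_stoich: Optional[Mapping[str, int]] = None,
    min_count: int = 10,
) -> "SMomentModel":
    """End-to-end construction of an sMOMENT model from a plain model.

    Runs: validate -> split reversibles -> enzymes from GPR -> kcat
    assignment from the local databases -> minimal-cost table -> pool
    augmentation.  Returns the assembled :class:`SMomentModel`.
    """
    from .kcat import assign_all  # deferred: kcat imports this module

    validate(model)
    split, dmap = split_reversible(model, scope=split_scope)
    enzymes, remap = enzymes_from_gene_rules(model, mw_table, subunit_stoich)
    assignment = assign_all(
        model, dmap, remap, enzymes, kcat_db, taxonomy, organism,
        custom_db=custom_db, min_count=min_count,
    )
    exempt = default_exempt(model)
    costs = compute_enzyme_costs(dmap, remap, enzymes,
                                 assignment.value_by_direction, exempt)
    augmented = augment_with_pool(split, costs, pool)
    return SMomentModel(augmented, dmap, enzymes, remap, costs, pool)


# ---------------------------------------------------------------------------
# Enzyme-concentration integration (GECKO-style, but only where measured)
# ---------------------------------------------------------------------------

def integrate_concentrations(
    sm: SMomentModel,
    concentrations: Mapping[str, float],
) -> SMomentModel:
    """Constrain measured enzymes: sum of v_i/kcat_i over the reactions an
    enzyme catalyzes may not exceed its measured concentration (mmol/gDW).

    Where a measured enzyme shares a reaction with other enzymes, the
    reaction column is split into an exclusive copy (catalyzed only by the
    measured enzyme, cost MW/kcat of that enzyme) and the original column
    kept for the remaining enzymes (cost re-minimized over them).  If the
    shared reaction had a finite flux bound, a linking arm pseudo-metabolite
    enforces the original bound on the *sum* of the copies.  One
    pseudo-metabolite/pseudo-reaction pair per measured enzyme encodes the
    concentration cap.  Constraints are only added, never removed, so the
    feasible flux space can only shrink.
    """
    sm = sm.copy()
    model = sm.model
    pool_met = sm.pool_metabolite
    # working per-column enzyme sets
    col_enzymes: Dict[str, Set[str]] = {}
    for col, orig, _d in sm.direction_map.columns():
        if sm.costs.cost.get(col, 0.0) > 0:
            col_enzymes[col] = set(sm.rxn_enz_map.enzymes_of.get(orig, set()))
    arms: Dict[str, cobra.Metabolite] = {}

    for eid in sorted(concentrations):
        conc = concentrations[eid]
        if eid not in sm.enzymes:
            raise KeyError(f"concentration given for unknown enzyme {eid!r}")
        if conc <= 0:
            raise ValueError(f"enzyme {eid}: concentration must be positive")
        enz = sm.enzymes[eid]
        exclusive: List[str] = []
        for col in [c for c, es in col_enzymes.items() if eid in es]:
            if col_enzymes[col] == {eid}:
                exclusive.append(col)
                continue
            rxn = model.reactions.get_by_id(col)
            kcat = sm.costs.kcat[col]
            # exclusive copy for the measured enzyme
            copy_ = cobra.Reaction(
                f"{col}{ENZ_COPY_SUFFIX}{eid}", name=rxn.name,
                lower_bound=0.0, upper_bound=rxn.upper_bound,
            )
            stoich = {m: c for m, c in rxn.metabolites.items() if m is not pool_met}
            copy_.add_metabolites(stoich)
            copy_.add_metabolites({pool_met: -enz.MW / kcat})
            copy_.gene_reaction_rule = " and ".join(sorted(enz.subunits))
            model.add_reactions([copy_])
            sm.costs.cost[copy_.id] = enz.MW / kcat
            sm.costs.chosen[copy_.id] = eid
            sm.costs.kcat[copy_.id] = kcat
            col_enzymes[copy_.id] = {eid}
            # original column keeps the remaining enzymes, cost re-minimized
            col_enzymes[col] -= {eid}
            rest = sorted(col_enzymes[col])
            best = min((sm.enzymes[e].MW / kcat, e) for e in rest)
            sm.costs.cost[col], sm.costs.chosen[col] = best[0], best[1]
            rxn.add_metabolites({pool_met: -best[0]}, combine=False)
            # arm constraint if the original bound was finite
            if rxn.upper_bound < ARTIFICIAL_BOUND:
                if col not in arms:
                    arm_met = cobra.Metabolite(
                        f"{ARM_MET_PREFIX}{col}", name=f"arm of {col}",
                        compartment="c",
                    )
                    arms[col] = arm_met
                    rxn.add_metabolites({arm_met: 1.0})
                    drain = cobra.Reaction(
                        f"{ARM_RXN_PREFIX}{col}", lower_bound=0.0,
                        upper_bound=rxn.upper_bound,
                    )
                    drain.add_metabolites({arm_met: -1.0})
                    model.add_reactions([drain])
                copy_.add_metabolites({arms[col]: 1.0})
            exclusive.append(copy_.id)
        if not exclusive:
            logger.warning("enzyme %s catalyzes no costed reaction; concentration ignored", eid)
            continue
        enz_met = cobra.Metabolite(
            f"{ENZ_MET_PREFIX}{eid}", name=f"enzyme {eid}", compartment="c",
        )
        for col in exclusive:
            model.reactions.get_by_id(col).add_metabolites(
                {enz_met: -1.0 / sm.costs.kcat[col]}
            )
        delivery = cobra.Reaction(
            f"{ENZ_RXN_PREFIX}{eid}", name=f"delivery of {eid}",
            lower_bound=0.0, upper_bound=conc,
        )
        delivery.add_metabolites({enz_met: 1.0})
        model.add_reactions([delivery])
        sm.enzymes[eid] = Enzyme(enz.id, enz.subunits, enz.MW,
                                 dict(enz.kcat_by_direction), conc)
    return sm


def gecko_expand(sm: SMomentModel) -> SMomentModel:
    """Fully expanded GECKO-analogous model: every enzyme gets an explicit
    concentration constraint with a non-limiting concentration, so the
    feasible flux space (and any LP optimum) is unchanged."""
    used = {
        e for col, es in _columns_with_enzymes(sm).items() for e in es
    }
    return integrate_concentrations(
        sm, {eid: NON_LIMITING_CONCENTRATION for eid in sorted(used)}
    )


def strip_pool(sm: SMomentModel) -> cobra.Model:
    """Copy of the augmented model with the pool row and delivery column
    removed — the plain split model the augmentation started from."""
    m = sm.model.copy()
    m.remove_reactions([m.reactions.get_by_id(sm.pool.pool_rxn_id)])
    met = m.metabolites.get_by_id(sm.pool.pool_met_id)
    for rxn in list(met.reactions):
        rxn.subtract_metabolites({met: rxn.metabolites[met]})
    m.remove_metabolites([met])
    return m


def _columns_with_enzymes(sm: SMomentModel) -> Dict[str, Set[str]]:
    out: Dict[str, Set[str]] = {}
    for col, orig, _d in sm.direction_map.columns():
        if sm.costs.cost.get(col, 0.0) > 0:
            out[col] = set(sm.rxn_enz_map.enzymes_of.get(orig, set()))
    return out
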