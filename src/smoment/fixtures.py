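"""Synthetic toy fixtures and an explicit-enzyme oracle.

Everything here exists so the whole pipeline is exercisable offline at toy
scale: seeded generators produce a small linear-pathway model together
with the side data the pipeline consumes in the wild (a protein
molecular-weight table, an EC-keyed kinetic database with substrate and
organism metadata, a taxonomy lineage map, and flux measurements obtained
by solving the generated model itself).  A two-pathway "overflow" fixture
with an analytically known critical uptake rate mirrors the classic
respiration/fermentation switch.

The oracle (:func:`oracle_optimum`) formulates the *original* MOMENT
program — explicit enzyme-concentration variables g with v <= kcat * g
per (reaction, enzyme) pair and sum(g * MW) <= P — as a dense LP solved
with scipy's HiGHS backend.  It shares no code path with the compact
pool-row formulation (which runs through cobra/GLPK), so agreement
between the two is a genuine cross-check of the matrix augmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import cobra
import numpy as np
from scipy.optimize import linprog

from .calibration import FluxMeasurementSet, Scenario
from .core import (
    FORWARD,
    REVERSE,
    ProteinPool,
    SMomentModel,
    build_smoment,
)
from .kcat import KcatDatabase, TaxonomyMap, PER_SECOND_TO_PER_HOUR
from .model_io import set_organism

#: Scale guard: the oracle is a test instrument, not a production solver.
ORACLE_MAX_REACTIONS = 200

DEFAULT_ORGANISM = "Toyococcus modelii"
SISTER_ORGANISM = "Toyococcus vicinus"
DISTANT_ORGANISM = "Alienobacter remotus"


def default_taxonomy() -> TaxonomyMap:
    """Three-taxon toy taxonomy.  Lineages start with a species-level
    clade so congeneric species sit at distance 1, not 0."""
    return TaxonomyMap({
        DEFAULT_ORGANISM: ["modelii-clade", "Toyococcus", "Toyococcaceae",
                           "Bacteria", "cellular organisms"],
        SISTER_ORGANISM: ["vicinus-clade", "Toyococcus", "Toyococcaceae",
                          "Bacteria", "cellular organisms"],
        DISTANT_ORGANISM: ["Alienobacter", "Alienobacteraceae",
                           "Bacteria", "cellular organisms"],
    })


# ---------------------------------------------------------------------------
# Toy model generation
# ---------------------------------------------------------------------------

@dataclass
class ToyModelSpec:
    """Blueprint of a seeded linear-pathway toy model.

    ``patterns`` (one of ``single``/``isozyme``/``complex`` per pathway
    step) and ``reversible`` flags are drawn from the seed when omitted,
    with the guarantees the default fixture must provide: at least one
    reversible enzymatic reaction, one isozyme pair, one complex and one
    enzyme-free reaction.  ``maintenance`` is a non-growth demand
    (mmol/gDW/h) on the first pathway intermediate.  ``p_eff`` is the
    effective protein pool (g/gDW) used when building the enzyme-
    constrained form and the self-generated measurements.
    """

    n_steps: int = 4
    patterns: Optional[List[str]] = None
    reversible: Optional[List[bool]] = None
    maintenance: float = 0.0
    p_eff: float = 0.1
    seed: int = 0
    noise_sigma: float = 0.0  # lognormal noise on measurements; off by default
    organism: str = DEFAULT_ORGANISM
    db_entries_per_direction: int = 10
    decoy_entries: int = 3


@dataclass
class ToyFixture:
    """A generated toy model plus all side data and the built sMOMENT form."""

    spec: ToyModelSpec
    model: cobra.Model
    mw_table: Dict[str, float]
    subunit_stoich: Dict[str, int]
    kcat_db: KcatDatabase
    taxonomy: TaxonomyMap
    organism: str
    true_kcats_h: Dict[Tuple[str, str], float]
    smoment: SMomentModel
    measurements: FluxMeasurementSet
    expected: Dict[str, float] = field(default_factory=dict)

    @property
    def biomass_id(self) -> str:
        return "BIOMASS_toy"


def make_toy_model(spec: ToyModelSpec) -> ToyFixture:
    """Generate the deterministic toy fixture described by ``spec``.

    The pathway is EX_S -> uptake -> n 1:1 conversion steps -> biomass
    drain; kinetic parameters are seeded draws (kcat 10-100 /s, subunit
    masses 20-100 g/mmol).  The kinetic database holds, per reaction
    direction, ``db_entries_per_direction`` same-organism entries at the
    true value plus sister-taxon decoys at 7x the value, so correct
    substrate/taxonomy selection is required to recover the true kcats.
    Measurements are produced by solving the built sMOMENT model itself.
    """
    if spec.n_steps < 1:
        raise ValueError("a toy model needs at least one pathway step")
    rng = np.random.default_rng(spec.seed)
    patterns = list(spec.patterns) if spec.patterns is not None else None
    if patterns is None:
        patterns = [str(rng.choice(["single", "isozyme", "complex"]))
                    for _ in range(spec.n_steps)]
        patterns[0] = "complex"
        if spec.n_steps > 1:
            patterns[1] = "isozyme"
    if len(patterns) != spec.n_steps:
        raise ValueError("patterns length must equal n_steps")
    reversible = list(spec.reversible) if spec.reversible is not None else None
    if reversible is None:
        reversible = [bool(rng.random() < 0.3) for _ in range(spec.n_steps)]
        reversible[spec.n_steps // 2] = True
    if len(reversible) != spec.n_steps:
        raise ValueError("reversible length must equal n_steps")

    model = cobra.Model(f"toy_seed{spec.seed}")
    set_organism(model, spec.organism)
    s_e = cobra.Metabolite("S_e", name="substrate (ext)", compartment="e")
    mets = [cobra.Metabolite(f"M{i}_c", compartment="c")
            for i in range(spec.n_steps + 1)]
    reactions: List[cobra.Reaction] = []

    ex = cobra.Reaction("EX_S_e", lower_bound=-1000.0, upper_bound=1000.0)
    ex.add_metabolites({s_e: -1})
    reactions.append(ex)

    mw_table: Dict[str, float] = {}
    subunit_stoich: Dict[str, int] = {}
    true_kcats_s: Dict[Tuple[str, str], float] = {}

    def enzymatic(rxn_id: str, stoich, ec: str, genes: str, rev: bool) -> None:
        lb = -1000.0 if rev else 0.0
        r = cobra.Reaction(rxn_id, lower_bound=lb, upper_bound=1000.0)
        r.add_metabolites(stoich)
        r.gene_reaction_rule = genes
        r.annotation["ec-code"] = ec
        reactions.append(r)
        true_kcats_s[(rxn_id, FORWARD)] = float(rng.uniform(10.0, 100.0))
        if rev:
            true_kcats_s[(rxn_id, REVERSE)] = float(rng.uniform(10.0, 100.0))

    up_rule = "gT"
    mw_table["gT"] = float(rng.uniform(20.0, 100.0))
    enzymatic("T_UP", {s_e: -1, mets[0]: 1}, "2.7.1.1", up_rule, rev=False)

    for i in range(spec.n_steps):
        rid = f"R{i + 1}"
        ga, gb = f"g{i + 1}a", f"g{i + 1}b"
        mw_table[ga] = float(rng.uniform(20.0, 100.0))
        if patterns[i] == "single":
            rule = ga
        elif patterns[i] == "isozyme":
            mw_table[gb] = float(rng.uniform(20.0, 100.0))
            rule = f"{ga} or {gb}"
        elif patterns[i] == "complex":
            mw_table[gb] = float(rng.uniform(20.0, 100.0))
            subunit_stoich[gb] = 2
            rule = f"{ga} and {gb}"
        else:
            raise ValueError(f"unknown pattern {patterns[i]!r}")
        enzymatic(rid, {mets[i]: -1, mets[i + 1]: 1}, f"1.1.1.{i + 1}",
                  rule, reversible[i])

    if spec.maintenance > 0:
        ngam = cobra.Reaction("NGAM", lower_bound=spec.maintenance,
                              upper_bound=1000.0)
        ngam.add_metabolites({mets[0]: -1})
        reactions.append(ngam)

    biomass = cobra.Reaction("BIOMASS_toy", lower_bound=0.0, upper_bound=1000.0)
    biomass.add_metabolites({mets[-1]: -1})
    reactions.append(biomass)

    model.add_reactions(reactions)
    model.objective = "BIOMASS_toy"

    # --- kinetic database: true values for the model organism, decoys from
    # a sister taxon at 7x so wrong selection is visible
    db = KcatDatabase()
    tax = default_taxonomy()
    for (rid, direction), kcat_s in true_kcats_s.items():
        rxn = model.reactions.get_by_id(rid)
        sign = -1 if direction == FORWARD else 1
        subs = sorted(
            m.id.rsplit("_", 1)[0]
            for m, c in rxn.metabolites.items() if c * sign > 0
        )
        ec = rxn.annotation["ec-code"]
        for _ in range(spec.db_entries_per_direction):
            db.add(ec, kcat_s, subs, spec.organism)
        for _ in range(spec.decoy_entries):
            db.add(ec, kcat_s * 7.0, subs, SISTER_ORGANISM)

    true_kcats_h = {k: v * PER_SECOND_TO_PER_HOUR
                    for k, v in true_kcats_s.items()}

    sm = build_smoment(
        model, mw_table, db, tax, spec.organism,
        ProteinPool(spec.p_eff), subunit_stoich=subunit_stoich,
    )

    # --- closed-form ceiling for the 1:1 chain: all steps carry the growth
    # flux, the uptake step additionally carries the maintenance demand
    def min_cost(rid: str) -> float:
        rxn = model.reactions.get_by_id(rid)
        alts = []
        for alt in rxn.gene_reaction_rule.replace("(", "").replace(")", "").split(" or "):
            proteins = [p.strip() for p in alt.split(" and ")]
            mw = sum(subunit_stoich.get(p, 1) * mw_table[p] for p in proteins)
            alts.append(mw / true_kcats_h[(rid, FORWARD)])
        return min(alts)

    c_up = min_cost("T_UP")
    c_steps = sum(min_cost(f"R{i + 1}") for i in range(spec.n_steps))
    total = c_up + c_steps
    mu_expected = (spec.p_eff - c_up * spec.maintenance) / total
    expected = {"max_growth": mu_expected, "total_cost": total}

    mu = sm.model.slim_optimize()
    if spec.noise_sigma > 0:
        mu *= math.exp(rng.normal(0.0, spec.noise_sigma))
    measurements = FluxMeasurementSet([
        Scenario("ref", environment={}, measurements={"BIOMASS_toy": float(mu)})
    ])

    return ToyFixture(
        spec=spec, model=model, mw_table=mw_table,
        subunit_stoich=subunit_stoich, kcat_db=db, taxonomy=tax,
        organism=spec.organism, true_kcats_h=true_kcats_h, smoment=sm,
        measurements=measurements, expected=expected,
    )


# ---------------------------------------------------------------------------
# Overflow fixture
# ---------------------------------------------------------------------------

@dataclass
class OverflowFixture:
    model: cobra.Model
    mw_table: Dict[str, float]
    kcat_db: KcatDatabase
    taxonomy: TaxonomyMap
    organism: str
    smoment: SMomentModel
    expected: Dict[str, float]


def make_overflow_fixture(
    p_eff: float = 0.01,
    maintenance: float = 0.5,
) -> OverflowFixture:
    """Two-pathway energy model with an analytic overflow switch.

    An efficient pathway yields 2 ATP per substrate at high enzyme cost;
    an overflow pathway yields 1 ATP plus an excreted byproduct at low
    cost.  Below the critical uptake u* = P_eff / (c_uptake + c_efficient)
    the optimum is purely efficient (no byproduct); above it, the protein
    pool forces a growing overflow fraction.  The analytic switch point,
    maximal uptake and minimal (maintenance-driven) uptake are recorded in
    ``expected``.
    """
    organism = DEFAULT_ORGANISM
    model = cobra.Model("overflow_toy")
    set_organism(model, organism)
    s_e = cobra.Metabolite("S_e", compartment="e")
    s_c = cobra.Metabolite("S_c", compartment="c")
    atp = cobra.Metabolite("ATP_c", compartment="c")
    p_c = cobra.Metabolite("P_c", compartment="c")
    p_e = cobra.Metabolite("P_e", compartment="e")

    params = {  # (MW g/mmol, kcat 1/s, EC)
        "T_S": (30.0, 50.0, "2.7.1.2"),
        "R_EFF": (60.0, 20.0, "1.1.1.1"),
        "R_OVF": (25.0, 80.0, "1.1.1.2"),
    }
    stoichs = {
        "T_S": {s_e: -1, s_c: 1},
        "R_EFF": {s_c: -1, atp: 2},
        "R_OVF": {s_c: -1, atp: 1, p_c: 1},
    }
    reactions = []
    ex_s = cobra.Reaction("EX_S_e", lower_bound=-1000.0, upper_bound=1000.0)
    ex_s.add_metabolites({s_e: -1})
    reactions.append(ex_s)
    mw_table: Dict[str, float] = {}
    db = KcatDatabase()
    for rid, (mw, kcat_s, ec) in params.items():
        gene = f"g{rid}"
        mw_table[gene] = mw
        r = cobra.Reaction(rid, lower_bound=0.0, upper_bound=1000.0)
        r.add_metabolites(stoichs[rid])
        r.gene_reaction_rule = gene
        r.annotation["ec-code"] = ec
        reactions.append(r)
        subs = sorted(m.id.rsplit("_", 1)[0]
                      for m, c in stoichs[rid].items() if c < 0)
        for _ in range(10):
            db.add(ec, kcat_s, subs, organism)
    t_p = cobra.Reaction("T_P", lower_bound=0.0, upper_bound=1000.0)
    t_p.add_metabolites({p_c: -1, p_e: 1})  # spontaneous export, no enzyme
    ex_p = cobra.Reaction("EX_P_e", lower_bound=0.0, upper_bound=1000.0)
    ex_p.add_metabolites({p_e: -1})
    atpm = cobra.Reaction("ATPM", lower_bound=maintenance, upper_bound=1000.0)
    atpm.add_metabolites({atp: -1})
    biomass = cobra.Reaction("BIOMASS_toy", lower_bound=0.0, upper_bound=1000.0)
    biomass.add_metabolites({atp: -1})
    reactions += [t_p, ex_p, atpm, biomass]
    model.add_reactions(reactions)
    model.objective = "BIOMASS_toy"

    tax = default_taxonomy()
    sm = build_smoment(model, mw_table, db, tax, organism, ProteinPool(p_eff))

    def cost(rid: str) -> float:
        mw, kcat_s, _ = params[rid]
        return mw / (kcat_s * PER_SECOND_TO_PER_HOUR)

    c_t, c_eff, c_ovf = cost("T_S"), cost("R_EFF"), cost("R_OVF")
    expected = {
        "critical_uptake": p_eff / (c_t + c_eff),
        "max_uptake": p_eff / (c_t + c_ovf),
        "min_uptake": maintenance / 2.0,
        "cost_uptake": c_t,
        "cost_efficient": c_eff,
        "cost_overflow": c_ovf,
    }
    return OverflowFixture(model, mw_table, db, tax, organism, sm, expected)


# ---------------------------------------------------------------------------
# Explicit-enzyme oracle (original MOMENT formulation as a dense LP)
# ---------------------------------------------------------------------------

def oracle_optimum(
    model: cobra.Model,
    column_enzymes: Mapping[str, Sequence[Tuple[float, float]]],
    p_eff: float,
    objective: str,
) -> float:
    """LP optimum of the explicit enzyme-allocation program.

    ``model`` is the split (irreversible) model *without* the pool row;
    ``column_enzymes[rxn_id]`` lists ``(MW, kcat_per_h)`` for every enzyme
    that can catalyze that column.  Each (column, enzyme) pair gets its own
    flux share v and concentration g with v <= kcat * g; the shares sum to
    the column flux, and sum(g * MW) <= p_eff.  Solved densely with
    scipy/HiGHS; refuses models beyond toy scale.
    """
    n_r = len(model.reactions)
    if n_r > ORACLE_MAX_REACTIONS:
        raise ValueError(
            f"oracle is a test instrument; refusing model with {n_r} reactions"
        )
    mets = {m.id: i for i, m in enumerate(model.metabolites)}
    n_m = len(mets)

    v_index: Dict[Tuple[str, int], int] = {}
    col_vars: Dict[str, List[int]] = {}
    nvar = 0
    for rxn in model.reactions:
        enz = column_enzymes.get(rxn.id) or []
        k = max(len(enz), 1)
        col_vars[rxn.id] = list(range(nvar, nvar + k))
        for j in range(k):
            v_index[(rxn.id, j)] = nvar + j
        nvar += k
    g_index: Dict[Tuple[str, int], int] = {}
    for rxn in model.reactions:
        for j, _ in enumerate(column_enzymes.get(rxn.id) or []):
            g_index[(rxn.id, j)] = nvar
            nvar += 1

    A_eq = np.zeros((n_m, nvar))
    for rxn in model.reactions:
        for met, coeff in rxn.metabolites.items():
            for idx in col_vars[rxn.id]:
                A_eq[mets[met.id], idx] = coeff
    b_eq = np.zeros(n_m)

    rows: List[np.ndarray] = []
    rhs: List[float] = []
    for rxn in model.reactions:
        enz = column_enzymes.get(rxn.id) or []
        for j, (_mw, kcat) in enumerate(enz):
            row = np.zeros(nvar)
            row[v_index[(rxn.id, j)]] = 1.0
            row[g_index[(rxn.id, j)]] = -kcat
            rows.append(row)
            rhs.append(0.0)
        if enz:
            row = np.zeros(nvar)
            for idx in col_vars[rxn.id]:
                row[idx] = 1.0
            rows.append(row)
            rhs.append(rxn.upper_bound)
            if rxn.lower_bound > 0:
                rows.append(-row)
                rhs.append(-rxn.lower_bound)
    pool_row = np.zeros(nvar)
    for (rid, j), gi in g_index.items():
        pool_row[gi] = column_enzymes[rid][j][0]
    rows.append(pool_row)
    rhs.append(p_eff)

    bounds = []
    for rxn in model.reactions:
        enz = column_enzymes.get(rxn.id) or []
        if enz:
            bounds.extend([(0.0, None)] * len(enz))
        else:
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    bounds.extend([(0.0, None)] * len(g_index))

    c = np.zeros(nvar)
    for idx in col_vars[objective]:
        c[idx] = -1.0

    res = linprog(c, A_ub=np.vstack(rows), b_ub=np.array(rhs),
                  A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 3:
        return math.inf
    if not res.success:
        raise RuntimeError(f"oracle LP failed: {res.message}")
    return float(-res.fun)


def oracle_from_smoment(
    sm: SMomentModel, objective: Optional[str] = None
) -> float:
    """Run the oracle on the explicit-enzyme equivalent of an sMOMENT model
    (pool row stripped, per-column enzyme lists reconstructed)."""
    from .core import strip_pool
    from .model_io import find_biomass

    plain = strip_pool(sm)
    if objective is None:
        biomass = find_biomass(plain)
        if biomass is None:
            raise ValueError("no objective reaction identified")
        objective = biomass.id
    column_enzymes: Dict[str, List[Tuple[float, float]]] = {}
    for col, orig, direction in sm.direction_map.columns():
        if sm.costs.cost.get(col, 0.0) <= 0:
            continue
        entries = []
        for eid in sorted(sm.rxn_enz_map.enzymes_of.get(orig, set())):
            enz = sm.enzymes[eid]
            k = enz.kcat_by_direction.get((orig, direction),
                                          sm.costs.kcat.get(col))
            if k:
                entries.append((enz.MW, k))
        if entries:
            column_enzymes[col] = entries
    return oracle_optimum(plain, column_enzymes, sm.pool.P_eff, objective)
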