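"""Shared fixtures: seeded toy models and hand-assembled micro models."""

import cobra
import pytest

from smoment.core import (
    FORWARD,
    REVERSE,
    Enzyme,
    ProteinPool,
    ReactionEnzymeMap,
    SMomentModel,
    augment_with_pool,
    compute_enzyme_costs,
    split_reversible,
)
from smoment.fixtures import ToyModelSpec, make_overflow_fixture, make_toy_model


@pytest.fixture(scope="session")
def toy():
    """Default seeded toy fixture (pathway + databases + measurements)."""
    return make_toy_model(ToyModelSpec(seed=0))


@pytest.fixture(scope="session")
def overflow():
    return make_overflow_fixture()


def assemble(model, enzyme_spec, p_eff, exempt=None):
    """Hand-assemble an SMomentModel from explicit enzyme parameters.

    ``enzyme_spec[rxn_id] = [(enzyme_id, MW, kcat_per_h), ...]``; every
    listed enzyme gets the given kcat for both directions of its reaction.
    """
    split, dmap = split_reversible(model, scope="enzymatic")
    enzymes = {}
    remap = ReactionEnzymeMap()
    for rid, entries in enzyme_spec.items():
        for eid, mw, kcat in entries:
            enzymes[eid] = Enzyme(
                id=eid,
                subunits={eid: 1},
                MW=mw,
                kcat_by_direction={(rid, FORWARD): kcat, (rid, REVERSE): kcat},
            )
            remap.add(rid, eid)
    costs = compute_enzyme_costs(dmap, remap, enzymes, {}, exempt=exempt or set())
    pool = ProteinPool(p_eff)
    augmented = augment_with_pool(split, costs, pool)
    return SMomentModel(augmented, dmap, enzymes, remap, costs, pool)


def linear_chain(costed=True):
    """EX -> P1 -> BIOMASS micro model; P1 optionally enzyme-catalyzed."""
    m = cobra.Model("micro")
    a = cobra.Metabolite("A_e", compartment="e")
    b = cobra.Metabolite("B_c", compartment="c")
    ex = cobra.Reaction("EX_A_e", lower_bound=-1000, upper_bound=1000)
    ex.add_metabolites({a: -1})
    p1 = cobra.Reaction("P1", lower_bound=0, upper_bound=1000)
    p1.add_metabolites({a: -1, b: 1})
    if costed:
        p1.gene_reaction_rule = "gP"
    bio = cobra.Reaction("BIOMASS", lower_bound=0, upper_bound=1000)
    bio.add_metabolites({b: -1})
    m.add_reactions([ex, p1, bio])
    m.objective = "BIOMASS"
    return m


@pytest.fixture()
def two_substrate_sm():
    """Two scenario-exclusive transporters + one shared conversion step.

    Costs: TA 0.01, TB 0.02, RS 0.01 g*h/mmol; P_eff 0.1 g/gDW, so
    mu = 5 /h on substrate A alone and 10/3 /h on substrate B alone.
    """
    m = cobra.Model("two_sub")
    a_e = cobra.Metabolite("A_e", compartment="e")
    b_e = cobra.Metabolite("B_e", compartment="e")
    c_c = cobra.Metabolite("C_c", compartment="c")
    d_c = cobra.Metabolite("D_c", compartment="c")
    rxns = []
    for mid, met in (("EX_A_e", a_e), ("EX_B_e", b_e)):
        r = cobra.Reaction(mid, lower_bound=-1000, upper_bound=1000)
        r.add_metabolites({met: -1})
        rxns.append(r)
    ta = cobra.Reaction("TA", lower_bound=0, upper_bound=1000)
    ta.add_metabolites({a_e: -1, c_c: 1})
    ta.gene_reaction_rule = "gTA"
    tb = cobra.Reaction("TB", lower_bound=0, upper_bound=1000)
    tb.add_metabolites({b_e: -1, c_c: 1})
    tb.gene_reaction_rule = "gTB"
    rs = cobra.Reaction("RS", lower_bound=0, upper_bound=1000)
    rs.add_metabolites({c_c: -1, d_c: 1})
    rs.gene_reaction_rule = "gRS"
    bio = cobra.Reaction("BIOMASS", lower_bound=0, upper_bound=1000)
    bio.add_metabolites({d_c: -1})
    rxns += [ta, tb, rs, bio]
    m.add_reactions(rxns)
    m.objective = "BIOMASS"
    return assemble(
        m,
        {
            "TA": [("eTA", 36.0, 3600.0)],   # cost 0.01
            "TB": [("eTB", 72.0, 3600.0)],   # cost 0.02
            "RS": [("eRS", 36.0, 3600.0)],   # cost 0.01
        },
        p_eff=0.1,
    )
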