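"""Matrix augmentation: splitting, enzyme derivation, costs, pool row,
concentration constraints."""

import cobra
import numpy as np
import pytest

from smoment import analysis
from smoment.core import (
    FORWARD,
    REVERSE,
    Enzyme,
    ProteinPool,
    augment_with_pool,
    compute_enzyme_costs,
    enzymes_from_gene_rules,
    gecko_expand,
    gpr_alternatives,
    integrate_concentrations,
    split_reversible,
    strip_pool,
)

from .conftest import assemble, linear_chain


# ---------------------------------------------------------------------------
# Reversible splitting
# ---------------------------------------------------------------------------

def _one_reaction_model(lb, ub, rule="gX"):
    m = cobra.Model("m")
    a = cobra.Metabolite("A_c", compartment="c")
    b = cobra.Metabolite("B_c", compartment="c")
    r = cobra.Reaction("R", lower_bound=lb, upper_bound=ub)
    r.add_metabolites({a: -1, b: 1})
    r.gene_reaction_rule = rule
    m.add_reactions([r])
    return m


def test_split_sign_convention():
    """alpha=-10, beta=5 becomes fwd [0,5] and rev [0,10] with negated
    stoichiometry."""
    split, dmap = split_reversible(_one_reaction_model(-10, 5))
    fwd_id, rev_id = dmap.pairs["R"]
    fwd = split.reactions.get_by_id(fwd_id)
    rev = split.reactions.get_by_id(rev_id)
    assert fwd.bounds == (0, 5)
    assert rev.bounds == (0, 10)
    assert {m.id: c for m, c in rev.metabolites.items()} == {"A_c": 1, "B_c": -1}


def test_split_leaves_irreversible_untouched():
    split, dmap = split_reversible(_one_reaction_model(0, 7))
    assert dmap.pairs["R"] == ("R", None)
    assert split.reactions.get_by_id("R").bounds == (0, 7)


def test_split_scope_enzymatic_only(toy):
    """Only reversible reactions with a gene rule are split; the reaction
    count grows by exactly the number of reversible enzymatic reactions."""
    n_rev_enz = sum(
        1 for r in toy.model.reactions if r.lower_bound < 0 and r.genes
    )
    assert n_rev_enz >= 1  # fixture guarantee
    split, _ = split_reversible(toy.model, scope="enzymatic")
    assert len(split.reactions) == len(toy.model.reactions) + n_rev_enz
    split_all, _ = split_reversible(toy.model, scope="all")
    n_rev = sum(1 for r in toy.model.reactions if r.lower_bound < 0)
    assert len(split_all.reactions) == len(toy.model.reactions) + n_rev


def test_split_preserves_flux_cone(toy):
    """Any LP optimum is unchanged by splitting: v = v_fwd - v_rev maps the
    split polytope onto the original one."""
    orig_opt = toy.model.slim_optimize()
    split, _ = split_reversible(toy.model, scope="all")
    assert split.slim_optimize() == pytest.approx(orig_opt, abs=1e-9)


# ---------------------------------------------------------------------------
# Enzymes from GPR rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rule, expected",
    [
        ("(a and b) or c", [{"a", "b"}, {"c"}]),
        ("a", [{"a"}]),
        ("", []),
        ("a and (b or c)", [{"a", "b"}, {"a", "c"}]),
    ],
)
def test_gpr_normalization_to_or_of_ands(rule, expected):
    assert [set(s) for s in gpr_alternatives(rule)] == expected


def test_enzyme_masses_from_complex_and_isozymes():
    """(a and b) or c with masses 10/20/25 gives two enzymes of MW 30, 25."""
    m = _one_reaction_model(0, 10, rule="(a and b) or c")
    enzymes, remap = enzymes_from_gene_rules(m, {"a": 10, "b": 20, "c": 25})
    assert sorted(e.MW for e in enzymes.values()) == [25, 30]
    assert remap.enzymes_of["R"] == set(enzymes)


def test_subunit_stoichiometry_scales_mass():
    """Homotetramer: one protein with count 4 and mass 10 gives MW 40."""
    m = _one_reaction_model(0, 10, rule="a")
    enzymes, _ = enzymes_from_gene_rules(m, {"a": 10}, subunit_stoich={"a": 4})
    (enz,) = enzymes.values()
    assert enz.MW == 40


def test_missing_mass_drops_enzyme_with_warning(caplog):
    m = _one_reaction_model(0, 10, rule="(a and b) or c")
    with caplog.at_level("WARNING", logger="smoment"):
        enzymes, remap = enzymes_from_gene_rules(m, {"c": 25})
    assert [e.MW for e in enzymes.values()] == [25]
    assert "dropped" in caplog.text


# ---------------------------------------------------------------------------
# Cost table
# ---------------------------------------------------------------------------

def test_minimal_cost_selection_and_zero_rule():
    """Isozymes (MW 2, kcat 4) and (MW 3, kcat 10) give cost 0.3; a
    reaction with no enzyme gets cost 0."""
    m = linear_chain(costed=True)
    split, dmap = split_reversible(m)
    from smoment.core import ReactionEnzymeMap

    enzymes = {
        "e1": Enzyme("e1", {"e1": 1}, 2.0, {("P1", FORWARD): 4.0}),
        "e2": Enzyme("e2", {"e2": 1}, 3.0, {("P1", FORWARD): 10.0}),
    }
    remap = ReactionEnzymeMap()
    remap.add("P1", "e1")
    remap.add("P1", "e2")
    costs = compute_enzyme_costs(dmap, remap, enzymes, {})
    assert costs.cost["P1"] == pytest.approx(0.3)
    assert costs.chosen["P1"] == "e2"
    assert costs.cost["EX_A_e"] == 0.0 and costs.chosen["EX_A_e"] is None


def test_cost_tie_break_is_lexicographic():
    m = linear_chain()
    split, dmap = split_reversible(m)
    from smoment.core import ReactionEnzymeMap

    enzymes = {
        "zz": Enzyme("zz", {"zz": 1}, 1.0, {("P1", FORWARD): 2.0}),
        "aa": Enzyme("aa", {"aa": 1}, 1.0, {("P1", FORWARD): 2.0}),
    }
    remap = ReactionEnzymeMap()
    remap.add("P1", "zz")
    remap.add("P1", "aa")
    costs = compute_enzyme_costs(dmap, remap, enzymes, {})
    assert costs.chosen["P1"] == "aa"


# ---------------------------------------------------------------------------
# Pool augmentation
# ---------------------------------------------------------------------------

def test_pool_caps_flux_at_peff_over_cost():
    """Single pathway with cost 0.5 and P_eff=1: max flux is exactly 2."""
    sm = assemble(linear_chain(), {"P1": [("eP", 1.0, 2.0)]}, p_eff=1.0)
    assert sm.costs.cost["P1"] == pytest.approx(0.5)
    assert sm.model.slim_optimize() == pytest.approx(2.0, abs=1e-9)


def test_augmented_dimensions_grow_by_one_row_and_column(toy):
    split, _ = split_reversible(toy.model)
    aug = toy.smoment.model
    assert len(aug.metabolites) == len(split.metabolites) + 1
    assert len(aug.reactions) == len(split.reactions) + 1


def test_pool_row_coefficients_bit_equal_to_cost_table(toy):
    sm = toy.smoment
    pool_met = sm.pool_metabolite
    for col, cost in sm.costs.cost.items():
        rxn = sm.model.reactions.get_by_id(col)
        coeff = rxn.metabolites.get(pool_met, 0.0)
        assert coeff == -cost  # exact, not approx


def test_cost_zero_column_bounded_only_by_beta():
    sm = assemble(linear_chain(costed=False), {}, p_eff=1.0)
    assert sm.model.slim_optimize() == pytest.approx(1000.0)


def test_augment_refuses_unsplit_costed_reversible():
    m = _one_reaction_model(-10, 10, rule="gX")
    split, dmap = split_reversible(m, scope="enzymatic")
    # fabricate a cost on a still-reversible column
    from smoment.core import EnzymeCostTable

    costs = EnzymeCostTable(cost={"R": 0.5}, chosen={"R": "e"}, kcat={"R": 2.0})
    with pytest.raises(ValueError, match="split"):
        augment_with_pool(m, costs, ProteinPool(1.0))


def test_pool_monotonicity_and_relaxation(toy):
    """Raising P_eff never decreases the optimum; a huge pool reproduces
    the unconstrained model's optimum exactly."""
    sm = toy.smoment.copy()
    last = -np.inf
    for p in (0.01, 0.05, 0.1, 1.0, 10.0):
        sm.set_pool_bound(p)
        mu = sm.model.slim_optimize()
        assert mu >= last - 1e-9
        last = mu
    sm.set_pool_bound(1e6)
    unconstrained = strip_pool(sm).slim_optimize()
    assert sm.model.slim_optimize() == pytest.approx(unconstrained, abs=1e-6)


# ---------------------------------------------------------------------------
# Concentration integration / GECKO expansion
# ---------------------------------------------------------------------------

def test_sole_catalyst_concentration_caps_flux():
    """v <= kcat * [E]: kcat 10/h and [E]=0.5 mmol/gDW cap the flux at 5."""
    sm = assemble(linear_chain(), {"P1": [("eP", 0.001, 10.0)]}, p_eff=1000.0)
    con = integrate_concentrations(sm, {"eP": 0.5})
    assert con.model.slim_optimize() == pytest.approx(5.0, abs=1e-9)


def test_shared_reaction_is_split_into_two_copies():
    sm = assemble(
        linear_chain(),
        {"P1": [("eA", 1.0, 2.0), ("eB", 2.0, 2.0)]},
        p_eff=1.0,
    )
    n_before = len(sm.model.reactions)
    con = integrate_concentrations(sm, {"eA": 100.0})
    new = {r.id for r in con.model.reactions} - {r.id for r in sm.model.reactions}
    assert f"P1_enz_eA" in new           # exclusive copy
    assert "R_enz_eA" in new             # concentration delivery
    assert len(con.model.reactions) == n_before + 2


def test_nonlimiting_concentrations_keep_flux_space(toy):
    """With very large concentrations for every enzyme the feasible space
    is unchanged: FVA ranges match the plain pool model."""
    sm = toy.smoment
    expanded = gecko_expand(sm)
    shared = [r.id for r in sm.model.reactions]
    fva_a = analysis.flux_variability(sm.model, reactions=shared)
    fva_b = analysis.flux_variability(expanded.model, reactions=shared)
    assert np.allclose(
        fva_a.table[["minimum", "maximum"]].loc[shared],
        fva_b.table[["minimum", "maximum"]].loc[shared],
        atol=1e-6,
    )


def test_gecko_expansion_counts_and_optimum(toy):
    """Full expansion adds one pseudo-metabolite/pseudo-reaction pair per
    enzyme (plus reaction copies for shared columns) and leaves any LP
    optimum unchanged."""
    sm = toy.smoment
    expanded = gecko_expand(sm)
    used_enzymes = {
        e
        for col, orig, _ in sm.direction_map.columns()
        if sm.costs.cost.get(col, 0.0) > 0
        for e in sm.rxn_enz_map.enzymes_of[orig]
    }
    delivery = [r.id for r in expanded.model.reactions if r.id.startswith("R_enz_")]
    assert len(delivery) == len(used_enzymes)
    assert expanded.model.slim_optimize() == pytest.approx(
        sm.model.slim_optimize(), abs=1e-8
    )


def test_concentration_errors():
    sm = assemble(linear_chain(), {"P1": [("eP", 1.0, 2.0)]}, p_eff=1.0)
    with pytest.raises(KeyError):
        integrate_concentrations(sm, {"ghost": 1.0})
    with pytest.raises(ValueError):
        integrate_concentrations(sm, {"eP": -1.0})


def test_concentration_constraints_only_shrink_fva(toy):
    sm = toy.smoment
    con = integrate_concentrations(sm, {sorted(sm.enzymes)[0]: 1e-4})
    shared = [r.id for r in sm.model.reactions]
    before = analysis.flux_variability(sm.model, reactions=shared).table
    after = analysis.flux_variability(con.model, reactions=shared).table
    assert (after["maximum"] <= before["maximum"] + 1e-6).all()
    assert (after["minimum"] >= before["minimum"] - 1e-6).all()
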