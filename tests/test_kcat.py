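"""Turnover-number selection: substrate/organism filters, taxonomy
relaxation, means, medians, defaults."""

import statistics

import pytest
from hypothesis import given, settings, strategies as st

from smoment.core import FORWARD, REVERSE, split_reversible, enzymes_from_gene_rules
from smoment.kcat import (
    CustomKcatDatabase,
    CustomKcatEntry,
    KcatDatabase,
    TaxonomyMap,
    assign_all,
    collect_candidates,
    ec_matches,
    select_kcat,
    taxonomic_distance,
)
from smoment.fixtures import default_taxonomy, DEFAULT_ORGANISM, SISTER_ORGANISM


TAX = TaxonomyMap({
    "a": ["x", "p", "r"],
    "b": ["y", "p", "r"],
    "c": ["c1", "c2", "r"],
})


# ---------------------------------------------------------------------------
# Taxonomic distance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("a", "a", 0),          # identity
        ("a", "b", 1),          # sister clades joining at p
        ("a", "c", 2),          # join only at the root
        ("a", "unknown", 3),    # unknown taxon: full lineage length
    ],
)
def test_taxonomic_distance(a, b, expected):
    assert taxonomic_distance(a, b, TAX) == expected


def test_distance_is_symmetric_for_balanced_lineages():
    assert taxonomic_distance("a", "b", TAX) == taxonomic_distance("b", "a", TAX)


# ---------------------------------------------------------------------------
# Candidate collection
# ---------------------------------------------------------------------------

def _db(entries):
    db = KcatDatabase()
    for ec, val, subs, org in entries:
        db.add(ec, val, subs, org)
    return db


def test_no_relaxation_when_enough_local_values():
    """12 same-organism substrate-matching entries: exactly those 12."""
    db = _db([("1.1.1.1", float(i + 1), ["glc__D"], "a") for i in range(12)]
             + [("1.1.1.1", 99.0, ["glc__D"], "b")] * 5)
    vals = collect_candidates(["1.1.1.1"], ["glc__D"], "a", db, TAX)
    assert sorted(vals) == [float(i + 1) for i in range(12)]


def test_taxonomy_relaxed_until_min_count():
    """4 same-organism + 8 sister entries with min_count 10: all 12 used."""
    db = _db([("1.1.1.1", 1.0, ["glc__D"], "a")] * 4
             + [("1.1.1.1", 2.0, ["glc__D"], "b")] * 8
             + [("1.1.1.1", 50.0, ["glc__D"], "c")] * 3)
    vals = collect_candidates(["1.1.1.1"], ["glc__D"], "a", db, TAX, min_count=10)
    assert sorted(vals) == [1.0] * 4 + [2.0] * 8  # distance-2 entries untouched


def test_relaxation_is_monotone():
    """The candidate set can only grow as min_count rises."""
    db = _db([("1.1.1.1", 1.0, ["s"], "a")] * 2
             + [("1.1.1.1", 2.0, ["s"], "b")] * 2
             + [("1.1.1.1", 3.0, ["s"], "c")] * 2)
    prev: list = []
    for mc in (1, 3, 5, 10):
        vals = sorted(collect_candidates(["1.1.1.1"], ["s"], "a", db, TAX,
                                         min_count=mc))
        assert all(v in vals for v in prev)
        prev = vals


def test_substrate_filter_dropped_only_when_empty():
    db = _db([("1.1.1.1", 5.0, ["other"], "a")] * 3)
    vals = collect_candidates(["1.1.1.1"], ["glc__D"], "a", db, TAX)
    assert vals == [5.0] * 3  # no substrate match at any distance: filter off
    assert collect_candidates(["9.9.9.9"], ["glc__D"], "a", db, TAX) == []


def test_ec_wildcards_match_by_prefix():
    assert ec_matches("1.1.1.-", "1.1.1.42")
    assert ec_matches("1.1.1", "1.1.1.42")
    assert not ec_matches("1.1.2.-", "1.1.1.42")


# ---------------------------------------------------------------------------
# Value selection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "candidates, custom, expected",
    [
        ([2.0, 4.0], [], 3.0 * 3600),
        ([5.0], [], 5.0 * 3600),
        ([], [], None),
        ([2.0], [4.0], 3.0 * 3600),  # custom values pooled into the mean
    ],
)
def test_mean_selection_and_unit_conversion(candidates, custom, expected):
    assert select_kcat(candidates, custom) == expected


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    vals=st.lists(st.floats(0.01, 1e4), min_size=1, max_size=8),
    lam=st.floats(0.1, 10.0),
)
def test_selection_scale_equivariance(vals, lam):
    """Scaling every database value by lambda scales the selection by
    lambda."""
    base = select_kcat(vals)
    scaled = select_kcat([v * lam for v in vals])
    assert scaled == pytest.approx(base * lam, rel=1e-12)


# ---------------------------------------------------------------------------
# Whole-model assignment
# ---------------------------------------------------------------------------

def _assignment(toy, db=None, custom=None):
    split, dmap = split_reversible(toy.model)
    enzymes, remap = enzymes_from_gene_rules(
        toy.model, toy.mw_table, toy.subunit_stoich
    )
    return assign_all(
        toy.model, dmap, remap, enzymes,
        db if db is not None else toy.kcat_db,
        toy.taxonomy, toy.organism, custom_db=custom,
    )


def test_assignment_recovers_true_values_despite_decoys(toy):
    """Same-organism substrate-matching entries outvote the 7x sister-taxon
    decoys, so every direction recovers its generating value."""
    asg = _assignment(toy)
    for key, true_k in toy.true_kcats_h.items():
        assert asg.value_by_direction[key] == pytest.approx(true_k, rel=1e-9)


def test_uncovered_reaction_gets_median_default(toy):
    """Dropping one reaction's EC from the database sends it to the default,
    the median of everything that was assigned directly."""
    db = KcatDatabase()
    dropped_ec = toy.model.reactions.get_by_id("R1").annotation["ec-code"]
    for ec, entries in toy.kcat_db.entries.items():
        if ec == dropped_ec:
            continue
        for e in entries:
            db.add(ec, e.value_per_s, e.substrates, e.organism)
    asg = _assignment(toy, db=db)
    direct = [v for k, v in asg.value_by_direction.items()
              if asg.provenance[k] not in ("default", "mirrored")]
    for d in ("fwd",):
        key = ("R1", d)
        assert asg.provenance[key] == "default"
        assert asg.value_by_direction[key] == pytest.approx(
            statistics.median(direct)
        )
    assert asg.default_value == pytest.approx(statistics.median(direct))


def test_one_sided_data_is_mirrored(toy):
    """A reversible reaction whose database only covers the forward
    substrates reuses the forward value for the reverse direction."""
    rev_rxn = next(r.id for r in toy.model.reactions
                   if r.lower_bound < 0 and r.genes)
    ec_rev = toy.model.reactions.get_by_id(rev_rxn).annotation["ec-code"]
    db = KcatDatabase()
    fwd_subs = {
        m.id.rsplit("_", 1)[0]
        for m, c in toy.model.reactions.get_by_id(rev_rxn).metabolites.items()
        if c < 0
    }
    for ec, entries in toy.kcat_db.entries.items():
        for e in entries:
            if ec == ec_rev and not (e.substrates & fwd_subs):
                continue  # strip the reverse-direction evidence
            db.add(ec, e.value_per_s, e.substrates, e.organism)
    asg = _assignment(toy, db=db)
    assert asg.provenance[(rev_rxn, REVERSE)] == "mirrored"
    assert asg.value_by_direction[(rev_rxn, REVERSE)] == asg.value_by_direction[
        (rev_rxn, FORWARD)
    ]


def test_custom_overrides_are_pooled(toy):
    """A custom per-enzyme value shifts that reaction's mean and only
    that reaction's."""
    split, dmap = split_reversible(toy.model)
    enzymes, remap = enzymes_from_gene_rules(toy.model, toy.mw_table,
                                             toy.subunit_stoich)
    eid = sorted(remap.enzymes_of["T_UP"])[0]
    base = _assignment(toy)
    custom = CustomKcatDatabase([CustomKcatEntry(eid, 1000.0, "T_UP")])
    asg = _assignment(toy, custom=custom)
    n = toy.spec.db_entries_per_direction
    true_s = toy.true_kcats_h[("T_UP", FORWARD)] / 3600.0
    expected = (n * true_s + 1000.0) / (n + 1) * 3600.0
    assert asg.value_by_direction[("T_UP", FORWARD)] == pytest.approx(expected)
    for key in base.value_by_direction:
        if key[0] != "T_UP":
            assert asg.value_by_direction[key] == base.value_by_direction[key]


def test_assignment_is_deterministic(toy):
    a = _assignment(toy)
    b = _assignment(toy)
    assert a.value_by_direction == b.value_by_direction
    assert a.provenance == b.provenance


def test_assignment_scale_equivariance(toy):
    lam = 2.5
    scaled = KcatDatabase()
    for ec, entries in toy.kcat_db.entries.items():
        for e in entries:
            scaled.add(ec, e.value_per_s * lam, e.substrates, e.organism)
    a = _assignment(toy)
    b = _assignment(toy, db=scaled)
    for key, v in a.value_by_direction.items():
        assert b.value_by_direction[key] == pytest.approx(v * lam, rel=1e-9)
    assert b.default_value == pytest.approx(a.default_value * lam, rel=1e-9)


def test_no_kinetic_information_raises(toy):
    stripped = toy.model.copy()
    for rxn in stripped.reactions:
        rxn.annotation.pop("ec-code", None)
    split, dmap = split_reversible(stripped)
    enzymes, remap = enzymes_from_gene_rules(stripped, toy.mw_table,
                                             toy.subunit_stoich)
    with pytest.raises(ValueError, match="no kinetic information"):
        assign_all(stripped, dmap, remap, enzymes, toy.kcat_db,
                   toy.taxonomy, toy.organism)


def test_fixture_taxonomy_resolves_congeners():
    tax = default_taxonomy()
    assert taxonomic_distance(DEFAULT_ORGANISM, DEFAULT_ORGANISM, tax) == 0
    assert taxonomic_distance(DEFAULT_ORGANISM, SISTER_ORGANISM, tax) == 1
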