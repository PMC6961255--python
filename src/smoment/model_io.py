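"""SBML input/output for constraint-based models.

Models are held in memory as :class:`cobra.Model` objects — the field's
standard container for a stoichiometric matrix with flux bounds, gene-protein-
reaction (GPR) rules and MIRIAM-style annotations.  This module wraps reading
and writing (SBML Level 3 with the fbc package) and exposes the handful of
accessors the enzyme-constraint pipeline needs: EC numbers, namespace
metabolite identifiers, reversibility, and the sparse stoichiometric matrix.

Identifiers are never rewritten; downstream code only appends documented
suffixes (``_fwd``/``_rev`` for split reversibles, ``_enz_<id>`` for
concentration splits).
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional

import cobra
from cobra.util.array import create_stoichiometric_matrix
from scipy import sparse

logger = logging.getLogger("smoment")

#: Conventional "infinite" flux bound of genome-scale models (mmol/gDW/h).
#: Preserved verbatim on read/write; also the "practically unbounded"
#: threshold in flux-variability summaries.
ARTIFICIAL_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


def read_model(path: str) -> cobra.Model:
    """Read an SBML model, including bounds, GPR rules and annotations.

    Reaction and metabolite order follow document order, so two reads of the
    same file yield identical orderings.  Models lacking any gene association
    load fine; their reactions are simply treated as enzyme-free downstream
    (a warning is logged).

    Raises
    ------
    CobraSBMLError
        If the file is not well-formed SBML (the error names the offending
        element).
    """
    model = cobra.io.read_sbml_model(path)
    if not any(r.genes for r in model.reactions):
        logger.warning(
            "model %s has no gene associations; all reactions will be "
            "treated as enzyme-free",
            model.id or path,
        )
    return model


def write_model(model: cobra.Model, path: str) -> None:
    """Write a model to SBML L3/fbc.

    Pool pseudo-species and pseudo-reactions are ordinary species/reactions
    in the serialization, so ``read_model(write_model(m))`` reproduces every
    field the pipeline uses (stoichiometry, bounds, GPR, annotations).
    """
    cobra.io.write_sbml_model(model, path)


def validate(model: cobra.Model) -> None:
    """Check structural invariants; raise :class:`ModelValidationError`.

    Checked: every stoichiometry entry references a declared metabolite
    (cobra guarantees this at construction, re-verified here), and
    ``lb <= ub`` for every reaction.
    """
    declared = set(model.metabolites)
    for rxn in model.reactions:
        for met in rxn.metabolites:
            if met not in declared:
                raise ModelValidationError(
                    f"reaction {rxn.id} references undeclared metabolite {met.id}"
                )
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )


def is_reversible(rxn: cobra.Reaction) -> bool:
    """A reaction is reversible iff its lower bound is negative."""
    return rxn.lower_bound < 0


def ec_numbers(rxn: cobra.Reaction) -> List[str]:
    """EC numbers of a reaction from its ``ec-code`` annotation."""
    raw = rxn.annotation.get("ec-code", [])
    if isinstance(raw, str):
        raw = [raw]
    return list(raw)


def namespace_id(met: cobra.Metabolite) -> str:
    """Namespace (BiGG-style) id of a metabolite, compartment tag stripped.

    Prefers an explicit ``bigg.metabolite`` annotation; otherwise strips a
    trailing ``_<compartment>`` from the metabolite id.
    """
    ann = met.annotation.get("bigg.metabolite")
    if ann:
        return ann if isinstance(ann, str) else ann[0]
    mid = met.id
    if met.compartment and mid.endswith(f"_{met.compartment}"):
        return mid[: -(len(met.compartment) + 1)]
    return mid


def is_exchange(rxn: cobra.Reaction) -> bool:
    """True for boundary (single-metabolite) exchange/demand reactions."""
    return len(rxn.metabolites) == 1


def find_biomass(model: cobra.Model) -> Optional[cobra.Reaction]:
    """The model's biomass reaction: the current objective if it is a single
    reaction, else the first reaction whose id contains 'biomass'."""
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(model)
        if len(coeffs) == 1:
            return next(iter(coeffs))
    except Exception:  # pragma: no cover - solver-less models
        pass
    for rxn in model.reactions:
        if "biomass" in rxn.id.lower():
            return rxn
    return None


def stoichiometric_matrix(model: cobra.Model) -> sparse.csr_matrix:
    """Sparse stoichiometric matrix S (rows = metabolites in model order,
    columns = reactions in model order)."""
    return sparse.csr_matrix(create_stoichiometric_matrix(model, array_type="dense"))


def organism_of(model: cobra.Model, default: str = "") -> str:
    """Taxon name recorded in the model's annotation, if any."""
    for key in ("taxonomy", "organism"):
        val = model.annotation.get(key)
        if val:
            return val if isinstance(val, str) else val[0]
    return default


def set_organism(model: cobra.Model, taxon: str) -> None:
    model.annotation["taxonomy"] = taxon
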