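"""Automated kcat (turnover number) assignment from local kinetic databases.

Every enzyme-catalyzed reaction direction needs a kcat for its pool-row
coefficient MW/kcat.  Values are drawn from an EC-number-keyed database
(a local snapshot of the kind of records SABIO-RK/BRENDA hold: value,
substrates, source organism) plus an optional custom per-enzyme override
table.  Selection prefers entries measured with the reaction's own
substrates and in the model's organism; when fewer than ``min_count``
such values exist, the taxonomic-distance constraint is relaxed one
lineage level at a time (nearest species first), and the substrate filter
is dropped only if no substrate-matching entry exists at any distance.
The arithmetic mean of the collected values is used.  Directions with no
data mirror their opposite direction where possible; everything still
unassigned receives the median of all assigned values as default.

Databases are plain JSON/TSV files so the whole procedure is reproducible
offline; no network access is involved anywhere.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import cobra

from .core import DirectionMap, Enzyme, ReactionEnzymeMap, FORWARD, REVERSE
from .model_io import ec_numbers, namespace_id

logger = logging.getLogger("smoment")

PER_SECOND_TO_PER_HOUR = 3600.0

_EC_FIELD = re.compile(r"^(\d+|-|\*)$")


def _check_ec(ec: str) -> None:
    fields = ec.split(".")
    if len(fields) != 4 or not all(_EC_FIELD.match(f) for f in fields):
        raise ValueError(f"invalid EC number {ec!r}")


def ec_matches(query: str, entry: str) -> bool:
    """Field-wise EC comparison; '-'/'*' wildcards and missing trailing
    fields match anything (prefix semantics)."""
    q = query.split(".")
    e = entry.split(".")
    for qf, ef in zip(q, e):
        if qf in ("-", "*") or ef in ("-", "*"):
            continue
        if qf != ef:
            return False
    return True


# ---------------------------------------------------------------------------
# Databases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KcatEntry:
    value_per_s: float
    substrates: frozenset
    organism: str
    source: str = "primary"

    def __post_init__(self) -> None:
        if self.value_per_s <= 0:
            raise ValueError("kcat entries must be positive")


@dataclass
class KcatDatabase:
    """EC-number-keyed kinetic entries (versioned JSON snapshot format)."""

    entries: Dict[str, List[KcatEntry]] = field(default_factory=dict)
    version: str = "1"

    def __post_init__(self) -> None:
        for ec in self.entries:
            _check_ec(ec)

    def add(self, ec: str, value_per_s: float, substrates: Iterable[str],
            organism: str, source: str = "primary") -> None:
        _check_ec(ec)
        self.entries.setdefault(ec, []).append(
            KcatEntry(value_per_s, frozenset(substrates), organism, source)
        )

    def lookup(self, ecs: Sequence[str]) -> List[KcatEntry]:
        """All entries whose EC number matches any of the queried ECs,
        in deterministic (EC, insertion) order."""
        out: List[KcatEntry] = []
        seen: Set[int] = set()
        for ec_db in sorted(self.entries):
            if any(ec_matches(q, ec_db) for q in ecs):
                for entry in self.entries[ec_db]:
                    if id(entry) not in seen:
                        seen.add(id(entry))
                        out.append(entry)
        return out

    # -- serialization -------------------------------------------------
    def to_json(self, path: str) -> None:
        doc = {
            "format": "smoment-kcat-db",
            "version": self.version,
            "entries": {
                ec: [
                    {
                        "value_per_s": e.value_per_s,
                        "substrates": sorted(e.substrates),
                        "organism": e.organism,
                        "source": e.source,
                    }
                    for e in entries
                ]
                for ec, entries in self.entries.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "KcatDatabase":
        with open(path) as fh:
            doc = json.load(fh)
        entries = doc.get("entries", doc)  # tolerate bare {EC: [...]} form
        db = cls(version=str(doc.get("version", "1")))
        for ec, recs in entries.items():
            for rec in recs:
                db.add(ec, rec["value_per_s"], rec.get("substrates", []),
                       rec.get("organism", ""), rec.get("source", "primary"))
        return db

    @classmethod
    def from_tsv(cls, path: str) -> "KcatDatabase":
        """Converter from tabular form: columns
        ec, value_per_s, substrates (';'-separated), organism[, source]."""
        db = cls()
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                subs = [s for s in row.get("substrates", "").split(";") if s]
                db.add(row["ec"], float(row["value_per_s"]), subs,
                       row.get("organism", ""), row.get("source", "primary"))
        return db


@dataclass
class TaxonomyMap:
    """Taxon name -> ordered ancestor lineage (nearest first, root last)."""

    lineage: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = {lin[-1] for lin in self.lineage.values() if lin}
        if any(not lin for lin in self.lineage.values()) or len(roots) > 1:
            raise ValueError("every lineage must be non-empty and share one root")

    @property
    def max_distance(self) -> int:
        return max((len(l) for l in self.lineage.values()), default=1)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.lineage, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "TaxonomyMap":
        with open(path) as fh:
            return cls(json.load(fh))


@dataclass(frozen=True)
class CustomKcatEntry:
    enzyme_id: str
    value_per_s: float
    reaction_id: Optional[str] = None  # None: applies to all its reactions


@dataclass
class CustomKcatDatabase:
    """User-supplied per-enzyme kcat overrides, pooled with database hits."""

    entries: List[CustomKcatEntry] = field(default_factory=list)

    def values_for(self, enzyme_ids: Iterable[str], rxn_id: str) -> List[float]:
        out = []
        eids = set(enzyme_ids)
        for e in self.entries:
            if e.enzyme_id in eids and e.reaction_id in (None, rxn_id):
                out.append(e.value_per_s)
        return out

    @classmethod
    def from_tsv(cls, path: str) -> "CustomKcatDatabase":
        """Columns: enzyme_id, value_per_s[, reaction_id]."""
        db = cls()
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                rid = row.get("reaction_id") or None
                db.entries.append(
                    CustomKcatEntry(row["enzyme_id"], float(row["value_per_s"]), rid)
                )
        return db


# ---------------------------------------------------------------------------
# Selection algorithm
# ---------------------------------------------------------------------------

def taxonomic_distance(a: str, b: str, tax: TaxonomyMap) -> int:
    """Lineage steps from ``a`` up to the lowest common ancestor of ``a``
    and ``b``; 0 iff the taxa are identical.  Unknown taxa are treated as
    maximally distant (the full lineage length) and logged."""
    if a == b:
        return 0
    la = tax.lineage.get(a)
    lb = tax.lineage.get(b)
    if la is None and lb is None:
        logger.warning("taxa %r and %r unknown; treated as maximally distant", a, b)
        return tax.max_distance
    if la is None:
        logger.warning("taxon %r unknown; treated as maximally distant", a)
        return len(lb)  # type: ignore[arg-type]
    if lb is None:
        logger.warning("taxon %r unknown; treated as maximally distant", b)
        return len(la)
    b_side = {b} | set(lb)
    for i, ancestor in enumerate(la):
        if ancestor in b_side:
            return i
    return len(la)


def collect_candidates(
    ec_numbers: Sequence[str],
    substrates: Iterable[str],
    organism: str,
    db: KcatDatabase,
    tax: TaxonomyMap,
    min_count: int = 10,
) -> List[float]:
    """Collect candidate kcat values (1/s) for one reaction direction.

    Entries matching any queried EC number are filtered to those measured
    with at least one of the direction's substrates; within the matches the
    taxonomically nearest entries are taken, relaxing the distance one
    level at a time while fewer than ``min_count`` values are collected.
    If no entry matches the substrates at any distance, the substrate
    filter is dropped and the organism procedure repeats over all entries.
    Returns an empty list when the database has nothing for these ECs.
    """
    values, _info = _collect_with_info(
        ec_numbers, substrates, organism, db, tax, min_count
    )
    return values


def _collect_with_info(
    ec_numbers: Sequence[str],
    substrates: Iterable[str],
    organism: str,
    db: KcatDatabase,
    tax: TaxonomyMap,
    min_count: int,
) -> Tuple[List[float], str]:
    if not ec_numbers:
        return [], "no-ec"
    entries = db.lookup(ec_numbers)
    if not entries:
        return [], "no-entry"
    subs = set(substrates)
    matching = [e for e in entries if e.substrates & subs]
    substrate_matched = bool(matching)
    pool = matching if matching else entries
    by_distance: Dict[int, List[float]] = {}
    for e in pool:
        d = taxonomic_distance(organism, e.organism, tax)
        by_distance.setdefault(d, []).append(e.value_per_s)
    out: List[float] = []
    used = 0
    for d in sorted(by_distance):
        if out and len(out) >= min_count:
            break
        out.extend(by_distance[d])
        used = d
    rule = "substrate" if substrate_matched else "any-substrate"
    return out, f"{rule},taxonomic-distance<={used}"


#: Sentinel returned by :func:`select_kcat` when nothing was collected.
USE_DEFAULT = None


def select_kcat(
    candidates: Sequence[float],
    custom_values: Sequence[float] = (),
) -> Optional[float]:
    """Arithmetic mean of the pooled candidate and custom values, converted
    from 1/s to 1/h; ``None`` (use-default sentinel) when both are empty."""
    pooled = list(candidates) + list(custom_values)
    if not pooled:
        return USE_DEFAULT
    return (sum(pooled) / len(pooled)) * PER_SECOND_TO_PER_HOUR


# ---------------------------------------------------------------------------
# Whole-model assignment
# ---------------------------------------------------------------------------

@dataclass
class KcatAssignment:
    """kcat per reaction direction (1/h) with selection provenance."""

    value_by_direction: Dict[Tuple[str, str], float] = field(default_factory=dict)
    provenance: Dict[Tuple[str, str], str] = field(default_factory=dict)
    default_value: Optional[float] = None


def _direction_substrates(rxn: cobra.Reaction, direction: str) -> Set[str]:
    """Namespace ids (compartment-stripped) of the metabolites consumed in
    the given direction."""
    sign = -1 if direction == FORWARD else 1
    return {
        namespace_id(m)
        for m, coeff in rxn.metabolites.items()
        if coeff * sign > 0  # consumed: negative coeff fwd, positive rev
    }


def assign_all(
    model: cobra.Model,
    dmap: DirectionMap,
    rxn_enz_map: ReactionEnzymeMap,
    enzymes: Mapping[str, Enzyme],
    db: KcatDatabase,
    tax: TaxonomyMap,
    organism: str,
    custom_db: Optional[CustomKcatDatabase] = None,
    min_count: int = 10,
) -> KcatAssignment:
    """Assign a kcat to every enzyme-catalyzed reaction direction.

    Selection per direction: database candidates (substrate/organism/
    taxonomy procedure of :func:`collect_candidates`) pooled with custom
    per-enzyme values, arithmetic mean.  A direction with no data mirrors
    its opposite direction's value; whatever remains gets the default —
    the median of all directly assigned values, computed after every
    selection has been made.  Deterministic: reactions are visited in
    model order, directions forward first.
    """
    asg = KcatAssignment()
    weak: List[Tuple[Tuple[str, str], float, str]] = []  # substrate-filter dropped
    pending: List[Tuple[str, str]] = []
    any_ec = False
    for rxn in model.reactions:
        eids = sorted(rxn_enz_map.enzymes_of.get(rxn.id, set()))
        if not eids:
            continue
        ecs = ec_numbers(rxn)
        if ecs:
            any_ec = True
        custom = (
            custom_db.values_for(eids, rxn.id) if custom_db is not None else []
        )
        for direction in dmap.directions_of(rxn.id):
            substrates = _direction_substrates(rxn, direction)
            candidates, rule = _collect_with_info(
                ecs, substrates, organism, db, tax, min_count
            )
            value = select_kcat(candidates, custom)
            key = (rxn.id, direction)
            if value is USE_DEFAULT:
                pending.append(key)
            elif custom and not candidates:
                asg.value_by_direction[key] = value
                asg.provenance[key] = "custom"
            elif custom:
                asg.value_by_direction[key] = value
                asg.provenance[key] = f"{rule}+custom"
            elif rule.startswith("any-substrate"):
                # substrate filter had to be dropped; the opposite
                # direction's substrate-matched value, if any, is the
                # better evidence — decide after the first pass
                weak.append((key, value, rule))
            else:
                asg.value_by_direction[key] = value
                asg.provenance[key] = rule
    # directions with no substrate match mirror a substrate-matched
    # opposite direction; otherwise their fallback selection stands
    for key, value, rule in weak:
        rxn_id, direction = key
        other = (rxn_id, REVERSE if direction == FORWARD else FORWARD)
        if other in asg.value_by_direction and not asg.provenance[other].startswith(
            "any-substrate"
        ):
            asg.value_by_direction[key] = asg.value_by_direction[other]
            asg.provenance[key] = "mirrored"
            logger.info("kcat for %s (%s) mirrored from opposite direction",
                        rxn_id, direction)
        else:
            asg.value_by_direction[key] = value
            asg.provenance[key] = rule
    # directions with nothing at all also mirror before taking the default
    still_pending: List[Tuple[str, str]] = []
    for rxn_id, direction in pending:
        other = (rxn_id, REVERSE if direction == FORWARD else FORWARD)
        if other in asg.value_by_direction:
            asg.value_by_direction[(rxn_id, direction)] = asg.value_by_direction[other]
            asg.provenance[(rxn_id, direction)] = "mirrored"
            logger.info("kcat for %s (%s) mirrored from opposite direction",
                        rxn_id, direction)
        else:
            still_pending.append((rxn_id, direction))
    direct = [
        v for k, v in asg.value_by_direction.items()
        if asg.provenance[k] not in ("mirrored",)
    ]
    if direct:
        asg.default_value = statistics.median(direct)
    elif not any_ec and not (custom_db and custom_db.entries):
        raise ValueError(
            "no kinetic information: model has no EC annotations and no "
            "custom kcat values were provided"
        )
    for key in still_pending:
        if asg.default_value is None:
            raise ValueError(
                "no kinetic information: no kcat value could be assigned to "
                "any reaction, so no default median exists"
            )
        asg.value_by_direction[key] = asg.default_value
        asg.provenance[key] = "default"
    return asg
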