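"""Inverting a key into a taxon × character constraint matrix.

Walking the unique root-to-terminal path of each occurrence and
intersecting all predicates per character yields the occurrence-level
constraint row: the set of states (or union of intervals) a specimen must
show to key out there.  Taxon-level rows then union the rows of a taxon's
occurrences character by character; when two occurrences admit disjoint
values for the same character the taxon is polymorphic for it.

Two deliberate semantics:

* A lead's coding covers only its own statement — the complement of the
  sibling lead is never inferred, because alternate leads are worded
  independently and are not guaranteed logical complements.
* A character never mentioned on any path of a taxon is *unconstrained*
  (absent from the row), not defaulted.
* The taxon-level union for a character runs over the occurrences that
  mention it: an occurrence silent about a character does not widen the
  constraint contributed by the occurrences that do constrain it.

Clauses whose alternatives span several characters ("and/or" contrasts)
cannot be folded into a single-character set; they are kept verbatim as
*residual clauses* of the row and participate in compatibility checks.
"""

from __future__ import annotations

import csv
import io as _io
import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .model import (
    Character,
    Clause,
    FULL_QUANTITATIVE,
    Interval,
    IntervalUnion,
    Key,
    KeyError_,
    Observation,
    TaxonOccurrence,
)
from . import keyio

# --- constraints -----------------------------------------------------------


@dataclass
class Constraint:
    """Allowed values of one character for one taxon/occurrence.

    Exactly one of ``states`` / ``interval`` is set, matching the
    character's kind.  ``provenance`` lists the (couplet, slot) leads that
    contributed; ``polymorphic`` marks taxon-level unions of disjoint
    occurrence constraints; ``contradictory`` marks an empty intersection
    (reported, never dropped).
    """

    char_id: str
    states: Optional[frozenset] = None
    interval: Optional[IntervalUnion] = None
    provenance: tuple[tuple[int, str], ...] = ()
    polymorphic: bool = False
    contradictory: bool = False

    def is_empty(self) -> bool:
        if self.states is not None:
            return not self.states
        return self.interval.is_empty()

    def allows(self, value: Union[str, float]) -> bool:
        if self.states is not None:
            return value in self.states
        return self.interval.contains(float(value))

    def render(self) -> str:
        if self.contradictory:
            return "CONTRADICTION"
        if self.states is not None:
            return "{" + ",".join(sorted(self.states)) + "}"
        return "|".join(str(iv) for iv in self.interval.parts)

    def clone(self) -> "Constraint":
        return Constraint(char_id=self.char_id, states=self.states,
                          interval=self.interval, provenance=self.provenance,
                          polymorphic=self.polymorphic,
                          contradictory=self.contradictory)


@dataclass
class ConstraintRow:
    """One matrix row: a taxon (or occurrence) and its constraints."""

    label: str
    constraints: dict[str, Constraint] = field(default_factory=dict)
    #: clauses spanning several characters, with the contributing lead
    residual_clauses: list[tuple[Clause, tuple[int, str]]] = field(
        default_factory=list)
    occurrences: tuple[TaxonOccurrence, ...] = ()

    def constraint(self, char_id: str) -> Optional[Constraint]:
        return self.constraints.get(char_id)


@dataclass
class InducedMatrix:
    """The full inverted key at one level (``occurrence`` or ``taxon``)."""

    level: str
    characters: dict[str, Character]
    rows: dict[str, ConstraintRow]
    contradictions: list[tuple[str, str]] = field(default_factory=list)
    occurrence_matrix: Optional["InducedMatrix"] = None

    def row(self, label: str) -> ConstraintRow:
        try:
            return self.rows[label]
        except KeyError:
            raise KeyError_(f"unknown taxon {label!r} in matrix") from None


# --- induction -------------------------------------------------------------


def _full_allowed(char: Character):
    if char.is_quantitative:
        return FULL_QUANTITATIVE
    return frozenset(char.state_list)


def _clause_single_char(clause: Clause) -> Optional[str]:
    ids = set(clause.char_ids)
    return ids.pop() if len(ids) == 1 else None


def induce_matrix(key: Key, level: str = "taxon") -> InducedMatrix:
    """Invert the key by path propagation (see module docstring)."""
    if level not in ("occurrence", "taxon"):
        raise ValueError(f"level must be 'occurrence' or 'taxon', got {level!r}")
    key.require_valid()

    occ_matrix = InducedMatrix(level="occurrence", characters=key.characters,
                               rows={})

    def build(cid: int, acc: ConstraintRow) -> None:
        for lead in key.couplets[cid].leads:
            row = ConstraintRow(label="",
                                constraints={cid: con.clone() for cid, con
                                             in acc.constraints.items()},
                                residual_clauses=list(acc.residual_clauses))
            _apply_lead(key, row, lead)
            if lead.is_terminal:
                occ = lead.target_taxon
                row.label = occ.label
                row.occurrences = (occ,)
                occ_matrix.rows[row.label] = row
                for char_id, con in row.constraints.items():
                    if con.contradictory:
                        occ_matrix.contradictions.append((row.label, char_id))
            else:
                build(lead.target_couplet, row)

    build(key.root, ConstraintRow(label=""))
    occ_matrix.rows = dict(sorted(occ_matrix.rows.items()))
    if level == "occurrence":
        return occ_matrix

    taxon_matrix = InducedMatrix(level="taxon", characters=key.characters,
                                 rows={}, occurrence_matrix=occ_matrix)
    groups: dict[str, list[ConstraintRow]] = {}
    for row in occ_matrix.rows.values():
        groups.setdefault(row.occurrences[0].taxon_key, []).append(row)
    for taxon_key in sorted(groups):
        taxon_matrix.rows[taxon_key] = _union_rows(key, taxon_key,
                                                   groups[taxon_key])
    taxon_matrix.contradictions = list(occ_matrix.contradictions)
    return taxon_matrix


def _apply_lead(key: Key, row: ConstraintRow, lead) -> None:
    """Intersect one lead's coding into a row (in place)."""
    prov = (lead.couplet_id, lead.slot)
    for clause in lead.clauses:
        char_id = _clause_single_char(clause)
        if char_id is None:
            row.residual_clauses.append((clause, prov))
            continue
        char = key.character(char_id)
        if char.is_quantitative:
            add = IntervalUnion.from_intervals(
                p.interval() for p in clause.predicates)
        else:
            add = frozenset().union(
                *(p.allowed_states(char) for p in clause.predicates))
        con = row.constraints.get(char_id)
        if con is None:
            con = Constraint(char_id=char_id)
            if char.is_quantitative:
                con.interval = FULL_QUANTITATIVE
            else:
                con.states = _full_allowed(char)
            row.constraints[char_id] = con
        if char.is_quantitative:
            con.interval = con.interval.intersect(add)
        else:
            con.states = con.states & add
        con.provenance = con.provenance + (prov,)
        if con.is_empty():
            con.contradictory = True


def _union_rows(key: Key, taxon_key: str,
                occ_rows: list[ConstraintRow]) -> ConstraintRow:
    """Union occurrence rows into one taxon row (per mentioning occurrence,
    with polymorphism detection)."""
    row = ConstraintRow(label=taxon_key)
    occs: list[TaxonOccurrence] = []
    for r in occ_rows:
        occs.extend(r.occurrences)
        for clause, prov in r.residual_clauses:
            if (clause, prov) not in row.residual_clauses:
                row.residual_clauses.append((clause, prov))
    row.occurrences = tuple(sorted(occs))

    char_ids = sorted({c for r in occ_rows for c in r.constraints})
    for char_id in char_ids:
        char = key.character(char_id)
        parts = [r.constraints[char_id] for r in occ_rows
                 if char_id in r.constraints]
        merged = Constraint(char_id=char_id)
        merged.provenance = tuple(p for c in parts for p in c.provenance)
        merged.contradictory = any(c.contradictory for c in parts)
        if char.is_quantitative:
            acc = IntervalUnion(())
            for c in parts:
                acc = acc.union(c.interval)
            merged.interval = acc
        else:
            acc_s = frozenset()
            for c in parts:
                acc_s = acc_s | c.states
            merged.states = acc_s
        # polymorphic: some pair of occurrence constraints is disjoint
        poly = False
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                a, b = parts[i], parts[j]
                if char.is_quantitative:
                    disjoint = not a.interval.intersects(b.interval)
                else:
                    disjoint = not (a.states & b.states)
                if disjoint:
                    poly = True
        merged.polymorphic = poly
        row.constraints[char_id] = merged
    return row


def constraint_of(matrix: InducedMatrix, taxon: str,
                  char_id: str) -> Optional[Constraint]:
    """The canonical constraint of (taxon, character), or ``None`` as the
    explicit unconstrained marker.  Unknown taxa/characters raise."""
    row = matrix.row(taxon)
    if char_id not in matrix.characters:
        raise KeyError_(f"unknown character {char_id!r}")
    return row.constraint(char_id)


# --- compatibility and representatives -------------------------------------


def value_compatible(matrix: InducedMatrix, row: ConstraintRow,
                     char_id: str, value: Union[str, float]) -> bool:
    """Is an observed value compatible with a row's per-character
    constraint?  Unconstrained characters are compatible with anything
    (identification stays conservative for polymorphic taxa)."""
    con = row.constraint(char_id)
    if con is None:
        return True
    if con.contradictory:
        return False
    return con.allows(value)


def violated_residual_clauses(matrix: InducedMatrix, row: ConstraintRow,
                              obs: Observation) -> list[Clause]:
    """Residual clauses all of whose alternatives are refuted by the
    observation (alternatives on unobserved characters keep a clause
    alive)."""
    known = obs.known()
    out = []
    for clause, _prov in row.residual_clauses:
        alive = False
        for pred in clause.predicates:
            if pred.char_id not in known:
                alive = True
                break
            char = matrix.characters[pred.char_id]
            if pred.evaluate(char, known[pred.char_id]):
                alive = True
                break
        if not alive:
            out.append(clause)
    return out


def representative_observation(matrix: InducedMatrix,
                               taxon: str) -> Observation:
    """A concrete full observation satisfying a row's constraints,
    including its residual clauses (used for soundness checks: keying this
    observation must land on the taxon)."""
    row = matrix.row(taxon)
    values: dict[str, Union[str, float]] = {}
    for char_id, con in sorted(row.constraints.items()):
        if con.contradictory:
            raise KeyError_(f"{taxon}: contradictory constraint on {char_id}")
        char = matrix.characters[char_id]
        if char.is_quantitative:
            values[char_id] = con.interval.sample_point()
        else:
            order = char.state_list
            values[char_id] = min(con.states, key=order.index)
    for clause, _prov in row.residual_clauses:
        if any(p.char_id in values
               and p.evaluate(matrix.characters[p.char_id], values[p.char_id])
               for p in clause.predicates):
            continue
        satisfied = False
        for pred in sorted(clause.predicates, key=lambda p: p.char_id):
            char = matrix.characters[pred.char_id]
            con = row.constraint(pred.char_id)
            if char.is_quantitative:
                allowed = con.interval if con is not None else FULL_QUANTITATIVE
                pick_iv = allowed.intersect(
                    IntervalUnion.from_intervals([pred.interval()]))
                if not pick_iv.is_empty():
                    values[pred.char_id] = pick_iv.sample_point()
                    satisfied = True
                    break
            else:
                allowed = con.states if con is not None \
                    else _full_allowed(char)
                pick = allowed & pred.allowed_states(char)
                if pick:
                    values[pred.char_id] = min(pick, key=char.state_list.index)
                    satisfied = True
                    break
        if not satisfied:
            raise KeyError_(f"{taxon}: residual clause unsatisfiable "
                            "against per-character constraints")
    return Observation(values)


# --- CSV export / import ---------------------------------------------------

_CELL_INTERVAL = re.compile(
    r"([\[(])\s*(-inf|[-+]?[0-9.eE+]+)\s*\.\.\s*(inf|[-+]?[0-9.eE+]+)\s*([)\]])")


def export_matrix(matrix: InducedMatrix) -> str:
    """One row per taxon, one column per character (sorted ids), cells as
    ``{state,...}`` or ``[lo..hi)|...`` with a trailing ``*`` marking
    polymorphism; a final ``residual_clauses`` column keeps multi-character
    alternatives in the predicate DSL.  Empty cell = unconstrained."""
    char_ids = sorted(matrix.characters)
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["taxon", *char_ids, "residual_clauses"])
    for label in sorted(matrix.rows):
        row = matrix.rows[label]
        cells = [label]
        for cid in char_ids:
            con = row.constraint(cid)
            if con is None:
                cells.append("")
            else:
                cells.append(con.render() + ("*" if con.polymorphic else ""))
        residual = "; ".join(
            keyio.render_predicates((clause,), matrix.characters)
            for clause, _prov in row.residual_clauses)
        cells.append(residual)
        w.writerow(cells)
    return buf.getvalue()


def parse_matrix_csv(text: str, key: Key, level: str = "taxon") -> InducedMatrix:
    """Re-read an exported matrix.  Constraint values, polymorphism flags
    and residual clauses round-trip; lead provenance does not survive
    serialization."""
    reader = csv.reader(text.splitlines())
    header = next(reader)
    if header[0] != "taxon" or header[-1] != "residual_clauses":
        raise keyio.KeyFormatError("malformed matrix CSV header")
    char_ids = header[1:-1]
    out = InducedMatrix(level=level, characters=key.characters, rows={})
    for cells in reader:
        if not cells:
            continue
        label = cells[0]
        row = ConstraintRow(label=label)
        for cid, cell in zip(char_ids, cells[1:-1]):
            if not cell:
                continue
            char = key.character(cid)
            poly = cell.endswith("*")
            if poly:
                cell = cell[:-1]
            con = Constraint(char_id=cid, polymorphic=poly)
            if cell == "CONTRADICTION":
                con.contradictory = True
                if char.is_quantitative:
                    con.interval = IntervalUnion(())
                else:
                    con.states = frozenset()
            elif char.is_quantitative:
                parts = []
                for chunk in cell.split("|"):
                    m = _CELL_INTERVAL.fullmatch(chunk.strip())
                    if not m:
                        raise keyio.KeyFormatError(
                            f"{label}/{cid}: bad interval cell {chunk!r}")
                    parts.append(Interval(float(m.group(2)), float(m.group(3)),
                                          m.group(1) == "[",
                                          m.group(4) == "]"))
                con.interval = IntervalUnion.from_intervals(parts)
            else:
                if not (cell.startswith("{") and cell.endswith("}")):
                    raise keyio.KeyFormatError(
                        f"{label}/{cid}: bad state cell {cell!r}")
                con.states = frozenset(
                    s for s in cell[1:-1].split(",") if s)
                if not con.states:
                    con.contradictory = True
            row.constraints[cid] = con
        if cells[-1]:
            for chunk in cells[-1].split("; "):
                clauses = keyio.parse_predicates(chunk, key.characters)
                for clause in clauses:
                    row.residual_clauses.append((clause, (0, "a")))
        out.rows[label] = row
    return out
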