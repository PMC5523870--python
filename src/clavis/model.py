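"""Domain model for single-access (dichotomous) identification keys.

A key is a rooted binary decision tree.  Each internal node is a *couplet*:
a numbered decision point offering exactly two contrasting statements
(*leads*, rendered ``n`` and ``n′``).  Every lead either forwards the user
to another couplet or terminates at a *taxon occurrence* — a named taxon,
possibly qualified by an infraspecific epithet or a free-text form label,
and disambiguated by an occurrence index because polymorphic taxa may key
out in more than one place.

Leads carry, besides their verbatim statement, a machine-readable coding:
a conjunction of clauses, each clause a disjunction of predicates over a
declared character ontology.  Characters are binary, categorical, ordinal
(ordered states) or quantitative (a measurement with units); predicates
compare an observed value against states, state sets or numeric intervals.

Everything downstream — traversal, matrix induction, polyclave matching,
congruence analysis — operates on the types defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

# --- rendering conventions -------------------------------------------------

PRIME = "′"  # second lead of couplet n renders as "n′"
SLOTS = ("a", "b")
UNKNOWN = "?"  # observation files use this for "not observed"

CHARACTER_KINDS = ("binary", "categorical", "ordinal", "quantitative")
BINARY_STATES = ("absent", "present")

#: Quantitative characters here are physical measurements or counts, so the
#: implicit domain is the nonnegative half-line.
QUANTITATIVE_DOMAIN_LO = 0.0


class KeyError_(Exception):
    """Base class for key-model errors (not the builtin KeyError)."""


class KeyStructureError(KeyError_):
    """Raised when a structurally invalid key is passed where a valid one
    is required."""


class PredicateTypeError(KeyError_):
    """Predicate operator or value incompatible with its character kind."""


# --- intervals -------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Interval:
    """A real interval with independently open/closed endpoints.

    ``lo``/``hi`` may be ``-inf``/``inf`` (infinite endpoints are always
    open).  The canonical text form is ``[lo..hi]`` with ``(``/``)`` for
    open endpoints, e.g. ``[0..0.25)`` for "less than 0.25, nonnegative".
    """

    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", float(self.lo))
        object.__setattr__(self, "hi", float(self.hi))
        if math.isinf(self.lo) and self.lo_closed:
            object.__setattr__(self, "lo_closed", False)
        if math.isinf(self.hi) and self.hi_closed:
            object.__setattr__(self, "hi_closed", False)

    def is_empty(self) -> bool:
        if self.lo > self.hi:
            return True
        if self.lo == self.hi:
            return not (self.lo_closed and self.hi_closed)
        return False

    def contains(self, x: float) -> bool:
        if x < self.lo or x > self.hi:
            return False
        if x == self.lo and not self.lo_closed:
            return False
        if x == self.hi and not self.hi_closed:
            return False
        return True

    def intersect(self, other: "Interval") -> "Interval":
        if self.lo > other.lo or (self.lo == other.lo and not self.lo_closed):
            lo, lo_closed = self.lo, self.lo_closed
        else:
            lo, lo_closed = other.lo, other.lo_closed
        if self.hi < other.hi or (self.hi == other.hi and not self.hi_closed):
            hi, hi_closed = self.hi, self.hi_closed
        else:
            hi, hi_closed = other.hi, other.hi_closed
        return Interval(lo, hi, lo_closed, hi_closed)

    def touches_or_overlaps(self, other: "Interval") -> bool:
        """True if the union of the two intervals is a single interval."""
        if not self.intersect(other).is_empty():
            return True
        # adjacency: [a..b) + [b..c]
        if self.hi == other.lo and (self.hi_closed or other.lo_closed):
            return True
        if other.hi == self.lo and (other.hi_closed or self.lo_closed):
            return True
        return False

    def hull(self, other: "Interval") -> "Interval":
        if other.lo < self.lo or (other.lo == self.lo and other.lo_closed):
            lo, lo_closed = other.lo, other.lo_closed
        else:
            lo, lo_closed = self.lo, self.lo_closed
        if other.hi > self.hi or (other.hi == self.hi and other.hi_closed):
            hi, hi_closed = other.hi, other.hi_closed
        else:
            hi, hi_closed = self.hi, self.hi_closed
        return Interval(lo, hi, lo_closed, hi_closed)

    def sample_point(self) -> float:
        """A representative value inside the interval (must be non-empty)."""
        if self.is_empty():
            raise ValueError(f"empty interval {self}")
        if math.isfinite(self.lo) and self.lo_closed:
            return self.lo
        if math.isfinite(self.hi) and self.hi_closed:
            return self.hi
        if math.isfinite(self.lo) and math.isfinite(self.hi):
            return (self.lo + self.hi) / 2.0
        if math.isfinite(self.lo):
            return self.lo + 1.0
        if math.isfinite(self.hi):
            return self.hi - 1.0
        return 0.0

    def __str__(self) -> str:
        lo = "[" if self.lo_closed else "("
        hi = "]" if self.hi_closed else ")"
        return f"{lo}{_fmt_num(self.lo)}..{_fmt_num(self.hi)}{hi}"


def _fmt_num(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


@dataclass(frozen=True)
class IntervalUnion:
    """A canonical (sorted, pairwise disjoint) union of intervals."""

    parts: tuple[Interval, ...] = ()

    @staticmethod
    def from_intervals(intervals: Iterable[Interval]) -> "IntervalUnion":
        parts = sorted((iv for iv in intervals if not iv.is_empty()),
                       key=lambda iv: (iv.lo, not iv.lo_closed, iv.hi))
        merged: list[Interval] = []
        for iv in parts:
            if merged and merged[-1].touches_or_overlaps(iv):
                merged[-1] = merged[-1].hull(iv)
            else:
                merged.append(iv)
        return IntervalUnion(tuple(merged))

    def is_empty(self) -> bool:
        return not self.parts

    def contains(self, x: float) -> bool:
        return any(iv.contains(x) for iv in self.parts)

    def intersect(self, other: "IntervalUnion") -> "IntervalUnion":
        out = [a.intersect(b) for a in self.parts for b in other.parts]
        return IntervalUnion.from_intervals(out)

    def union(self, other: "IntervalUnion") -> "IntervalUnion":
        return IntervalUnion.from_intervals(self.parts + other.parts)

    def intersects(self, other: "IntervalUnion") -> bool:
        return not self.intersect(other).is_empty()

    def sample_point(self) -> float:
        return self.parts[0].sample_point()

    def endpoints(self) -> list[float]:
        out: list[float] = []
        for iv in self.parts:
            for x in (iv.lo, iv.hi):
                if math.isfinite(x):
                    out.append(x)
        return out

    def __str__(self) -> str:
        return " | ".join(str(iv) for iv in self.parts) if self.parts else "(empty)"


FULL_QUANTITATIVE = IntervalUnion((Interval(QUANTITATIVE_DOMAIN_LO, math.inf,
                                            True, False),))


# --- characters ------------------------------------------------------------


@dataclass(frozen=True)
class Character:
    """One entry of the character ontology.

    ``kind`` is one of ``binary`` (implicit states absent/present),
    ``categorical``, ``ordinal`` (``states`` is an ordered scale) or
    ``quantitative`` (``units`` required, ``unitless`` for counts).
    ``symbol`` records a conventional figure abbreviation where one exists.
    """

    char_id: str
    label: str
    kind: str
    states: tuple[str, ...] = ()
    units: str = ""
    symbol: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in CHARACTER_KINDS:
            raise KeyError_(f"{self.char_id}: unknown character kind {self.kind!r}")
        if self.kind in ("categorical", "ordinal") and len(self.states) < 2:
            raise KeyError_(f"{self.char_id}: {self.kind} character needs >=2 states")
        if self.kind == "binary" and self.states not in ((), BINARY_STATES):
            raise KeyError_(f"{self.char_id}: binary characters have implicit "
                            "states absent/present")
        if self.kind == "quantitative" and not self.units:
            raise KeyError_(f"{self.char_id}: quantitative character needs units "
                            "('unitless' for dimensionless counts)")
        if self.kind != "quantitative" and self.units:
            raise KeyError_(f"{self.char_id}: only quantitative characters "
                            "carry units")

    @property
    def is_quantitative(self) -> bool:
        return self.kind == "quantitative"

    @property
    def state_list(self) -> tuple[str, ...]:
        if self.kind == "binary":
            return BINARY_STATES
        return self.states


# --- predicates ------------------------------------------------------------

OPS = ("eq", "ne", "lt", "le", "gt", "ge", "in_set", "in_interval")
_CATEGORICAL_OPS = ("eq", "ne", "in_set")
_ORDER_OPS = ("lt", "le", "gt", "ge", "in_interval")

Value = Union[str, float, frozenset, Interval]


@dataclass(frozen=True)
class Predicate:
    """An atomic test of one character against a value.

    State-valued characters (binary / categorical / ordinal) use ``eq`` /
    ``ne`` / ``in_set``; ordered characters (ordinal / quantitative)
    additionally support comparisons and ``in_interval``.
    """

    char_id: str
    op: str
    value: Value

    def __post_init__(self) -> None:
        if self.op not in OPS:
            raise PredicateTypeError(f"unknown predicate op {self.op!r}")
        if self.op == "in_set" and not isinstance(self.value, frozenset):
            object.__setattr__(self, "value", frozenset(self.value))
        if self.op == "in_interval":
            iv = self.value
            if not isinstance(iv, Interval):
                raise PredicateTypeError("in_interval needs an Interval value")
            if iv.lo > iv.hi:
                raise PredicateTypeError(f"interval lower > upper in {iv}")

    def check_against(self, char: Character) -> None:
        """Raise PredicateTypeError if op/value do not fit the character."""
        if char.char_id != self.char_id:
            raise PredicateTypeError("predicate/character id mismatch")
        if char.is_quantitative:
            if self.op in _CATEGORICAL_OPS:
                raise PredicateTypeError(
                    f"{self.char_id}: {self.op} not valid on a quantitative "
                    "character")
            if self.op != "in_interval" and not isinstance(self.value, (int, float)):
                raise PredicateTypeError(
                    f"{self.char_id}: comparison against non-number "
                    f"{self.value!r}")
            return
        # state-valued characters
        if self.op in _ORDER_OPS:
            if char.kind != "ordinal":
                raise PredicateTypeError(
                    f"{self.char_id}: comparison on a {char.kind} character")
            if self.op == "in_interval":
                raise PredicateTypeError(
                    f"{self.char_id}: numeric interval on an ordinal character")
            if self.value not in char.state_list:
                raise PredicateTypeError(
                    f"{self.char_id}: unknown state {self.value!r}")
            return
        states = (self.value if self.op == "in_set" else frozenset([self.value]))
        unknown = states - frozenset(char.state_list)
        if unknown:
            raise PredicateTypeError(
                f"{self.char_id}: unknown state(s) {sorted(unknown)}")

    # -- set semantics ------------------------------------------------------

    def allowed_states(self, char: Character) -> frozenset:
        """The subset of the character's states satisfying this predicate
        (state-valued characters only)."""
        order = char.state_list
        if self.op == "eq":
            return frozenset([self.value])
        if self.op == "ne":
            return frozenset(order) - frozenset([self.value])
        if self.op == "in_set":
            return frozenset(self.value)
        idx = order.index(self.value)
        if self.op == "lt":
            return frozenset(order[:idx])
        if self.op == "le":
            return frozenset(order[: idx + 1])
        if self.op == "gt":
            return frozenset(order[idx + 1:])
        if self.op == "ge":
            return frozenset(order[idx:])
        raise PredicateTypeError(f"{self.op} has no state-set semantics")

    def interval(self) -> Interval:
        """The numeric solution set (quantitative characters only)."""
        if self.op == "in_interval":
            return self.value  # type: ignore[return-value]
        x = float(self.value)  # type: ignore[arg-type]
        if self.op == "lt":
            return Interval(-math.inf, x, False, False)
        if self.op == "le":
            return Interval(-math.inf, x, False, True)
        if self.op == "gt":
            return Interval(x, math.inf, False, False)
        if self.op == "ge":
            return Interval(x, math.inf, True, False)
        raise PredicateTypeError(f"{self.op} has no interval semantics")

    def evaluate(self, char: Character, value: Union[str, float]) -> bool:
        if char.is_quantitative:
            return self.interval().contains(float(value))
        return value in self.allowed_states(char)


@dataclass(frozen=True)
class Clause:
    """A disjunction of predicates; a lead's coding is a conjunction of
    clauses ("and/or" statements put two predicates in one clause)."""

    predicates: tuple[Predicate, ...]

    def __post_init__(self) -> None:
        if not self.predicates:
            raise KeyError_("empty clause")

    @property
    def char_ids(self) -> tuple[str, ...]:
        return tuple(p.char_id for p in self.predicates)

    def is_single(self) -> bool:
        return len(self.predicates) == 1


# --- taxa ------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class TaxonOccurrence:
    """One terminal of the key.

    ``form`` is a free-text qualifier (e.g. "high elevation form") that does
    not create a new taxon; ``index`` distinguishes repeated terminals of
    the same full name.  Names render deterministically:
    ``Genus epithet[ subsp. infra][|form][#index]``.
    """

    genus: str
    epithet: str
    rank: str = "species"
    infra: Optional[str] = None
    form: Optional[str] = None
    index: int = 1

    def __post_init__(self) -> None:
        if self.rank not in ("species", "subspecies"):
            raise KeyError_(f"unknown rank {self.rank!r}")
        if self.rank == "subspecies" and not self.infra:
            raise KeyError_("subspecies rank requires an infraspecific epithet")
        if self.index < 1:
            raise KeyError_("occurrence index must be positive")

    @property
    def species_name(self) -> str:
        return f"{self.genus} {self.epithet}".strip()

    @property
    def full_name(self) -> str:
        """Name including infraspecific epithet and form, without index."""
        name = self.species_name
        if self.rank == "subspecies":
            name += f" subsp. {self.infra}"
        if self.form:
            name += f"|{self.form}"
        return name

    @property
    def label(self) -> str:
        """Fully disambiguated occurrence label, e.g. ``Syagrus harleyi|high
        elevation form#2``."""
        return f"{self.full_name}#{self.index}"

    @property
    def taxon_key(self) -> str:
        """Row identity for the taxon-level matrix: species, except that a
        non-autonym subspecies is its own taxon.  Form qualifiers and
        occurrence indices always collapse."""
        if self.rank == "subspecies" and self.infra != self.epithet:
            return f"{self.species_name} subsp. {self.infra}"
        return self.species_name


# --- couplets and keys -----------------------------------------------------


@dataclass(frozen=True)
class Lead:
    couplet_id: int
    slot: str  # "a" or "b"
    statement: str
    clauses: tuple[Clause, ...]
    target_couplet: Optional[int] = None
    target_taxon: Optional[TaxonOccurrence] = None

    def __post_init__(self) -> None:
        if self.slot not in SLOTS:
            raise KeyError_(f"lead slot must be one of {SLOTS}")
        if (self.target_couplet is None) == (self.target_taxon is None):
            raise KeyError_("lead needs exactly one of couplet/taxon target")

    @property
    def is_terminal(self) -> bool:
        return self.target_taxon is not None

    @property
    def branch_label(self) -> str:
        return f"{self.couplet_id}" if self.slot == "a" else f"{self.couplet_id}{PRIME}"


@dataclass(frozen=True)
class Couplet:
    couplet_id: int
    leads: tuple[Lead, ...]
    heading: str = ""  # optional section heading printed above the couplet

    def lead(self, slot: str) -> Lead:
        for ld in self.leads:
            if ld.slot == slot:
                return ld
        raise KeyError_(f"couplet {self.couplet_id} has no lead {slot!r}")


ROOT_LABEL = "ROOT"


@dataclass
class Key:
    """A couplet graph plus its character ontology and metadata."""

    characters: dict[str, Character]
    couplets: dict[int, Couplet]
    root: int
    metadata: dict[str, str] = field(default_factory=dict)

    # -- iteration ----------------------------------------------------------

    def leads(self) -> Iterator[Lead]:
        for cid in sorted(self.couplets):
            yield from self.couplets[cid].leads

    def terminal_leads(self) -> Iterator[Lead]:
        return (ld for ld in self.leads() if ld.is_terminal)

    def occurrences(self) -> list[TaxonOccurrence]:
        return sorted((ld.target_taxon for ld in self.terminal_leads()))

    def character(self, char_id: str) -> Character:
        try:
            return self.characters[char_id]
        except KeyError:
            raise KeyError_(f"unknown character {char_id!r}") from None

    # -- structure ----------------------------------------------------------

    def parent_lead(self, couplet_id: int) -> Optional[Lead]:
        """The unique lead that references this couplet (None for root)."""
        for ld in self.leads():
            if ld.target_couplet == couplet_id:
                return ld
        return None

    def lead_by_label(self, label: str) -> Lead:
        cid, slot = parse_branch_label(label)
        if cid not in self.couplets:
            raise KeyError_(f"unknown branch label {label!r}")
        return self.couplets[cid].lead(slot)

    def require_valid(self) -> "ValidationReport":
        report = validate_key(self)
        if report.errors:
            raise KeyStructureError(
                "key has structural errors: "
                + "; ".join(f"{e.code}@{e.location}" for e in report.errors))
        return report


def parse_branch_label(label: str) -> tuple[int, str]:
    """Parse a branch label like ``"53"`` / ``"57′"`` (ASCII ``'`` accepted)
    into (couplet id, slot)."""
    text = label.strip()
    slot = "a"
    if text.endswith((PRIME, "'")):
        slot = "b"
        text = text[:-1]
    try:
        cid = int(text)
    except ValueError:
        raise KeyError_(f"malformed branch label {label!r}") from None
    return cid, slot


# --- validation ------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    code: str
    location: str
    message: str


@dataclass
class ValidationReport:
    errors: list[Issue] = field(default_factory=list)
    warnings: list[Issue] = field(default_factory=list)
    stats: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_key(key: Key) -> ValidationReport:
    """Structural validation.

    Errors: missing root, couplets without exactly two leads (slots a/b),
    dangling couplet references, self references, couplets referenced by
    more than one lead, couplets unreachable from the root, reference
    cycles, predicates over unknown characters.

    Warnings: taxa keying out more than once (multi-entry, judged on the
    full name including infraspecific epithet and form), couplets whose two
    leads are jointly satisfiable (no mutually exclusive contrast on any
    shared character), and couplets whose two leads name the same terminal.
    """
    rep = ValidationReport()

    if key.root not in key.couplets:
        rep.errors.append(Issue("missing-root", str(key.root),
                                "root couplet does not exist"))
        _fill_stats(key, rep)
        return rep

    referenced: dict[int, list[str]] = {}
    for couplet in key.couplets.values():
        loc = str(couplet.couplet_id)
        slots = sorted(ld.slot for ld in couplet.leads)
        if slots != ["a", "b"]:
            rep.errors.append(Issue("lead-count", loc,
                                    f"couplet has leads {slots}, expected "
                                    "exactly two (a, b)"))
        for ld in couplet.leads:
            lloc = ld.branch_label
            if ld.target_couplet is not None:
                if ld.target_couplet == couplet.couplet_id:
                    rep.errors.append(Issue("self-reference", lloc,
                                            "lead targets its own couplet"))
                elif ld.target_couplet not in key.couplets:
                    rep.errors.append(Issue(
                        "dangling-reference", lloc,
                        f"lead targets missing couplet {ld.target_couplet}"))
                else:
                    referenced.setdefault(ld.target_couplet, []).append(lloc)
            for clause in ld.clauses:
                for pred in clause.predicates:
                    if pred.char_id not in key.characters:
                        rep.errors.append(Issue(
                            "unknown-character", lloc,
                            f"predicate references undeclared character "
                            f"{pred.char_id!r}"))
                    else:
                        try:
                            pred.check_against(key.characters[pred.char_id])
                        except PredicateTypeError as exc:
                            rep.errors.append(Issue("predicate-type", lloc,
                                                    str(exc)))

    if key.root in referenced:
        rep.errors.append(Issue("root-referenced", str(key.root),
                                f"root couplet referenced by "
                                f"{referenced[key.root]}"))
    for cid, sources in referenced.items():
        if len(sources) > 1:
            rep.errors.append(Issue("multi-reference", str(cid),
                                    f"couplet referenced by several leads: "
                                    f"{sources}"))

    # reachability and cycle detection from the root
    seen: set[int] = set()
    in_stack: set[int] = set()

    def visit(cid: int) -> None:
        if cid in in_stack:
            rep.errors.append(Issue("cycle", str(cid),
                                    "couplet reachable from itself"))
            return
        if cid in seen or cid not in key.couplets:
            return
        seen.add(cid)
        in_stack.add(cid)
        for ld in key.couplets[cid].leads:
            if ld.target_couplet is not None:
                visit(ld.target_couplet)
        in_stack.discard(cid)

    visit(key.root)
    for cid in sorted(set(key.couplets) - seen):
        rep.errors.append(Issue("unreachable", str(cid),
                                "couplet not reachable from the root"))

    # -- warnings -----------------------------------------------------------
    by_name: dict[str, int] = {}
    for ld in key.terminal_leads():
        name = ld.target_taxon.full_name
        by_name[name] = by_name.get(name, 0) + 1
    multi = sorted(name for name, n in by_name.items() if n > 1)
    for name in multi:
        rep.warnings.append(Issue("multi-entry-taxon", name,
                                  f"taxon keys out {by_name[name]} times"))

    for couplet in key.couplets.values():
        leads = couplet.leads
        if len(leads) != 2:
            continue
        a, b = leads
        if (a.is_terminal and b.is_terminal
                and a.target_taxon.full_name == b.target_taxon.full_name):
            rep.warnings.append(Issue("duplicate-terminal",
                                      str(couplet.couplet_id),
                                      "both leads name the same terminal"))
        if not rep.errors and leads_jointly_satisfiable(key, a, b):
            rep.warnings.append(Issue(
                "non-exclusive-leads", str(couplet.couplet_id),
                "no shared character with mutually exclusive constraints"))

    _fill_stats(key, rep)
    return rep


def _fill_stats(key: Key, rep: ValidationReport) -> None:
    terminals = list(key.terminal_leads())
    species = {ld.target_taxon.species_name for ld in terminals}
    by_name: dict[str, int] = {}
    for ld in terminals:
        name = ld.target_taxon.full_name
        by_name[name] = by_name.get(name, 0) + 1
    rep.stats = {
        "couplets": len(key.couplets),
        "leads": sum(len(c.leads) for c in key.couplets.values()),
        "terminal_leads": len(terminals),
        "distinct_species": len(species),
        "multi_entry_species": sum(1 for n in by_name.values() if n > 1),
    }


def leads_jointly_satisfiable(key: Key, a: Lead, b: Lead) -> bool:
    """Can one specimen satisfy both leads of a couplet?

    Exact for single-predicate clauses (per-character intersection);
    multi-character disjunctive clauses are checked against that
    intersection one clause at a time, which can only over-report
    satisfiability (erring toward a warning, never hiding one).
    """
    states: dict[str, frozenset] = {}
    numbers: dict[str, IntervalUnion] = {}
    residual: list[Clause] = []
    for ld in (a, b):
        for clause in ld.clauses:
            if not clause.is_single():
                residual.append(clause)
                continue
            pred = clause.predicates[0]
            char = key.characters.get(pred.char_id)
            if char is None:
                return True  # cannot judge; parse error reported elsewhere
            if char.is_quantitative:
                cur = numbers.get(pred.char_id, FULL_QUANTITATIVE)
                cur = cur.intersect(
                    IntervalUnion.from_intervals([pred.interval()]))
                if cur.is_empty():
                    return False
                numbers[pred.char_id] = cur
            else:
                cur = states.get(pred.char_id, frozenset(char.state_list))
                cur = cur & pred.allowed_states(char)
                if not cur:
                    return False
                states[pred.char_id] = cur
    for clause in residual:
        satisfiable = False
        for pred in clause.predicates:
            char = key.characters.get(pred.char_id)
            if char is None:
                satisfiable = True
                break
            if char.is_quantitative:
                cur = numbers.get(pred.char_id, FULL_QUANTITATIVE)
                if cur.intersects(
                        IntervalUnion.from_intervals([pred.interval()])):
                    satisfiable = True
                    break
            else:
                cur = states.get(pred.char_id, frozenset(char.state_list))
                if cur & pred.allowed_states(char):
                    satisfiable = True
                    break
        if not satisfiable:
            return False
    return True


# --- taxon listings --------------------------------------------------------

# --- observations ----------------------------------------------------------


@dataclass
class Observation:
    """A partial assignment of values to characters.

    Values are state names (binary/categorical/ordinal) or numbers
    (quantitative, in the character's declared units).  Characters not in
    the mapping are unknown; an explicit ``None`` also means unknown.
    """

    values: dict[str, Union[str, float, None]] = field(default_factory=dict)

    def known(self) -> dict[str, Union[str, float]]:
        return {k: v for k, v in self.values.items() if v is not None}

    def type_check(self, key: Key) -> None:
        """Raise on unknown characters or values outside the ontology."""
        for char_id, value in self.values.items():
            char = key.character(char_id)
            if value is None:
                continue
            if char.is_quantitative:
                try:
                    float(value)
                except (TypeError, ValueError):
                    raise KeyError_(
                        f"{char_id}: expected a number, got {value!r}") from None
            elif value not in char.state_list:
                raise KeyError_(
                    f"{char_id}: {value!r} is not one of {char.state_list}")


# --- taxon listings --------------------------------------------------------

RANK_MODES = ("occurrences", "species", "all_terminals")


def taxa(key: Key, rank_mode: str = "species"):
    """List the key's taxa.

    ``occurrences`` — every terminal, in deterministic (name, index) order;
    ``all_terminals`` — distinct full names (subspecies and forms distinct);
    ``species`` — distinct species names (subspecies, forms and repeated
    occurrences collapse).
    """
    if rank_mode not in RANK_MODES:
        raise ValueError(f"rank_mode must be one of {RANK_MODES}, "
                         f"got {rank_mode!r}")
    terminals = [ld.target_taxon for ld in key.terminal_leads()]
    if rank_mode == "occurrences":
        return sorted(terminals, key=lambda t: (t.full_name, t.index))
    if rank_mode == "all_terminals":
        return sorted({t.full_name for t in terminals})
    return sorted({t.species_name for t in terminals})
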