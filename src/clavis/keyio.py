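"""Readers and writers for the key exchange formats.

Keys travel as two UTF-8 TSV files:

``characters.tsv``
    ``char_id  label  kind  states  units  symbol  description`` — the
    ontology.  ``states`` is a comma-separated ordered list (categorical /
    ordinal only); quantitative characters declare ``units`` once here
    (``unitless`` for counts) and never inline in predicates.

``key.tsv``
    ``couplet  slot  statement  predicates  target`` — one row per lead.
    ``slot`` is ``a``/``b``; ``predicates`` uses the mini-DSL below;
    ``target`` is ``C:<couplet id>`` or ``T:<name>`` where a name is
    ``Genus epithet[ subsp. infra][|form][#k]``.  The ``#k`` occurrence
    index is optional on input (indices are assigned deterministically in
    couplet order) and written out whenever a name keys out more than once.

Leading ``# key: value`` comment lines in either file become key metadata.

Predicate mini-DSL
------------------
A coding is a conjunction of clauses separated by ``;``; within a clause,
``|`` separates alternative predicates (disjunction — "and/or" contrasts).
Atoms are::

    char=state        char!=state         char in {state,state,...}
    char<x  char<=x   char>x  char>=x     char in a..b | a.. | ..b

Ranges are closed; ``a..`` means ``[a, inf)`` and ``..b`` means
``(-inf, b]``; strict bounds come from the comparison forms.  Decimal
point is ``.``.
"""

from __future__ import annotations

import csv
import io as _io
import math
import re
from dataclasses import dataclass, field

from .model import (
    BINARY_STATES,
    Character,
    Clause,
    Couplet,
    Interval,
    Key,
    KeyError_,
    Lead,
    Predicate,
    Observation,
    TaxonOccurrence,
    UNKNOWN,
)


class KeyFormatError(KeyError_):
    """Malformed key/observation file."""


class DSLSyntaxError(KeyFormatError):
    """Predicate expression syntax error; carries the source offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


# --- predicate mini-DSL ----------------------------------------------------

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_NUMBER = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?")
_STATE = re.compile(r"[A-Za-z0-9_+.\-]+")


@dataclass(frozen=True)
class PredicateExpression:
    """A parsed predicate coding together with its source text."""

    source: str
    clauses: tuple[Clause, ...]


def parse_predicates(text: str, ontology: dict[str, Character]) -> tuple[Clause, ...]:
    """Parse a mini-DSL expression into a conjunction of clauses.

    Raises DSLSyntaxError (with offset) on malformed input and
    PredicateTypeError on operator/kind mismatches.
    """
    clauses: list[Clause] = []
    pos = 0
    for part in text.split(";"):
        preds: list[Predicate] = []
        dpos = pos
        for disjunct in part.split("|"):
            preds.append(_parse_atom(disjunct, dpos, ontology))
            dpos += len(disjunct) + 1
        clauses.append(Clause(tuple(preds)))
        pos += len(part) + 1
    return tuple(clauses)


def parse_predicate(text: str, ontology: dict[str, Character]) -> PredicateExpression:
    return PredicateExpression(text, parse_predicates(text, ontology))


def _parse_atom(text: str, base: int, ontology: dict[str, Character]) -> Predicate:
    work = text.rstrip()
    lead_ws = len(work) - len(work.lstrip())
    work = work.strip()
    off = base + lead_ws  # offset of the atom within the whole expression

    m = _IDENT.match(work)
    if not m:
        raise DSLSyntaxError("expected character identifier", off)
    char_id = m.group(0)
    char = ontology.get(char_id)
    if char is None:
        raise KeyError_(f"unknown character {char_id!r} in predicate {text!r}")
    rest = work[m.end():]
    rest_off = off + m.end()

    stripped = rest.lstrip()
    rest_off += len(rest) - len(stripped)
    rest = stripped

    for op_text, op in (("!=", "ne"), ("<=", "le"), (">=", "ge"),
                        ("=", "eq"), ("<", "lt"), (">", "gt")):
        if rest.startswith(op_text):
            value_text = rest[len(op_text):].strip()
            value_off = rest_off + len(op_text) + (
                len(rest) - len(op_text) - len(rest[len(op_text):].lstrip()))
            pred = Predicate(char_id, op,
                             _parse_scalar(value_text, value_off, char))
            pred.check_against(char)
            return pred
    if rest.startswith("in ") or rest.startswith("in{"):
        value_text = rest[2:].strip()
        value_off = rest_off + 2 + (len(rest) - 2 - len(rest[2:].lstrip()))
        pred = _parse_in(char_id, value_text, value_off, char)
        pred.check_against(char)
        return pred
    raise DSLSyntaxError(f"expected operator after {char_id!r}", rest_off)


def _parse_scalar(text: str, off: int, char: Character):
    if not text:
        raise DSLSyntaxError("missing value", off)
    if char.is_quantitative:
        m = _NUMBER.fullmatch(text)
        if not m:
            raise DSLSyntaxError(f"expected a number, got {text!r}", off)
        return float(text)
    m = _STATE.fullmatch(text)
    if not m:
        raise DSLSyntaxError(f"malformed state name {text!r}", off)
    return text


def _parse_in(char_id: str, text: str, off: int, char: Character) -> Predicate:
    if text.startswith("{"):
        if not text.endswith("}"):
            raise DSLSyntaxError("unterminated state set", off + len(text))
        items = [s.strip() for s in text[1:-1].split(",")]
        if not all(items) or not items:
            raise DSLSyntaxError("empty item in state set", off)
        return Predicate(char_id, "in_set", frozenset(items))
    if ".." in text:
        lo_text, hi_text = text.split("..", 1)
        lo_text, hi_text = lo_text.strip(), hi_text.strip()
        if not lo_text and not hi_text:
            raise DSLSyntaxError("interval needs at least one bound", off)
        lo = float(lo_text) if lo_text else -math.inf
        hi = float(hi_text) if hi_text else math.inf
        if lo_text and not _NUMBER.fullmatch(lo_text):
            raise DSLSyntaxError(f"bad lower bound {lo_text!r}", off)
        if hi_text and not _NUMBER.fullmatch(hi_text):
            raise DSLSyntaxError(f"bad upper bound {hi_text!r}",
                                 off + len(text) - len(hi_text))
        if lo > hi:
            raise KeyError_(f"interval lower bound exceeds upper in {text!r}")
        return Predicate(char_id, "in_interval", Interval(lo, hi, True, True))
    raise DSLSyntaxError("'in' expects {states} or an a..b range", off)


def _fmt_num(x: float) -> str:
    if math.isinf(x):
        return ""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


_OP_TEXT = {"eq": "=", "ne": "!=", "lt": "<", "le": "<=", "gt": ">", "ge": ">="}


def render_predicate(pred: Predicate, ontology: dict[str, Character]) -> str:
    char = ontology[pred.char_id]
    if pred.op in _OP_TEXT:
        value = pred.value
        text = _fmt_num(value) if char.is_quantitative else str(value)
        return f"{pred.char_id}{_OP_TEXT[pred.op]}{text}"
    if pred.op == "in_set":
        order = {s: i for i, s in enumerate(char.state_list)}
        states = sorted(pred.value, key=lambda s: order.get(s, len(order)))
        return f"{pred.char_id} in {{{','.join(states)}}}"
    iv: Interval = pred.value  # in_interval
    return f"{pred.char_id} in {_fmt_num(iv.lo)}..{_fmt_num(iv.hi)}"


def render_predicates(clauses: tuple[Clause, ...],
                      ontology: dict[str, Character]) -> str:
    return ";".join(
        "|".join(render_predicate(p, ontology) for p in clause.predicates)
        for clause in clauses)


# --- taxon name grammar ----------------------------------------------------

def parse_taxon_name(text: str) -> tuple[TaxonOccurrence, int | None]:
    """Parse ``Genus epithet[ subsp. infra][|form][#k]``; returns the
    occurrence (with index 1) and the explicit index, if any."""
    name = text.strip()
    index: int | None = None
    if "#" in name:
        name, idx_text = name.rsplit("#", 1)
        try:
            index = int(idx_text)
        except ValueError:
            raise KeyFormatError(f"bad occurrence index in {text!r}") from None
    form: str | None = None
    if "|" in name:
        name, form = name.split("|", 1)
        form = form.strip() or None
    name = name.strip()
    rank, infra = "species", None
    if " subsp. " in name:
        name, infra = name.split(" subsp. ", 1)
        infra = infra.strip()
        rank = "subspecies"
    tokens = name.split()
    if not tokens:
        raise KeyFormatError(f"empty taxon name in {text!r}")
    if len(tokens) == 1:
        genus, epithet = "", tokens[0]
    elif len(tokens) == 2:
        genus, epithet = tokens
    else:
        raise KeyFormatError(f"cannot parse taxon name {text!r}")
    occ = TaxonOccurrence(genus=genus, epithet=epithet, rank=rank,
                          infra=infra, form=form, index=1)
    return occ, index


# --- key files -------------------------------------------------------------

_CHAR_COLUMNS = ("char_id", "label", "kind", "states", "units", "symbol",
                 "description")
_KEY_COLUMNS = ("couplet", "slot", "statement", "predicates", "target")


def _read_tsv(text: str, columns: tuple[str, ...], what: str):
    """Yield row dicts; returns (metadata, rows)."""
    metadata: dict[str, str] = {}
    lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                metadata[k.strip()] = v.strip()
            continue
        if line.strip():
            lines.append(line)
    if not lines:
        raise KeyFormatError(f"{what}: no content")
    reader = csv.reader(lines, delimiter="\t")
    header = tuple(h.strip() for h in next(reader))
    if header != columns:
        raise KeyFormatError(f"{what}: header {header} != expected {columns}")
    rows = []
    for i, raw in enumerate(reader, start=2):
        if len(raw) != len(columns):
            raise KeyFormatError(
                f"{what} row {i}: {len(raw)} columns, expected {len(columns)}")
        rows.append(dict(zip(columns, (c.strip() for c in raw))))
    return metadata, rows


def parse_characters(text: str) -> tuple[dict[str, Character], dict[str, str]]:
    metadata, rows = _read_tsv(text, _CHAR_COLUMNS, "characters.tsv")
    chars: dict[str, Character] = {}
    for row in rows:
        cid = row["char_id"]
        if cid in chars:
            raise KeyFormatError(f"duplicate character {cid!r}")
        states = tuple(s.strip() for s in row["states"].split(",") if s.strip())
        chars[cid] = Character(
            char_id=cid, label=row["label"], kind=row["kind"],
            states=states, units=row["units"], symbol=row["symbol"],
            description=row["description"])
    return chars, metadata


def parse_key(characters_text: str, couplets_text: str) -> Key:
    """Parse the two TSV files into a Key (structure is NOT validated here;
    run :func:`clavis.model.validate_key` / ``key.require_valid()``)."""
    characters, meta_c = parse_characters(characters_text)
    meta_k, rows = _read_tsv(couplets_text, _KEY_COLUMNS, "key.tsv")

    seen: set[tuple[int, str]] = set()
    parsed = []
    for row in rows:
        try:
            cid = int(row["couplet"])
        except ValueError:
            raise KeyFormatError(f"bad couplet id {row['couplet']!r}") from None
        slot = row["slot"]
        if slot not in ("a", "b"):
            raise KeyFormatError(f"couplet {cid}: bad slot {slot!r}")
        if (cid, slot) in seen:
            raise KeyFormatError(f"duplicate lead: couplet {cid} slot {slot}")
        seen.add((cid, slot))
        parsed.append((cid, slot, row))

    # occurrence indices are assigned in (couplet, slot) order so the result
    # does not depend on physical row order
    parsed.sort(key=lambda t: (t[0], t[1]))
    counters: dict[str, int] = {}
    taken: dict[str, set[int]] = {}
    leads_by_couplet: dict[int, list[Lead]] = {}
    for cid, slot, row in parsed:
        clauses = parse_predicates(row["predicates"], characters) \
            if row["predicates"] else ()
        target = row["target"]
        target_couplet = None
        target_taxon = None
        if target.startswith("C:"):
            try:
                target_couplet = int(target[2:])
            except ValueError:
                raise KeyFormatError(
                    f"couplet {cid}{slot}: bad couplet target {target!r}"
                ) from None
        elif target.startswith("T:"):
            occ, explicit = parse_taxon_name(target[2:])
            name = occ.full_name
            used = taken.setdefault(name, set())
            if explicit is None:
                idx = counters.get(name, 0) + 1
                while idx in used:
                    idx += 1
            else:
                idx = explicit
                if idx in used:
                    raise KeyFormatError(
                        f"couplet {cid}{slot}: duplicate occurrence "
                        f"{name}#{idx}")
            counters[name] = max(counters.get(name, 0), idx)
            used.add(idx)
            target_taxon = TaxonOccurrence(
                genus=occ.genus, epithet=occ.epithet, rank=occ.rank,
                infra=occ.infra, form=occ.form, index=idx)
        else:
            raise KeyFormatError(
                f"couplet {cid}{slot}: target must be 'C:<id>' or 'T:<name>',"
                f" got {target!r}")
        leads_by_couplet.setdefault(cid, []).append(Lead(
            couplet_id=cid, slot=slot, statement=row["statement"],
            clauses=tuple(clauses), target_couplet=target_couplet,
            target_taxon=target_taxon))

    couplets = {cid: Couplet(cid, tuple(leads))
                for cid, leads in leads_by_couplet.items()}
    metadata = dict(meta_c)
    metadata.update(meta_k)
    root = int(metadata.get("root", min(couplets) if couplets else 1))
    return Key(characters=characters, couplets=couplets, root=root,
               metadata=metadata)


def write_key(key: Key) -> tuple[str, str]:
    """Serialize canonically: metadata lines sorted, characters sorted by
    id, leads sorted by (couplet, slot).  ``parse_key(*write_key(k))`` is
    structurally equal to ``k`` and re-writing is byte-stable."""
    multi = {}
    for ld in key.terminal_leads():
        name = ld.target_taxon.full_name
        multi[name] = multi.get(name, 0) + 1

    def render_target(ld: Lead) -> str:
        if ld.target_couplet is not None:
            return f"C:{ld.target_couplet}"
        occ = ld.target_taxon
        name = occ.full_name
        if multi.get(name, 0) > 1:
            name += f"#{occ.index}"
        return f"T:{name}"

    meta_lines = [f"# {k}: {v}" for k, v in sorted(key.metadata.items())
                  if k != "root"]
    meta_lines.append(f"# root: {key.root}")

    cbuf = _io.StringIO()
    cw = csv.writer(cbuf, delimiter="\t", lineterminator="\n")
    cw.writerow(_CHAR_COLUMNS)
    for cid in sorted(key.characters):
        ch = key.characters[cid]
        cw.writerow([ch.char_id, ch.label, ch.kind, ",".join(ch.states),
                     ch.units, ch.symbol, ch.description])
    characters_text = "\n".join(meta_lines) + "\n" + cbuf.getvalue()

    kbuf = _io.StringIO()
    kw = csv.writer(kbuf, delimiter="\t", lineterminator="\n")
    kw.writerow(_KEY_COLUMNS)
    for cid in sorted(key.couplets):
        for ld in sorted(key.couplets[cid].leads, key=lambda l: l.slot):
            kw.writerow([cid, ld.slot, ld.statement,
                         render_predicates(ld.clauses, key.characters),
                         render_target(ld)])
    couplets_text = "\n".join(meta_lines) + "\n" + kbuf.getvalue()
    return characters_text, couplets_text


@dataclass
class KeyDocument:
    """A serialized key: the two canonical TSV texts plus metadata."""

    characters_text: str
    couplets_text: str
    metadata: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_key(cls, key: Key) -> "KeyDocument":
        c, k = write_key(key)
        return cls(c, k, dict(key.metadata))

    def to_key(self) -> Key:
        return parse_key(self.characters_text, self.couplets_text)


# --- observations ----------------------------------------------------------

def parse_observation(text: str, key: Key) -> Observation:
    """``observations.tsv``: two columns ``char_id  value``; ``?`` = unknown."""
    values: dict[str, str | float | None] = {}
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if parts[0] == "char_id":  # optional header
            continue
        if len(parts) != 2:
            raise KeyFormatError(f"observations row {i}: expected 2 columns")
        char_id, raw = parts
        char = key.character(char_id)
        if raw == UNKNOWN:
            values[char_id] = None
        elif char.is_quantitative:
            try:
                values[char_id] = float(raw)
            except ValueError:
                raise KeyFormatError(
                    f"observations row {i}: {char_id} expects a number, "
                    f"got {raw!r}") from None
        else:
            values[char_id] = raw
    obs = Observation(values)
    obs.type_check(key)
    return obs


def write_observation(obs: Observation) -> str:
    lines = ["char_id\tvalue"]
    for char_id in sorted(obs.values):
        v = obs.values[char_id]
        text = UNKNOWN if v is None else (
            _fmt_num(v) if isinstance(v, float) else str(v))
        lines.append(f"{char_id}\t{text}")
    return "\n".join(lines) + "\n"


# --- Newick export ---------------------------------------------------------

_SAFE_NEWICK = re.compile(r"[A-Za-z0-9_.#\-]+")


def _newick_label(text: str) -> str:
    text = text.replace(" ", "_")
    if _SAFE_NEWICK.fullmatch(text):
        return text
    return "'" + text.replace("'", "''") + "'"


def export_newick(key: Key) -> str:
    """Render the couplet graph as a rooted Newick tree.

    Internal nodes are labelled ``c<couplet id>``, leaves carry the
    occurrence label (spaces become underscores), and every branch has
    length 1, e.g. ``(A#1:1,B#1:1)c1;`` for a single-couplet key.
    """
    key.require_valid()

    def render(cid: int) -> str:
        couplet = key.couplets[cid]
        parts = []
        for ld in sorted(couplet.leads, key=lambda l: l.slot):
            if ld.is_terminal:
                parts.append(f"{_newick_label(ld.target_taxon.label)}:1")
            else:
                parts.append(f"{render(ld.target_couplet)}:1")
        return f"({','.join(parts)})c{cid}"

    return render(key.root) + ";"


# --- auxiliary tables (clades, regions) ------------------------------------

def read_table(text: str, columns: tuple[str, ...], what: str):
    """Generic TSV reader used for the clade and region tables; returns
    (metadata, row dicts)."""
    return _read_tsv(text, columns, what)
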