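"""Executing a key against observations, and key-tree queries.

Lead evaluation is three-valued: a lead *matches* if every clause is true,
*fails* if any clause is false, and is *undetermined* otherwise (some
clause depends on an unobserved character).

``strict`` mode follows the couplet chain only while exactly one lead
matches and the other fails — the field workflow, where an undecidable
couplet is reported so the user can go observe the deciding character.
``explore`` mode descends every non-failing lead and returns the union of
reachable terminals — the partial-specimen workflow.  In either mode a
couplet whose two leads both match is reported as a contradiction (the
observation is inconsistent with the key's contrasts) rather than being
resolved silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Iterable, Optional, Union

from .model import (
    Key,
    KeyError_,
    Lead,
    Observation,
    ROOT_LABEL,
    TaxonOccurrence,
    parse_branch_label,
)

# --- lead evaluation -------------------------------------------------------


def evaluate_lead(key: Key, lead: Lead, obs: Observation) -> Optional[bool]:
    """Three-valued lead evaluation: True / False / None (undetermined)."""
    known = obs.known()
    result: Optional[bool] = True
    for clause in lead.clauses:
        any_true = False
        any_unknown = False
        for pred in clause.predicates:
            if pred.char_id not in known:
                any_unknown = True
                continue
            char = key.character(pred.char_id)
            if pred.evaluate(char, known[pred.char_id]):
                any_true = True
                break
        if any_true:
            continue
        if any_unknown:
            result = None
        else:
            return False
    return result


# --- traversal -------------------------------------------------------------

STATUS_IDENTIFIED = "identified"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_CONTRADICTION = "contradiction"


@dataclass
class TraversalResult:
    status: str
    path: list[tuple[int, str]] = field(default_factory=list)
    outcomes: set[TaxonOccurrence] = field(default_factory=set)
    unresolved: list[int] = field(default_factory=list)
    contradictions: list[int] = field(default_factory=list)

    @property
    def outcome(self) -> TaxonOccurrence:
        if self.status != STATUS_IDENTIFIED:
            raise KeyError_(f"no unique outcome (status {self.status})")
        (occ,) = self.outcomes
        return occ


def traverse(key: Key, obs: Observation, mode: str = "strict") -> TraversalResult:
    """Run the key against an observation (see module docstring for modes)."""
    if mode not in ("strict", "explore"):
        raise ValueError(f"mode must be 'strict' or 'explore', got {mode!r}")
    key.require_valid()
    obs.type_check(key)
    if mode == "strict":
        return _traverse_strict(key, obs)
    return _traverse_explore(key, obs)


def _traverse_strict(key: Key, obs: Observation) -> TraversalResult:
    result = TraversalResult(status=STATUS_AMBIGUOUS)
    cid = key.root
    while True:
        couplet = key.couplets[cid]
        a, b = couplet.lead("a"), couplet.lead("b")
        va, vb = evaluate_lead(key, a, obs), evaluate_lead(key, b, obs)
        if va is True and vb is True:
            result.status = STATUS_CONTRADICTION
            result.contradictions.append(cid)
            result.outcomes = (subtree_occurrences(key, a)
                               | subtree_occurrences(key, b))
            return result
        if va is True and vb is False:
            chosen = a
        elif vb is True and va is False:
            chosen = b
        else:
            # undetermined couplet (or both leads fail): stop and report
            result.status = STATUS_AMBIGUOUS
            result.unresolved.append(cid)
            pool: set[TaxonOccurrence] = set()
            for lead, v in ((a, va), (b, vb)):
                if v is not False:
                    pool |= subtree_occurrences(key, lead)
            result.outcomes = pool
            return result
        result.path.append((cid, chosen.slot))
        if chosen.is_terminal:
            result.status = STATUS_IDENTIFIED
            result.outcomes = {chosen.target_taxon}
            return result
        cid = chosen.target_couplet


def _traverse_explore(key: Key, obs: Observation) -> TraversalResult:
    result = TraversalResult(status=STATUS_AMBIGUOUS)

    def descend(cid: int) -> set[TaxonOccurrence]:
        couplet = key.couplets[cid]
        a, b = couplet.lead("a"), couplet.lead("b")
        va, vb = evaluate_lead(key, a, obs), evaluate_lead(key, b, obs)
        if va is True and vb is True:
            result.contradictions.append(cid)
        out: set[TaxonOccurrence] = set()
        for lead, v in ((a, va), (b, vb)):
            if v is False:
                continue
            if lead.is_terminal:
                out.add(lead.target_taxon)
            else:
                out |= descend(lead.target_couplet)
        return out

    result.outcomes = descend(key.root)

    # forced prefix: follow the chain while exactly one lead survives
    cid = key.root
    while True:
        couplet = key.couplets[cid]
        a, b = couplet.lead("a"), couplet.lead("b")
        va, vb = evaluate_lead(key, a, obs), evaluate_lead(key, b, obs)
        if (va is False) and (vb is not False):
            chosen = b
        elif (vb is False) and (va is not False):
            chosen = a
        else:
            break
        result.path.append((cid, chosen.slot))
        if chosen.is_terminal:
            break
        cid = chosen.target_couplet

    if result.contradictions:
        result.status = STATUS_CONTRADICTION
    elif len(result.outcomes) == 1:
        result.status = STATUS_IDENTIFIED
    else:
        result.status = STATUS_AMBIGUOUS
    return result


# --- tree queries ----------------------------------------------------------


def subtree_occurrences(key: Key, lead: Lead) -> set[TaxonOccurrence]:
    """All taxon occurrences reachable below a lead."""
    if lead.is_terminal:
        return {lead.target_taxon}
    out: set[TaxonOccurrence] = set()
    for child in key.couplets[lead.target_couplet].leads:
        out |= subtree_occurrences(key, child)
    return out


def path_to(key: Key, occurrence: Union[TaxonOccurrence, str]) -> list[int]:
    """The unique root-to-terminal couplet sequence for an occurrence
    (given either as a TaxonOccurrence or its label, e.g.
    ``"Syagrus cardenasii#1"``; a bare full name means index 1)."""
    key.require_valid()
    label = occurrence.label if isinstance(occurrence, TaxonOccurrence) \
        else occurrence.strip()
    if "#" not in label:
        label += "#1"
    target_lead = None
    for ld in key.terminal_leads():
        if ld.target_taxon.label == label:
            target_lead = ld
            break
    if target_lead is None:
        raise KeyError_(f"unknown occurrence {label!r}")
    parent: dict[int, int] = {}
    for ld in key.leads():
        if ld.target_couplet is not None:
            parent[ld.target_couplet] = ld.couplet_id
    path = [target_lead.couplet_id]
    while path[-1] in parent:
        path.append(parent[path[-1]])
    return list(reversed(path))


def branch_membership(key: Key, branch_label: str,
                      level: str = "species") -> Union[set, list]:
    """Taxa with at least one occurrence in the subtree below a lead.

    ``branch_label`` is ``"n"`` / ``"n′"`` (ASCII quote accepted) or
    ``"ROOT"`` for the whole key.  ``level`` is ``occurrences`` (sorted
    list) or ``species`` (set of species names).
    """
    if level not in ("occurrences", "species"):
        raise ValueError(f"level must be 'occurrences' or 'species', "
                         f"got {level!r}")
    key.require_valid()
    if branch_label == ROOT_LABEL:
        occs = set(key.occurrences())
    else:
        occs = subtree_occurrences(key, key.lead_by_label(branch_label))
    if level == "occurrences":
        return sorted(occs, key=lambda t: (t.full_name, t.index))
    return {occ.species_name for occ in occs}


def branch_labels(key: Key) -> list[str]:
    """All branch labels of the key, sorted by couplet then slot."""
    return [ld.branch_label for ld in key.leads()]


# --- key metrics -----------------------------------------------------------


@dataclass
class KeyMetrics:
    """Depth statistics of a key.

    Depth of a terminal = number of couplets answered from the root to it.
    ``expected_depth`` is the mean depth under a uniform prior over
    occurrences — the expected number of couplets to an identification.
    """

    min_depth: int
    max_depth: int
    mean_depth: float
    expected_depth: float
    subtree_sizes: dict[int, int]
    depths: dict[str, int]


def key_metrics(key: Key) -> KeyMetrics:
    key.require_valid()
    depths: dict[str, int] = {}

    def walk(cid: int, depth: int) -> int:
        size = 0
        for ld in key.couplets[cid].leads:
            if ld.is_terminal:
                depths[ld.target_taxon.label] = depth
                size += 1
            else:
                size += walk(ld.target_couplet, depth + 1)
        sizes[cid] = size
        return size

    sizes: dict[int, int] = {}
    walk(key.root, 1)
    values = list(depths.values())
    return KeyMetrics(
        min_depth=min(values),
        max_depth=max(values),
        mean_depth=mean(values),
        expected_depth=mean(values),
        subtree_sizes=sizes,
        depths=depths,
    )
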