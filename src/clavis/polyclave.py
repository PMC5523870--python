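"""Multi-access (polyclave) identification over the induced matrix.

Instead of answering couplets in the key's fixed order, any subset of
observed characters is matched against every taxon's constraint row.  A
taxon's mismatch count is the number of observed characters whose value is
incompatible with its constraints (plus any fully refuted multi-character
alternative clause); taxa with mismatches within an error tolerance are
ranked.  Unconstrained and polymorphic characters never count against a
taxon — identification is deliberately conservative, since the source keys
under-sample real variation.

``next_best_character`` implements greedy entropy reduction for
interactive use: among unanswered characters it returns the one whose
answer is expected to shrink the candidate set the most, measuring
expected information gain in bits with answer probabilities proportional
to candidate counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .model import Interval, IntervalUnion, KeyError_, Observation
from .matrix import (
    ConstraintRow,
    InducedMatrix,
    value_compatible,
    violated_residual_clauses,
)

# --- matching --------------------------------------------------------------


@dataclass
class MatchEntry:
    taxon: str
    mismatches: int
    conflicting: list[str] = field(default_factory=list)
    supporting: list[str] = field(default_factory=list)


@dataclass
class MatchResult:
    """Candidates ranked by ascending mismatch count (ties alphabetical)."""

    entries: list[MatchEntry]
    tolerance: int

    @property
    def taxa(self) -> list[str]:
        return [e.taxon for e in self.entries]


def mismatch_count(matrix: InducedMatrix, row: ConstraintRow,
                   obs: Observation) -> MatchEntry:
    conflicting: list[str] = []
    supporting: list[str] = []
    for char_id, value in sorted(obs.known().items()):
        if char_id not in matrix.characters:
            raise KeyError_(f"observation references unknown character "
                            f"{char_id!r}")
        con = row.constraint(char_id)
        if con is None:
            continue  # unconstrained: compatible but not evidence
        if value_compatible(matrix, row, char_id, value):
            supporting.append(char_id)
        else:
            conflicting.append(char_id)
    n = len(conflicting) + len(violated_residual_clauses(matrix, row, obs))
    return MatchEntry(taxon=row.label, mismatches=n,
                      conflicting=conflicting, supporting=supporting)


def match(matrix: InducedMatrix, obs: Observation,
          tolerance: int = 0) -> MatchResult:
    """All taxa whose mismatch count is at most ``tolerance``."""
    if tolerance < 0 or int(tolerance) != tolerance:
        raise ValueError("tolerance must be a nonnegative integer")
    entries = []
    for label in sorted(matrix.rows):
        entry = mismatch_count(matrix, matrix.rows[label], obs)
        if entry.mismatches <= tolerance:
            entries.append(entry)
    entries.sort(key=lambda e: (e.mismatches, e.taxon))
    return MatchResult(entries=entries, tolerance=int(tolerance))


# --- best-next-character selection -----------------------------------------


@dataclass
class CharacterGain:
    """Result of greedy character selection; ``char_id`` is None when no
    unanswered character can split the candidates (none informative)."""

    char_id: Optional[str]
    gain_bits: float
    answer_counts: dict[str, int] = field(default_factory=dict)

    @property
    def informative(self) -> bool:
        return self.char_id is not None


def _answer_space(matrix: InducedMatrix, char_id: str,
                  rows: Sequence[ConstraintRow]):
    """Possible answers with a membership test each.

    State-valued characters answer with a state.  Quantitative characters
    answer with a number, so the line is partitioned at every interval
    endpoint occurring in the candidates' constraints; degenerate point
    cells merge with their neighbours.  Each answer is returned as
    (label, IntervalUnion-or-state)."""
    char = matrix.characters[char_id]
    if not char.is_quantitative:
        return [(s, s) for s in char.state_list]
    points: set[float] = set()
    for row in rows:
        con = row.constraint(char_id)
        if con is not None and con.interval is not None:
            points.update(con.interval.endpoints())
    bounds = sorted(points)
    cells: list[tuple[str, IntervalUnion]] = []
    lo = 0.0
    for b in bounds:
        if b > lo:
            cells.append((f"[{lo}..{b})",
                          IntervalUnion((Interval(lo, b, True, False),))))
            lo = b
    cells.append((f"[{lo}..inf)",
                  IntervalUnion((Interval(lo, math.inf, True, False),))))
    return cells


def _compatible_with_answer(matrix: InducedMatrix, row: ConstraintRow,
                            char_id: str, answer) -> bool:
    con = row.constraint(char_id)
    if con is None:
        return True
    if con.contradictory:
        return False
    if isinstance(answer, IntervalUnion):
        return con.interval.intersects(answer)
    return answer in con.states


def next_best_character(matrix: InducedMatrix,
                        candidates: Iterable[str],
                        answered: Iterable[str] = ()) -> CharacterGain:
    """The unanswered character with maximal expected information gain.

    For character c with answers a: C_a = candidates compatible with a,
    p(a) = |C_a| / Σ|C_a′|, and
    gain(c) = log2 |C| − Σ_a p(a) · log2 |C_a|.  Ties break by character
    id; a gain of zero for every character yields a none-informative
    result.
    """
    cand = sorted(set(candidates))
    if len(cand) < 2:
        raise KeyError_("need at least 2 candidates to choose a character")
    rows = [matrix.row(label) for label in cand]
    answered = set(answered)
    best: Optional[CharacterGain] = None
    total_log = math.log2(len(rows))
    for char_id in sorted(matrix.characters):
        if char_id in answered:
            continue
        counts: dict[str, int] = {}
        for label, answer in _answer_space(matrix, char_id, rows):
            n = sum(1 for row in rows
                    if _compatible_with_answer(matrix, row, char_id, answer))
            if n:
                counts[label] = n
        denom = sum(counts.values())
        if not denom:
            continue
        expected = sum((n / denom) * math.log2(n) for n in counts.values())
        gain = total_log - expected
        if gain <= 1e-12:
            continue
        if best is None or gain > best.gain_bits + 1e-12:
            best = CharacterGain(char_id=char_id, gain_bits=gain,
                                 answer_counts=counts)
    if best is None:
        return CharacterGain(char_id=None, gain_bits=0.0)
    return best


def gain_of(matrix: InducedMatrix, candidates: Iterable[str],
            char_id: str) -> float:
    """Expected information gain (bits) of one specific character."""
    rows = [matrix.row(label) for label in sorted(set(candidates))]
    counts = []
    for _label, answer in _answer_space(matrix, char_id, rows):
        n = sum(1 for row in rows
                if _compatible_with_answer(matrix, row, char_id, answer))
        if n:
            counts.append(n)
    denom = sum(counts)
    if not denom:
        return 0.0
    expected = sum((n / denom) * math.log2(n) for n in counts)
    return math.log2(len(rows)) - expected


# --- greedy interactive identification -------------------------------------


def greedy_identify(matrix: InducedMatrix, obs: Observation,
                    max_questions: Optional[int] = None
                    ) -> tuple[list[str], list[str]]:
    """Identify by repeatedly asking the best next character and answering
    from ``obs`` (which must cover the characters asked).

    Returns (remaining candidate taxa, characters asked).  Stops when one
    candidate remains, no character is informative, or the question budget
    is exhausted.
    """
    known = obs.known()
    candidates = sorted(matrix.rows)
    asked: list[str] = []
    while len(candidates) > 1:
        if max_questions is not None and len(asked) >= max_questions:
            break
        step = next_best_character(matrix, candidates, answered=asked)
        if not step.informative:
            break
        asked.append(step.char_id)
        if step.char_id not in known:
            continue  # unanswerable: ask the next-best character
        value = known[step.char_id]
        candidates = [label for label in candidates
                      if value_compatible(matrix, matrix.rows[label],
                                          step.char_id, value)]
    return candidates, asked
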