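"""Packaged fixtures and a synthetic dichotomous-key generator.

``load_fixture`` returns the transcribed *Syagrus* key (71 couplets, 72
terminal occurrences, 65 species and two non-autonym subspecies) and the
accompanying clade and region reference tables.

``generate_key`` builds random valid dichotomous keys with a known
ground-truth taxon × character table, the workhorse of property-based
testing: every couplet splits the surviving value space of one character
into two mutually exclusive, satisfiable parts, so by construction each
taxon's truth row keys out exactly at its own terminal.  Splits are biased
toward balance, with a configurable probability of chain-like splits
(one taxon peeled off) so that deep tails — like the long couplet chain of
the packaged key — are exercised too.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Union

from .model import (
    Character,
    Clause,
    Couplet,
    Interval,
    IntervalUnion,
    Key,
    KeyError_,
    Lead,
    Observation,
    Predicate,
    TaxonOccurrence,
)
from . import keyio
from .congruence import CladeTable, RegionTable

FIXTURE_NAMES = ("syagrus_key", "clades", "regions")

#: default chance of peeling a single taxon off at a couplet (chain split)
DEFAULT_SKEW = 0.2
#: value range of synthetic quantitative characters
_QUANT_LO, _QUANT_HI = 0.0, 100.0


def _fixture_text(filename: str) -> str:
    return resources.files("clavis.fixtures").joinpath(filename) \
        .read_text(encoding="utf-8")


def transcription_notes() -> str:
    """The transcription notes shipped with the Syagrus fixture."""
    return _fixture_text("transcription_notes.md")


def load_fixture(name: str):
    """Load a packaged fixture: ``syagrus_key`` → validated Key,
    ``clades`` → CladeTable, ``regions`` → RegionTable."""
    if name == "syagrus_key":
        key = keyio.parse_key(_fixture_text("syagrus_characters.tsv"),
                              _fixture_text("syagrus_key.tsv"))
        key.require_valid()
        key.metadata.setdefault("transcription_notes",
                                "clavis/fixtures/transcription_notes.md")
        return key
    if name == "clades":
        return CladeTable.from_tsv(_fixture_text("clades.tsv"),
                                   load_fixture("syagrus_key"))
    if name == "regions":
        return RegionTable.from_tsv(_fixture_text("regions.tsv"),
                                    load_fixture("syagrus_key"))
    raise KeyError_(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")


# --- synthetic keys --------------------------------------------------------


@dataclass
class SyntheticKeyBundle:
    """A generated key plus its ground truth.

    ``truth`` maps each taxon's species name to a complete character →
    value assignment that satisfies exactly that taxon's path.
    """

    key: Key
    truth: dict[str, dict[str, Union[str, float]]]
    n_taxa: int
    n_characters: int
    seed: int
    skew: float = DEFAULT_SKEW

    def truth_observation(self, taxon: str) -> Observation:
        return Observation(dict(self.truth[taxon]))


def _make_characters(n_characters: int, rng: random.Random) -> dict[str, Character]:
    chars: dict[str, Character] = {}
    for i in range(n_characters):
        cid = f"char{i + 1:02d}"
        kind = ("binary", "categorical", "quantitative")[i % 3]
        if kind == "binary":
            chars[cid] = Character(cid, f"synthetic binary character {i + 1}",
                                   "binary")
        elif kind == "categorical":
            k = 3 + (i // 3) % 2  # alternate 3- and 4-state characters
            chars[cid] = Character(
                cid, f"synthetic categorical character {i + 1}", "categorical",
                states=tuple(f"s{j}" for j in range(k)))
        else:
            chars[cid] = Character(cid,
                                   f"synthetic quantitative character {i + 1}",
                                   "quantitative", units="unitless")
    return chars


def generate_key(n_taxa: int, n_characters: int, seed: int,
                 skew: float = DEFAULT_SKEW) -> SyntheticKeyBundle:
    """Generate a random valid dichotomous key (deterministic per seed).

    Requires ``n_taxa >= 2`` and ``n_characters >= ceil(log2 n_taxa)``
    (fewer characters cannot discriminate all taxa along a balanced path).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if n_characters < max(1, math.ceil(math.log2(n_taxa))):
        raise ValueError("insufficient characters to discriminate "
                         f"{n_taxa} taxa")
    if not 0.0 <= skew < 1.0:
        raise ValueError("skew must be in [0, 1)")
    rng = random.Random(seed)
    characters = _make_characters(n_characters, rng)
    taxa = [TaxonOccurrence(genus="Synthetica", epithet=f"sp{i + 1:03d}")
            for i in range(n_taxa)]

    couplets: dict[int, Couplet] = {}
    truth: dict[str, dict[str, Union[str, float]]] = {}
    counter = {"next": 1}

    def splittable(allowed: dict) -> list[str]:
        out = []
        for cid, dom in allowed.items():
            char = characters[cid]
            if char.is_quantitative:
                iv = dom  # a single Interval
                if iv.hi - iv.lo > 1e-6:
                    out.append(cid)
            elif len(dom) >= 2:
                out.append(cid)
        return out

    def split_predicates(cid: str, allowed: dict):
        """Two mutually exclusive satisfiable predicates partitioning the
        current domain of a character; returns (pred_a, pred_b, dom_a,
        dom_b)."""
        char = characters[cid]
        if char.is_quantitative:
            iv: Interval = allowed[cid]
            t = rng.uniform(iv.lo + 0.2 * (iv.hi - iv.lo),
                            iv.hi - 0.2 * (iv.hi - iv.lo))
            pa = Predicate(cid, "lt", t)
            pb = Predicate(cid, "ge", t)
            return (pa, pb,
                    Interval(iv.lo, t, iv.lo_closed, False),
                    Interval(t, iv.hi, True, iv.hi_closed))
        states = sorted(allowed[cid])
        rng.shuffle(states)
        k = rng.randint(1, len(states) - 1)
        left, right = frozenset(states[:k]), frozenset(states[k:])

        def pred(subset: frozenset) -> Predicate:
            if len(subset) == 1:
                return Predicate(cid, "eq", next(iter(subset)))
            return Predicate(cid, "in_set", subset)

        return pred(left), pred(right), left, right

    def grow(members: list[TaxonOccurrence], allowed: dict,
             acc: dict):
        """Build the subtree for `members`; returns a target (couplet id or
        taxon occurrence).  `acc` is the path assignment accumulated so
        far (per-character surviving domain)."""
        if len(members) == 1:
            occ = members[0]
            row: dict[str, Union[str, float]] = {}
            for cid2, char in characters.items():
                dom = acc.get(cid2)
                if dom is None:
                    # unconstrained on this path: any in-domain value
                    if char.is_quantitative:
                        row[cid2] = round(rng.uniform(_QUANT_LO, _QUANT_HI), 3)
                    else:
                        row[cid2] = rng.choice(sorted(char.state_list))
                elif char.is_quantitative:
                    lo, hi = dom.lo, dom.hi
                    row[cid2] = lo + (hi - lo) * rng.uniform(0.25, 0.75)
                else:
                    row[cid2] = rng.choice(sorted(dom))
            truth[occ.species_name] = row
            return occ

        cid = counter["next"]
        counter["next"] += 1
        options = splittable(allowed)
        if not options:
            raise KeyError_("insufficient characters to discriminate: "
                            "no splittable character left on this path")
        split_char = rng.choice(sorted(options))
        # chain split with probability `skew`, else balance-biased
        if len(members) > 2 and rng.random() < skew:
            n_left = 1
        else:
            mid = len(members) / 2.0
            n_left = min(len(members) - 1,
                         max(1, round(rng.gauss(mid, len(members) / 6.0))))
        pa, pb, dom_a, dom_b = split_predicates(split_char, allowed)
        leads = []
        for slot, pred, dom, part in (
                ("a", pa, dom_a, members[:n_left]),
                ("b", pb, dom_b, members[n_left:])):
            allowed_child = dict(allowed)
            allowed_child[split_char] = dom
            acc_child = dict(acc)
            acc_child[split_char] = dom
            target = grow(part, allowed_child, acc_child)
            statement = keyio.render_predicate(pred, characters)
            if isinstance(target, TaxonOccurrence):
                leads.append(Lead(cid, slot, statement, (Clause((pred,)),),
                                  target_taxon=target))
            else:
                leads.append(Lead(cid, slot, statement, (Clause((pred,)),),
                                  target_couplet=target))
        couplets[cid] = Couplet(cid, tuple(leads))
        return cid

    full_allowed = {}
    for cid2, char in characters.items():
        if char.is_quantitative:
            full_allowed[cid2] = Interval(_QUANT_LO, _QUANT_HI, True, True)
        else:
            full_allowed[cid2] = frozenset(char.state_list)

    root = grow(list(taxa), full_allowed, {})
    key = Key(characters=characters, couplets=couplets, root=root,
              metadata={"title": f"synthetic key (seed {seed})",
                        "source": "clavis synthetic key generator"})
    key.require_valid()
    return SyntheticKeyBundle(key=key, truth=truth, n_taxa=n_taxa,
                              n_characters=n_characters, seed=seed, skew=skew)
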