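"""Key-branch versus reference-clade congruence, and geographic coherence.

A dichotomous key built on overall anatomical similarity is not a
phylogeny, but its branches can be compared with independently derived
groups: molecular clades, or shared geographic regions.  Three measures
are provided:

* **crown branch** of a taxon group — the deepest lead whose subtree
  contains every group member present in the key (``ROOT`` if only the
  whole key does).  Multi-entry taxa can make several leads co-deepest;
  all are reported.
* **branch purity** — precision (|group ∩ branch| / |branch|) and recall
  (|group ∩ branch| / |group ∩ key|) of a branch against a group, at
  species level.
* **region homogeneity** — the fraction of a branch's species (with known
  ranges) whose region set intersects the branch's modal region.

Reference tables arrive as TSV.  Clade labels are normalized by dropping
any ``/``-suffix ("Rain Forest/ Lytocaryum" → "Rain Forest").  Taxon names
may be abbreviated ("S. weddelliana", "L. itapebiensis"); they are
resolved against the key's species list by epithet, and unresolved names
are reported rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import Key, KeyError_, ROOT_LABEL
from .traversal import branch_membership, subtree_occurrences
from . import keyio

# --- reference tables ------------------------------------------------------

_CLADE_COLUMNS = ("clade", "key_branch", "taxon", "molecular", "listed")
_REGION_COLUMNS = ("taxon", "region_codes")


def normalize_clade_label(label: str) -> str:
    return label.split("/")[0].strip()


def resolve_taxon_name(name: str, key: Key) -> Optional[str]:
    """Resolve a possibly genus-abbreviated name against the key's species
    list by specific epithet; None if no unique match."""
    text = name.strip().rstrip("*").strip()
    epithet = text.split()[-1] if text else ""
    hits = [sp for sp in branch_membership(key, ROOT_LABEL, "species")
            if sp.split()[-1] == epithet]
    if len(hits) == 1:
        return hits[0]
    return None


@dataclass
class CladeTable:
    """Reference groups (e.g. molecular clades) mapped onto the key.

    ``molecular`` holds the members of the underlying analysis;
    ``listed`` the full branch lists a source table prints next to them.
    ``branches`` are the key-branch labels the source associates with each
    clade.  ``unmatched`` reports names that did not resolve against the
    key.
    """

    molecular: dict[str, set[str]] = field(default_factory=dict)
    listed: dict[str, set[str]] = field(default_factory=dict)
    branches: dict[str, list[str]] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def clades(self) -> list[str]:
        return sorted(set(self.molecular) | set(self.listed))

    def members(self, clade: str, membership: str = "molecular") -> set[str]:
        if membership not in ("molecular", "listed"):
            raise ValueError("membership must be 'molecular' or 'listed'")
        table = self.molecular if membership == "molecular" else self.listed
        if clade not in table:
            raise KeyError_(f"unknown clade {clade!r}")
        return set(table[clade])

    @classmethod
    def from_tsv(cls, text: str, key: Key) -> "CladeTable":
        metadata, rows = keyio.read_table(text, _CLADE_COLUMNS, "clades.tsv")
        table = cls(metadata=metadata)
        for row in rows:
            clade = normalize_clade_label(row["clade"])
            table.molecular.setdefault(clade, set())
            table.listed.setdefault(clade, set())
            branches = table.branches.setdefault(clade, [])
            if row["key_branch"] and row["key_branch"] not in branches:
                branches.append(row["key_branch"])
            resolved = resolve_taxon_name(row["taxon"], key)
            if resolved is None:
                table.unmatched.append(row["taxon"])
                continue
            if row["molecular"] == "1":
                table.molecular[clade].add(resolved)
            if row["listed"] == "1":
                table.listed[clade].add(resolved)
        return table


@dataclass
class RegionTable:
    """Taxon → set of geographic region labels."""

    regions: dict[str, set[str]] = field(default_factory=dict)
    vocabulary: set[str] = field(default_factory=set)
    unmatched: list[str] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def of(self, species: str) -> set[str]:
        return set(self.regions.get(species, set()))

    def missing_species(self, key: Key) -> list[str]:
        return sorted(sp for sp in branch_membership(key, ROOT_LABEL, "species")
                      if sp not in self.regions)

    @classmethod
    def from_tsv(cls, text: str, key: Key) -> "RegionTable":
        metadata, rows = keyio.read_table(text, _REGION_COLUMNS, "regions.tsv")
        table = cls(metadata=metadata)
        if "vocabulary" in metadata:
            table.vocabulary = {v.strip()
                                for v in metadata["vocabulary"].split(";")}
        for row in rows:
            resolved = resolve_taxon_name(row["taxon"], key)
            if resolved is None:
                table.unmatched.append(row["taxon"])
                continue
            codes = {c.strip() for c in row["region_codes"].split(";")
                     if c.strip()}
            table.regions.setdefault(resolved, set()).update(codes)
            table.vocabulary.update(codes)
        return table


# --- crown branches and purity ---------------------------------------------


def crown_branch(key: Key, group: Iterable[str]) -> list[str]:
    """Deepest lead subtree(s) containing every group member present in
    the key; ``["ROOT"]`` if no proper lead contains them all."""
    key.require_valid()
    all_species = branch_membership(key, ROOT_LABEL, "species")
    present = {sp for sp in group if sp in all_species}
    if not present:
        raise KeyError_("group has no member present in the key")
    # depth of a couplet = length of its root path
    couplet_depth: dict[int, int] = {}

    def assign_depth(cid: int, d: int) -> None:
        couplet_depth[cid] = d
        for ld in key.couplets[cid].leads:
            if not ld.is_terminal:
                assign_depth(ld.target_couplet, d + 1)

    assign_depth(key.root, 1)

    hits: list[tuple[int, str]] = []  # (depth, label)
    for cid in key.couplets:
        for ld in key.couplets[cid].leads:
            species = {occ.species_name
                       for occ in subtree_occurrences(key, ld)}
            if present <= species:
                hits.append((couplet_depth[cid], ld.branch_label))
    if not hits:
        return [ROOT_LABEL]
    deepest = max(d for d, _ in hits)
    return sorted(label for d, label in hits if d == deepest)


def branch_purity(key: Key, group: Iterable[str],
                  branch_label: str) -> tuple[float, float]:
    """(precision, recall) of a branch against a species group."""
    branch = branch_membership(key, branch_label, "species")
    all_species = branch_membership(key, ROOT_LABEL, "species")
    group_in_key = {sp for sp in group if sp in all_species}
    if not branch:
        raise KeyError_(f"empty branch {branch_label!r}")
    if not group_in_key:
        raise KeyError_("group has no member present in the key")
    hit = len(group_in_key & branch)
    return hit / len(branch), hit / len(group_in_key)


def region_homogeneity(key: Key, regions: RegionTable,
                       branch_label: str) -> float:
    """Fraction of the branch's species (with known ranges) sharing the
    branch's modal region.  Species absent from the region table are
    excluded from the denominator."""
    branch = branch_membership(key, branch_label, "species")
    with_regions = [sp for sp in sorted(branch) if regions.of(sp)]
    if not with_regions:
        raise KeyError_(f"no region data for any species of branch "
                        f"{branch_label!r}")
    counts: dict[str, int] = {}
    for sp in with_regions:
        for code in regions.of(sp):
            counts[code] = counts.get(code, 0) + 1
    modal = min((code for code in counts
                 if counts[code] == max(counts.values())))
    share = sum(1 for sp in with_regions if modal in regions.of(sp))
    return share / len(with_regions)


# --- full report -----------------------------------------------------------


@dataclass
class CladeCongruence:
    clade: str
    members: list[str]
    crown: list[str]
    crown_precision: float
    crown_recall: float
    named_branches: dict[str, tuple[float, float]]


@dataclass
class CongruenceReport:
    clades: list[CladeCongruence]
    branch_homogeneity: dict[str, float]
    unmatched_names: list[str]


def congruence_report(key: Key, clades: CladeTable,
                      regions: Optional[RegionTable] = None,
                      membership: str = "molecular") -> CongruenceReport:
    """Crown/purity per clade plus region homogeneity per named branch."""
    out: list[CladeCongruence] = []
    homogeneity: dict[str, float] = {}
    for clade in clades.clades:
        members = sorted(clades.members(clade, membership))
        if not members:
            continue
        crown = crown_branch(key, members)
        prec, rec = branch_purity(key, members, crown[0])
        named = {}
        for label in clades.branches.get(clade, []):
            named[label] = branch_purity(key, members, label)
            if regions is not None and label not in homogeneity:
                homogeneity[label] = region_homogeneity(key, regions, label)
        out.append(CladeCongruence(clade=clade, members=members, crown=crown,
                                   crown_precision=prec, crown_recall=rec,
                                   named_branches=named))
    return CongruenceReport(clades=out, branch_homogeneity=homogeneity,
                            unmatched_names=list(clades.unmatched))
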