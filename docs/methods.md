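# Methods

## The key model and its assumptions

A single-access key is modelled as a rooted strictly dichotomous tree:
couplets are internal nodes with exactly two leads; every couplet except
the root is the target of exactly one lead; terminals are *taxon
occurrences* — a canonical name (`Genus epithet[ subsp. infra][|form]`)
plus an occurrence index, because variable taxa may key out in several
places.  Form qualifiers ("high elevation form") are occurrence metadata,
never taxa: species-level operations merge them, as the source treats both
elevation forms as one species.  Non-autonym subspecies, by contrast, are
their own taxa at matrix level (hence 65 + 2 rows), while the autonym
collapses into its species.

Lead codings are conjunctions of clauses, each clause a disjunction of
predicates.  Two semantic commitments shape everything downstream:

1. **A lead asserts only its own statement.**  The complement of the
   sibling lead is never inferred, because printed alternates are worded
   independently and are frequently not logical complements ("none or only
   weakly visible" vs "present and obvious").  Mutual exclusivity is
   therefore a *checked* property, not an assumption: validation warns
   about any couplet whose two leads are jointly satisfiable.  The
   packaged key has no such couplet.
2. **Unmentioned is unconstrained.**  A character absent from every lead
   on a taxon's path is absent from its matrix row; it is never defaulted,
   and it is compatible with any observed value during matching.

Multi-character disjunctions ("attached to both surfaces and/or hairy
trichomes") cannot be collapsed into one per-character set; they are kept
as *residual clauses* of the matrix row and participate in compatibility
checks and in the satisfiability test behind the exclusivity warning.
That test intersects per-character sets exactly and checks residual
clauses one at a time against the intersection, which can only
over-report satisfiability — it may warn unnecessarily, never miss.

## Traversal semantics

Lead evaluation is three-valued: true (every clause satisfied), false
(some clause refuted), undetermined (an unobserved character blocks a
clause).  Strict mode follows a couplet only when one lead is true *and*
the other false; anything else halts with the couplet reported — the
undecidable couplet is exactly what an interactive session should ask
about next.  Explore mode descends every non-failing lead and returns the
union of reachable terminals, the right behaviour for fragmentary
specimens.  A couplet whose two leads are both true is reported as a
contradiction (the observation is inconsistent with the key's contrast),
never resolved silently.

## Matrix induction

Occurrence rows intersect all predicates along the root path per
character; quantitative constraints are canonical interval unions over the
nonnegative half-line (measurements and counts), so "less than 0.25 mm"
becomes `[0..0.25)`.  Empty intersections are flagged contradictory and
reported, never dropped — the packaged key has none.  Taxon rows union
their occurrences' constraints **per mentioning occurrence**: an
occurrence silent about a character does not widen the constraint
contributed by occurrences that mention it.  This keeps, e.g., a rachis
length recorded on one of a species' two paths informative at taxon level
instead of dissolving into "anything".  When two occurrences admit
disjoint values for a character the taxon is flagged polymorphic there,
and matching treats any value inside the union as compatible —
identification stays conservative because the underlying sampling
understates real variation.

Soundness is the central invariant: keying a representative observation
drawn from an occurrence's own row (residual clauses included) must reach
exactly that occurrence in strict mode.  It holds for all 72 fixture
occurrences and for every synthetic key tested.

## Polyclave matching and character selection

A taxon's mismatch count against an observation is the number of observed
characters whose value falls outside the taxon's constraint, plus one per
residual clause all of whose alternatives are refuted.  `match` returns
all taxa within an integer tolerance, ranked ascending with alphabetical
ties.  Candidate sets are monotone in the tolerance by construction.

`next_best_character` scores each unanswered character by expected
information gain over the answer space: the states for state-valued
characters; for quantitative characters, the partition of the line at
every interval endpoint occurring in the candidates' constraints
(half-open cells; degenerate point cells merge with their neighbours by
construction).  Answer probabilities are proportional to compatible
candidate counts, so gain is always nonnegative and zero exactly when no
answer splits the candidates; ties break by character id for determinism.

## The predicate DSL and file formats

Keys travel as two UTF-8 TSV files (ontology + leads) with `#`-comment
metadata; the DSL uses `;` for conjunction, `|` for disjunction, `=`,
`!=`, comparisons, `in {a,b}`, and ranges `a..b` / `a..` / `..b` (closed;
strict bounds via comparisons).  Writing is canonical (sorted characters,
sorted leads, deterministic occurrence indices), so write∘parse is the
identity on canonical text and parse∘write is structural identity —
both are property-tested.  The Newick export labels internal nodes
`c<couplet>` and leaves with occurrence labels, all branch lengths 1;
tests re-parse it with an independent Newick library and check topology
against the couplet graph.

## Transcribing the Syagrus key

Deterministic rules beat ad-hoc judgment: "less than x" → strict `<`;
printed ranges `a–b` closed; `a–b+` open above; "ca. x" → `[0.9x, 1.1x]`
(which deliberately keeps "ca. 100 cm" disjoint from the alternate lead's
167–440 cm); abundance words on one ordinal scale per structure; compound
leaflet dimensions split into length and width.  Each of the 142 leads
received at least one coded predicate, and every couplet has a shared
character on which its leads exclude each other — this is what makes the
whole printed key sound under strict traversal.  The individual judgment
calls (a typographical species name, two printed adaxial/abaxial slips,
the ordinal visibility scale of couplet 19) are listed in
`src/clavis/fixtures/transcription_notes.md`, which ships with the
package.

The clade table keeps two membership notions: `molecular` (the taxa in the
underlying DNA analysis) and `listed` (the full branch lists printed next
to them) — they differ, e.g. *S. flexuosa* is molecularly cluster-stemmed
but keys out in the rain-forest branch, and the branch-18 list omits
*S. evansiana* though it keys there.  Region strings follow the source
table (state qualifiers dropped, compound strings split); species absent
from it are reported as missing rather than guessed.

## The synthetic-key generator

`generate_key(n_taxa, n_characters, seed, skew=0.2)` draws a random
dichotomous key over a mixed ontology (binary, 3–4-state categorical,
quantitative on [0, 100]).  Each couplet partitions the *surviving* domain
of one character into two non-empty parts — a state-set split or a
threshold split — so predicates along any path are nested and every
couplet is discriminating by construction.  Splits are balance-biased
(Gaussian around the midpoint); with probability `skew` (default 0.2) a
single taxon is peeled off instead, producing the deep chains a realistic
key has (the packaged key runs to depth 11).  The ground-truth table
assigns every taxon a full observation: in-constraint values on its path,
arbitrary in-domain values elsewhere.  One seeded stream drives all
choices, so bundles are bit-reproducible.

What the generator does *not* emulate: observation error, missing data
patterns, correlated characters, or polymorphic (multi-entry) taxa.
Passing the synthetic suite therefore demonstrates the engine's logic
(round trips, soundness, exactness, gain properties), not robustness to
noisy real-world scoring — the error-tolerance parameter of `match` exists
for that use but is exercised only with clean data.

## Problem sizes and numerical choices

The packaged key (71 couplets) computes everything in milliseconds; the
test suite and the acceptance script use 20 synthetic keys of 10 taxa × 8
characters, chosen to cover unbalanced shapes and all three character
kinds while keeping the whole suite around two seconds.  Floating-point
interval endpoints are compared exactly (they come from the same parsed
literals); gain comparisons use a 1e-12 slack for tie detection.
Quantitative domains start at 0 because every measured character is a
nonnegative length or count.

## Known limitations

- Strict traversal requires the observation to decide each couplet
  against both leads; observations that satisfy one lead while leaving
  the sibling undetermined halt as ambiguous rather than descending.
- Mismatch counting weights all characters equally; there is no
  observation-cost or reliability weighting.
- No probabilistic (Bayesian) identification — matching is set and
  interval logic.
- The congruence module computes containment and purity measures only; it
  is not a phylogenetic reconciliation and the key tree is not a
  phylogeny.
- Region homogeneity uses the species with known ranges as denominator;
  with the packaged table (transcribed from a source that lists regions
  only for the species in its comparison rows) 26 species have no region
  data and are excluded.
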