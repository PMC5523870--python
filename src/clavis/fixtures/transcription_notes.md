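# Transcription notes for the packaged *Syagrus* key

The key, character checklist, clade comparison table and region data were
transcribed by hand from the published leaflet-margin anatomical key to
*Syagrus*.  Lead statements are kept verbatim; the coded predicates are a
deterministic reading of each statement against the character ontology in
`syagrus_characters.tsv`.  Points where transcription required a judgment
call are recorded here.

## Deterministic coding rules

- "less than x" → strict `<x`; "x or more" / "x or thicker" → `>=x`.
- Printed ranges "a–b" → closed interval `a..b`; "a–b+" → `a..` (open
  above); "ca. x" → `0.9x..1.1x` (couplet 59: "ca. 100 cm" becomes
  `90..110`, deliberately disjoint from the alternate lead's `167..440`).
- Qualitative abundance words (none / few / occasional / many) are coded
  on one ordinal scale per anatomical structure.
- Compound leaflet measurements ("24–34 × 2–3 cm") are split into two
  quantitative characters, length and width.
- A lead's coding covers only its own statement; the logical complement of
  the sibling lead is never inferred.
- "and/or" contrasts (couplets 5, 7, 19, 53) are coded as disjunctive
  clauses (`|` in the predicate DSL).

## Individual judgment calls

- Couplet 14: the printed terminal "S. caerulescen" is a typographical
  slip and is transcribed as *S. caerulescens*.
- Couplet 22: the terminal *S. comosa* is typeset unlike the other
  terminals in the source; it is treated as a normal terminal.
- Couplet 19/19′: "none or only weakly visible" versus "present and
  obvious" is coded on a three-step ordinal visibility scale
  (absent < weak < present) for abaxial minor veins.
- Couplet 51′: the source reads "not usually opposite **adaxial** minor
  veins" where the first lead contrasts adaxial fiber bundles with
  **abaxial** minor veins; the statement is kept as printed and the coding
  uses the mirrored/dorsiventral symmetry character of couplet 51.
- Couplet 68′: the source reads "fibers or fiber bundles along the
  **abaxial** surface" in a couplet otherwise about the adaxial surface;
  the statement is kept as printed and the shared machine contrast is the
  abaxial vein with exaggerated fibrous sheath (absent / present).
- Elevation forms of *S. harleyi* ("high elevation form", "low elevation
  form") are occurrence qualifiers, not taxa; species-level counting
  merges them.  The high elevation form keys out twice (couplets 27 and
  52′), matching the source's remark that it may key out early when its
  abaxial minor veins are read as mesophyll veins.
- The *S. graminifolia* subspecies (couplets 16–17) are distinct terminal
  names; the autonym subspecies collapses into the species for
  species-level counts, the two non-autonym subspecies are their own
  taxon-level matrix rows.

## Clade and region tables

- Clade labels normalize by dropping any "/"-suffix ("Rain Forest/
  Lytocaryum" → "Rain Forest"), giving three clades.
- The asterisk flags of the source table (members of the original
  molecular analysis) are entangled with typographic italics in the
  available text; a taxon is flagged `molecular` exactly when it appears
  in the table's molecular-clade column.  Under that rule *S. flexuosa* is
  molecular (Cluster-stemmed clade) though it keys out in branch 57′, and
  *S. ruschiana* is molecular (Rain Forest) though absent from the printed
  branch-57′ species list (it keys out at couplet 34).
- The branch-18 species list of the source omits *S. evansiana* although
  it keys out under couplet 25′; the key itself is authoritative and the
  list is kept as printed.
- Region strings follow the source table, with parenthesised state
  qualifiers dropped and compound strings split ("E. & Central Brazil" →
  Eastern Brazil + Central Brazil; "Andes/Amazon" → Andes + Amazon).
  *S. petraea* keeps region "Bolivia" as printed.  The single-letter
  region codes of the key-outline diagrams (C, E, N, S plus country
  abbreviations) are recorded as the declared vocabulary.
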