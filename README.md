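# clavis

An engine for **single-access (dichotomous) identification keys**: encode a
key as data, validate its structure, execute it against observations,
invert it into a taxon × character matrix, identify specimens
polyclave-style from any subset of characters, and compare key branches
with independently derived groups (molecular clades, geographic regions).

The package ships a complete worked dataset: the 71-couplet anatomical key
to the Neotropical palm genus *Syagrus* (Arecaceae), built on characters of
the leaflet margin in cross-section — fiber bundle extent and shape, minor
vein placement, marginal veins with exaggerated fibrous sheaths, hypodermis
structure, lamina thickness and a few gross-morphological characters.  The
key covers all 65 species and two non-autonym subspecies of the genus in 72
terminal leads (polymorphic species key out more than once), and is useful
for identification when flowers and fruits are unavailable.

## Who this is for

Taxonomists and biodiversity informaticians who work with printed
dichotomous keys and want them machine-executable; anyone building
interactive or multi-access identification tools over legacy keys; and
palm systematists who want the *Syagrus* anatomical key in a queryable
form.

## The model

A key is a rooted binary tree.  Internal nodes are *couplets* — numbered
decision points with exactly two contrasting *leads* (rendered `n` and
`n′`).  Each lead carries its verbatim statement plus a machine coding: a
conjunction of clauses over a declared character ontology, where each
clause is a disjunction of predicates (`char=state`, `char in {a,b}`,
`char<0.25`, `char in 9..`).  Characters are binary, categorical, ordinal
or quantitative (with units).

Three computations build on this:

* **Traversal** — three-valued lead evaluation (match / fail /
  undetermined) in a *strict* mode that halts at the first undecidable
  couplet, and an *explore* mode that unions all terminals compatible with
  a partial specimen.
* **Matrix induction** — intersecting all predicates along each terminal's
  root path yields that occurrence's constraint row; taxon rows union the
  rows of a taxon's occurrences, flagging characters where occurrences
  disagree as polymorphic.
* **Polyclave matching** — a specimen's observed characters are scored
  against every taxon row (mismatch counts with an error tolerance), and
  `next_best_character` picks the question with maximal expected
  information gain, `gain(c) = log₂|C| − Σₐ p(a)·log₂|Cₐ|` with `p(a)`
  proportional to the candidates compatible with answer `a`.

Congruence measures (crown branch of a group, branch precision/recall,
region homogeneity) quantify how key branches line up with reference
clades; a synthetic-key generator with known ground truth backs the
property-based test suite.

## Worked example

Identify a specimen from five anatomical observations
(`examples/macrocarpa_observation.tsv`):

```
char_id	value
adaxial_fb_extent	over_one_third
mesophyll_minor_veins	few_or_none
marginal_vein_exaggerated	absent_or_small
adaxial_minor_veins	absent
lamina_thickness	0.2
```

```sh
$ clavis identify syagrus --obs examples/macrocarpa_observation.tsv
status	identified
path	1a 2a 3b 10b 12a
outcome	Syagrus macrocarpa#1
```

The specimen ran couplets 1 → 2 → 3 → 10 → 12 (large adaxial fiber
bundles; few mesophyll minor veins; no dominant marginal vein; no adaxial
minor veins; lamina thinner than 0.25 mm) and keyed out as *S. macrocarpa*.

The same from Python, plus the inverted matrix:

```python
>>> import clavis
>>> key = clavis.load_fixture("syagrus_key")
>>> m = clavis.induce_matrix(key, level="taxon")
>>> clavis.constraint_of(m, "Syagrus macrocarpa", "lamina_thickness").render()
'[0..0.25)'
>>> clavis.crown_branch(key, ["Syagrus itapebiensis", "Syagrus weddelliana",
...                           "Syagrus hoehnei", "Syagrus insignis"])
['53']
```

The four species of the former genus *Lytocaryum* all sit below lead 53 —
the key groups them exactly as the molecular analysis did.  Other commands:

```sh
$ clavis branch syagrus --label "53"     # 4 Atlantic Forest species
$ clavis metrics syagrus                 # depths: min 4, max 11, mean 7.18
$ clavis matrix syagrus --out matrix.csv
$ clavis export-newick syagrus
$ clavis congruence syagrus --format json
$ clavis simulate --n-taxa 12 --n-characters 8 --seed 7 --out-dir /tmp/key7
```

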