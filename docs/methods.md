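# Methods

## The validation model

A register snapshot *R* and a field audit *F* are two point datasets of
food outlets over the same study area.  The field audit is treated as the
gold standard.  Validation proceeds by partitioning the records inside a
set of sampled 250 m study cells into

- **TP** — register records with a one-to-one field match on name and
  location,
- **FP** — register records with no field match (closed, moved, renamed
  beyond recognition, or phantom entries),
- **FN** — open field outlets with no register match (unregistered or
  unmatched),

and summarising the partition as sensitivity TP/(TP+FN) and positive
predictive value TP/(TP+FP).  Permanently closed storefronts found in the
field are recorded by name and location but never matched and never count
as false negatives.  Proportions are labelled on the Landis scale
(<0 poor, 0–0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80
substantial, 0.81–1.00 almost perfect; boundary values take the band whose
printed range contains them, so 0.20 is "slight" and values in
(0.20, 0.21) are "fair").

## Classification

Branch codes alone are too coarse, so classification combines a DB07
branch code with name rules.  Rules live in an editable TSV
(`data/rules.tsv`): each maps (branch-code set, normalized term) to a
fine-grained category.  Chain names match as substrings of the normalized
name; generic product words (burger, pizza, kebab, …) match as whole
tokens to limit false hits.  When rules disagree, the longest matching
term wins — longer terms are more specific ("burger king" beats
"burger") — and a length tie between categories leaves the record
unclassified.  Unclassified records fall through to a manual-annotation
file (the stand-in for a virtual audit, which cannot be automated);
systematic outcomes take precedence over contradicting annotations,
mirroring the two-stage order of the procedure.

Fine categories map into six classifications through a fixed membership
table in which four classifications carry nested narrow ⊆ moderate ⊆ broad
definitions (encoded as each category's *minimal* definition, which makes
the nesting hold by construction).  Fruit & vegetable and miscellaneous
carry a single, definition-free membership set.  One outlet may belong to
several classifications (e.g. bakery chains sit in both broad fast food
and broad restaurants); per-class statistics count it in every cell it
belongs to.

## Name normalization and tiers

Normalization casefolds, strips punctuation and Danish legal-form
suffixes (ApS, A/S, I/S, v/ …), preserves å/ø/æ and accents, and is
idempotent.  Matching grades name agreement as

- **same** — identical after normalization;
- **similar** — one token set contains the other, or the character
  similarity reaches 0.6.  Similarity is the `difflib` ratio boosted by
  the best same-length window of the longer string, so a registered name
  embedded in a longer banner ("Mon Solo" vs "Non Solo Trattoria") still
  scores high while unrelated names do not;
- **tolerable** — both names map to an overlapping product-keyword set
  through the shipped lexicon (`data/lexicon.tsv`), capturing same-type
  matches such as "Dominos" vs "Pizza Group".

## Matching and assignment

Candidate pairs need a tier above *none* and spatial agreement: both
records inside the study cell (any in-cell separation), or a great-circle
distance strictly below 50 m when either lies outside.  The 50 m rule is
applied symmetrically to whichever record lies outside the cell.
Distances use the haversine formula on a 6,371 km sphere.  Candidates are
assigned one-to-one greedily by descending tier, then ascending distance,
then ascending record ids; property tests confirm the greedy assignment
equals the exhaustive lexicographic optimum on instances up to 6×6.
Across cells, a register record claimed by one grid is excluded from
later grids (cells processed in id order), keeping the global assignment
one-to-one.  Register records assigned to no study cell fall outside the
evaluation, as in a grid-sampled field design.

## Grids and sampling

Cells are squares in a spherical transverse-Mercator projection centred
on the region centroid — locally accurate metres with no external CRS
machinery; the lattice is anchored at integer multiples of the cell size,
making grid construction deterministic.  Boundary-straddling cells with
positive overlap are kept.  Outlets are assigned point-in-cell, boundary
points to the smaller cell id.  Study cells are drawn in seeded random
order among occupied cells until every (classification, definition) cell
holds at least the coverage fraction (default 10%) of that type's
outlets — the coverage criterion counts outlets, not grids.  Expected-
empty cells are a seeded sample (default 32) of cells with zero register
outlets, optionally restricted by a candidate mask polygon; their
correctness is judged against what the field survey found there.

## Confidence intervals and quantiles

Per-class PPVs are computed over location-matched pairs only: among pairs
whose register side belongs to a (classification, definition) cell, the
share whose field-side classification agrees.  Intervals are Wald,
p ± 1.959964·√(p(1−p)/n) clipped to [0, 1] (Wilson is available behind a
flag); Wald was chosen because it reproduces the reference intervals this
design is calibrated against at two-decimal rounding.  Positional error
is the median and Q3−Q1 of matched-pair distances with type-7
(linear-interpolation) quantiles.  Statistics with empty denominators
return NaN rather than raising, so reports can always be assembled.

## The synthetic generator

`synthetic_data` emulates the discrepancy structure of a register
validated against a field audit.  Defaults are the study regime:

| parameter | default | meaning |
|---|---|---|
| `n_outlets` | 1,880 | true outlets; with the rates below the register holds ≈1,861 records and the field ≈1,880 |
| `p_unregistered` | 0.25 | true outlet absent from the register (→ FN) |
| `p_stale` | 0.24 | stale register entries per true outlet (→ FP) |
| `position_error_median` | 13.61 m | median of the half-normal jitter magnitude |
| `name_noise` | banner | legal suffixes, dropped descriptors, owner markers; 2% uninformative renames |
| `p_misclassify_register` | 0.05 | register-side category (branch code + annotation) wrong |
| `p_field_missed` | 0.0 | surveyor misses an open outlet |
| `p_closed_observed` | 0.3 | stale entry encountered as a closed storefront |

The region defaults to a 4.75 km square (≈361 cells of 250 m, about five
outlets per cell); the grid is built over the region plus a 750 m margin
so register-empty cells exist.  Positional jitter is isotropic with a
half-normal magnitude parameterised by its median (σ = median/Φ⁻¹(0.75));
only median-level statistics are asserted against it, since any family
matching the observed median is admissible.  Names come from shipped
per-category pools (real chain banners plus generated non-chain names),
and banner-noise operators are explicit text edits so each matcher tier
is exercised deterministically in unit fixtures.  Stale entries draw
plausible names from the same pools and may collide with live outlets,
stressing the one-to-one assignment.  Register and field views consume
distinct seeded substreams, so each view is reproducible independently.

What the generator does **not** emulate: spatial clustering along street
networks (placement is uniform), shopping-mall geocoding artefacts,
surveyor route effects, and systematic category-dependent registration
gaps.  Passing parameter-recovery tests therefore shows the pipeline is
internally consistent at the study's error regime, not that any
particular real register meets these rates.

## Problem sizes and bookkeeping equivalence

Tests run the full pipeline at 1,880 true outlets (the study scale) and
smaller worlds of 150–300 outlets for pipeline/bookkeeping equivalence,
with density held near five outlets per cell.  The generator's
`truth_table` gives exact expected confusion counts independent of the
matcher; pipeline counts agree with it up to two effects inherent to the
design: stale-entry name collisions absorbed as matches, and field
outlets in cells that contain no register outlet, which a register-driven
grid selection can never sample.  The equivalence tests budget for both.

## Known limitations

- The shipped rule set covers the chains and product words of the source
  taxonomy; applying the classifier to a real register requires extending
  `rules.tsv` (it is data, not code).
- Deduplication is deterministic (normalized name + address, or a 5 m
  position fallback) and reports groups for human review; it does not
  attempt probabilistic record linkage, which is outside this design.
- The empty-grid statistic needs field observations inside the flagged
  cells; with a field view restricted to study cells it reflects only
  what was surveyed.
- Geocoding of free-text addresses is out of scope; positions must be
  supplied.
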