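# foodscape

Tools for validating an administrative register of retail food outlets
against ground-truthed field audits.

Administrative food-business registers (in Denmark, the government
food-safety inspection register) are a cheap, nationally complete source
for describing the *foodscape* — the distribution of food outlets across a
geographic area — but their completeness and accuracy must be established
before they can stand in for costly street-by-street field audits.  This
package implements that validation as a reproducible pipeline:

1. **Classification** — register records are filtered to food-retail DB07
   branch codes and classified by a systematic name-recognition procedure
   (chain names and product words combined with branch codes), with a
   manual-annotation fallback for records the rules cannot place.  The
   resulting categories map into six classifications (fast food,
   convenience, supermarket, restaurant, fruit & vegetable, miscellaneous),
   four of which carry nested *narrow ⊆ moderate ⊆ broad* definitions.
2. **Grid sampling** — the study region is tiled with 250 m × 250 m cells
   in a local transverse-Mercator projection; study cells are drawn at
   random until they contain at least 10% of every outlet type, and a set
   of register-empty cells is sampled to probe true-negative agreement.
3. **Matching** — register and field records are paired one-to-one within
   each study grid when their names are *same*, *similar* (token
   containment or character similarity ≥ 0.6) or *tolerable* (shared
   product-keyword, e.g. "Dominos" vs "Pizza Group"), and their positions
   agree (both inside the grid, or < 50 m apart when one lies outside).
4. **Validity statistics** — from the resulting partition into true
   positives (TP), false positives (FP) and false negatives (FN):

   - sensitivity = TP / (TP + FN) — how completely the register captures
     outlets actually present in the field,
   - PPV = TP / (TP + FP) — how many register entries are confirmed open
     where listed,

   with Wald 95% confidence intervals, Landis-scale qualitative labels,
   per-classification PPVs over matched pairs, the positional-error
   median ± IQR, the empty-grid agreement proportion, and an
   inspection-date split of FP vs TP.
5. **Synthetic data** — a seeded generator produces paired register/field
   datasets with a known ground truth and controllable error processes
   (unregistered outlets, stale register entries, banner-name noise,
   positional jitter with a configurable median), so the entire pipeline
   is testable end-to-end without any external data.

## Worked example

Simulate a study-scale world (1,880 true outlets; by default a quarter are
unregistered, a 24% stale-entry rate, banner-name noise, 13.61 m median
positional jitter) and validate the register view against the field view:

```sh
foodscape -q simulate --n-outlets 1880 --seed 4 --coverage 1.0 --out sim
foodscape -q validate sim/register.csv sim/field.csv sim/grids.geojson \
    --truth sim/truth.json --out report
```

```
Register validity against field audit
==============================================
register records: 1902   field outlets: 2037
TP=1401  FP=501  FN=470
sensitivity: 75% (substantial)
PPV:         74% (substantial)
positional error: 13.40 ± 17.72 m (median ± IQR)
empty grids correct: 100%

classification      definition    TP   FP        PPV (95% CI)  % systematic
fast_food           narrow        83    3    0.97 (0.93-1.00)           89%
fast_food           moderate     368    8    0.98 (0.96-0.99)           90%
...
recovery deltas vs bookkeeping: TP -17  FP +17  FN +8
```

Reading this: of 1,902 register records evaluated inside the study grids,
1,401 were confirmed open at their listed position (PPV 74%), while 75% of
the 1,871 open field outlets had a register match (sensitivity) — both
"substantial" on the Landis scale.  Matched pairs sat a median 13.40 m
from their registered coordinates, recovering the 13.61 m jitter the
generator injected.  The final line compares the matcher's confusion
counts against the generator's exact bookkeeping: the small deltas are
name-collisions between stale entries and live outlets plus field outlets
in cells the register-driven grid design cannot select.

The same steps are available as library calls (`generate_world`,
`derive_register_view`, `derive_field_view`, `build_grid`,
`select_study_grids`, `run_validation`) for use from Python.

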