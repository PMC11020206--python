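# Methods

This note records the statistical model, the synthetic study conditions, and
the design choices behind nhaneskit, in the spirit of a package vignette.

## Estimand and estimator

The data model is a stratified multi-stage cluster sample: strata *h*,
primary sampling units (PSUs) *j* within strata, and respondents *i* with
person-level sample weights *wᵢ* equal (in the synthetic fixtures, exactly)
to inverse inclusion probabilities. The target is the finite-population mean
of an analysis variable *y*, possibly within a subpopulation ("domain") *D*.

The estimator is the weighted ratio mean ȳ_w = Σ_D wᵢyᵢ / Σ_D wᵢ. Its
variance is estimated by Taylor linearization with the with-replacement
first-stage approximation: per-row scores uᵢ = wᵢ(yᵢ − ȳ_w)/W inside the
domain and 0 outside, aggregated to PSU totals z_hj, then

Var = Σ_h n_h/(n_h − 1) Σ_j (z_hj − z̄_h)²,

with n_h the number of PSUs of the **full** design in stratum h. Rows with
missing *y* inside the domain contribute zero score (complete-case within
domain); `n_obs` reports the count that actually contributed.

Three consequences are load-bearing and are asserted by the test suite:

- **Degenerate limit.** One stratum, each row its own PSU, equal weights
  reduces Var to s²/n exactly, so SE = sd/√n (checked to 1e−12 relative).
- **Scale invariance.** Multiplying all weights by c > 0 changes neither the
  estimate nor the SE.
- **Domain vs deletion.** Subsetting edits only a row mask; the stratum/PSU
  census is frozen at `make_design`. Deleting out-of-domain rows first gives
  a different (generally understated) variance whenever a PSU is emptied;
  the suite constructs exactly that case. This is why the design object must
  be created before any subsetting.

Only means and domain/grouped means are implemented. Totals, ratios of two
variables, regression, quantiles, and replicate-weight (BRR/jackknife)
variance are out of scope; multi-cycle weight rescaling is left to the
analyst.

### Lonely PSUs

A stratum with a single PSU has no between-PSU variance. The default policy
is to raise (`error`), matching conservative practice; `centered` takes the
lonely PSU's deviation about the grand mean of all PSU totals, and
`certainty` lets the stratum contribute zero variance. The end-to-end recipe
uses `centered` so that a stray lonely stratum degrades gracefully rather
than aborting an analysis.

## Synthetic study conditions

The fixture generator (`nhaneskit.fixtures`) draws one finite population and
emulates the published artifacts around it. Defaults, chosen once as the
package's standing study conditions:

- **Population**: 24 000 persons, 15 strata, 4 population PSUs per stratum
  (near-equal allocation). The released design mirrors a masked public-use
  file: pseudo-stratum, pseudo-PSU (1..2), and one examination-style weight.
- **Groups**: gender 1/2 at 50/50; five ethnicity codes with population
  shares (0.15, 0.10, 0.45, 0.20, 0.10) and the published label set
  ("Mexican American" … "Other race—including multiracial").
- **Outcome**: a diastolic-blood-pressure-like variable in mmHg with
  per-ethnicity means (74.0, 73.5, 71.0, 76.0, 74.0), an age slope of
  0.05 mmHg/yr about age 45, PSU-level intercepts with sd 1.5 (so clustering
  is real), and residual sd 9.
- **Sampling**: 2 of 4 PSUs per stratum by SRS, then Bernoulli sampling of
  persons with rate 0.12 × ethnicity multiplier (2.0, 1.6, 0.55, 1.6, 1.0)
  × age-band multiplier (1.4 under 20, 0.8 for 20–59, 1.6 for 60+). Weights
  are exact inverse inclusion probabilities, (M/m)/rate. Expected sample
  size ≈ 2000. The rates are deliberately informative: oversampled groups
  have higher outcome means, so the unweighted mean is biased upward by
  about +1 mmHg while the weighted estimator is unbiased — this designed
  contrast is what the parameter-recovery tests assert (500 replicate
  samples; the replicate-mean of the weighted estimates must sit within 3
  Monte-Carlo SEs of the population mean).
- **Coarsening**: ages released as min(age, 80); income-to-poverty ratio
  capped at 5.00. The codebook mixes a "Range of Values" row with the
  single top code, which is exactly the pattern `flag_coarsened` detects.
- **Skip pattern**: a gate question (35% "Yes", small item nonresponse)
  routes "No"/"Don't know" answerers past a follow-up, which is therefore
  structurally missing for exactly those rows; the codebook carries the
  Skip-to-Item annotations. Gate-"Yes" rows always have an answered
  follow-up, so after `apply_skip_fill` the only remaining missings are the
  unanswered gates.

What the fixtures do **not** emulate: NHANES's four-stage selection,
post-stratification/nonresponse calibration of weights, oversampling by
screener, pandemic-combined weighting, or realistic inter-variable
correlation structure beyond the outcome model above. Passing tests
therefore validate the *estimators and plumbing*, not any substantive claim
about real survey data.

## File formats and parsing

- **XPT**: SAS transport v5 only (the format the survey publishes); v8/v9
  headers are rejected with a clear error. Numeric cells are IBM/370
  doubles; encoding uses exact bit manipulation (53-bit significand shifted
  into the 56-bit hex fraction), so IEEE→IBM→IEEE is lossless and the
  general round trip is within 2⁻⁵² relative. Missing sentinels
  ('.', '._', '.A'–'.Z') are preserved as strings in `XptTable` and mapped
  to NaN only at the DataFrame boundary. Character cells are right-stripped;
  an empty string stays "" (the survey uses numeric sentinels for
  missingness, not blanks). Short numeric storage (2–7 bytes) is
  zero-extended before decoding. Row count is inferred from the byte length;
  trailing all-blank rows inside the final sub-80-byte padding are dropped —
  an all-blank *character-only* final row is therefore indistinguishable
  from padding, a known limit shared with other readers. Timestamps are
  written from a fixed epoch so fixture files are byte-reproducible.
- **Codebooks**: the modern dialect (anchored per-variable blocks with a
  definition list and a value table) is parsed first, with a lenient
  fallback that scans definition lists anywhere. Counts tolerate thousands
  separators; non-numeric counts become 0 with a warning (counts are
  informational). "End of Section" skip targets normalize to a sentinel.
  Check-item blocks are retained with a `doc_only` flag rather than dropped.
  A plain-text key-value cache format round-trips parsed codebooks exactly.
- **Manifests**: one record per data row; withdrawn/limited-access rows are
  excluded and logged; duplicate table names are an error.
- **Naming**: the suffix rule (letter k ↦ start year 1999 + 2(k−1), no
  suffix ↦ 1999–2000, P_ prefix ↦ the combined 2017–March 2020 release) is
  backed by an extensible overrides table seeded with the known irregular
  names; anything unparseable raises instead of guessing.

## Translation rules

A variable is translated only when it is a *pure* coded categorical: at
least two single-valued code rows whose descriptions are not "Range of
Values"/"Missing", and no range row at all. A variable that mixes a numeric
range with special codes (top-coded age, capped income ratio) stays numeric
and is reported by `flag_coarsened` instead — translating it would destroy
the quantitative scale. Categories keep codebook (code-ascending) order so
ordinal variables remain ordered; "Refused"/"Don't know" stay as explicit
categories unless `special_as_missing=True`. Observed codes absent from the
codebook become literal numeral strings with a warning, keeping the
translation invertible (the recorded code map is a bijection on mapped
codes, and the suite reconstructs the raw integers from the labels).

Skip-filling is opt-in with explicit rules; suggestions derived from the
codebook's Skip-to-Item links name the gate, the triggering answers, and
the questions skipped over, but choosing a fill label is an analyst
judgment and is never automated. Fill counts are recorded in provenance and
conservation (missing_before = missing_after + filled) is asserted.

## Assembly guards

SEQN is the only join key; within-cycle joins check provenance cycles and
refuse cross-cycle merges. Cross-cycle stacking adds a cycle column,
reports per-cycle-only variables and categorical label-set mismatches
(never silently unioning them, since question wording changes semantics),
and refuses to mix a pre-pandemic (P_) table with regular cycles unless
explicitly overridden — those weights are not cycle-additive.

## Problem sizes and numerical choices

The default test suite and the acceptance script run entirely offline on the
fixture scale described above (≈2000-row samples, 500 replicate draws, 10⁴
float round-trip draws), chosen so a full run completes in well under a
minute on one CPU. Variance agreement with an independently coded
brute-force evaluation of the linearization formula is asserted at 1e−10
relative on 300-row designs; closed-form limits at 1e−12. All generator and
test randomness is seeded; `scripts/acceptance.py` derives every stream
from its `--seed`.

## Known limitations

- The real-data reproduction (2017–2018 diastolic-pressure example and the
  pre-pandemic demographics row count) requires one-time network access to
  the CDC server; without network that test fails rather than silently
  skipping.
- Lonely-PSU handling beyond the three policies (e.g. stratum collapsing)
  is not implemented.
- No rename dictionary is shipped for variables whose names drift across
  cycles; drift is surfaced in alignment reports, not repaired.
- Same-integer code collisions (a value that is valid data in one cycle and
  a special code in another) are reported, not resolved.
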