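# Methods

## Design construction

The 27-run, three-level orthogonal array is generated algebraically rather
than copied from a catalog. Index the runs 0..26 and write each index in
base 3 as digits (a, b, c) with a slowest. Every array column is a linear
form x·a + y·b + z·c over GF(3), mapped to coded levels {1,2,3}. Two such
columns are strength-2 orthogonal (all 9 ordered level pairs equally
frequent) exactly when their coefficient vectors are linearly independent,
so the array supports up to 13 columns — one per projective direction of
GF(3)³.

The first six coefficient vectors are frozen as a named constant so that
`generate_l27(6)` reproduces the study's printed trial matrix cell for
cell: CO₂ = a, LED = b, EC = a + b, day temperature = 2a + b, night
temperature = c, humidity = a + c. The remaining seven directions extend
the constructor to 13 factors. `validate_orthogonality` re-checks any
matrix by exhaustive counting (9 per level per column, 3 per ordered pair
per column pair), independent of the construction.

Run order is the printed treatment order 1..27; no run-order randomisation
is modelled. Coded levels are 1-based everywhere at the interface.

## Data model and fixtures

Responses are long-format records (run, parameter, value) per species.
The packaged fixtures transcribe the published per-treatment means for
lettuce and basil: seven growth/chlorophyll parameters and ten leaf
elements, 27 runs each, every value a mean of three replicates. Raw
replicates are not published, so all S/N arithmetic uses n = 1 per run;
`replicate_semantics` records this. A few typeset cells admit more than
one digit grouping; each resolution and its rationale is listed in
`src/taguchigrow/fixtures/provenance.md`. Values must be strictly positive
(required by the larger-is-better criterion); validation aggregates all
problems with row numbers instead of stopping at the first.

## Signal-to-noise analysis

All three classic criteria are implemented; the pipeline uses
larger-is-better throughout because every response here is maximised. At
n = 1 this is 20·log₁₀(y), a strictly monotone map, so per-factor argmax
decisions coincide with decisions on mean log response — asserted as a
test property, not assumed.

Level means average the 9 runs at each coded level. Because the array is
balanced, the unweighted mean of a factor's three level means equals the
grand mean (tested to 1e-9 dB). Delta = max − min of level means; rank 1
is the largest delta. Tie handling is deterministic and flagged: equal
deltas keep design-column order; equal level means take the lowest level.
Argmax comparisons use exact dB values — no pre-rounding.

## Optimum prediction and confirmation error

The additive model predicts S/N at any setting as the grand mean plus the
sum of level-mean deviations. The predicted response is the n = 1
back-transform y = 10^(S/N/20), the exact inverse of the S/N used here
(round-trip tested at 1e-12 relative tolerance). Confirmation error is
100·|expected − predicted|/expected, computed at full precision and
rounded to 2 decimals only in reports; the absolute value matters because
predictions can exceed the confirmation measurement. The published
confirmation summary ships as a fixture; its S/N and predicted-value
columns were produced by closed-source software whose exact settings are
not recoverable, so only the error column — which is internally checkable
from the other two — is used for numeric cross-checks, and one
arithmetically inconsistent row (basil calcium) is excluded (see the
provenance notes).

## Interaction screening

For each of the 15 factor pairs the 3×3 cell-mean matrix of S/N is formed;
strength-2 balance guarantees exactly 3 runs per cell. Non-parallelism is
the maximum absolute non-additive residual after removing row, column and
grand means — zero iff the interaction-plot profile lines are exactly
parallel.

The saturated array forces a distinction the visual method hides. With six
of the thirteen orthogonal directions occupied, every column lies in the
GF(3) span of some pair of other columns (EC = CO₂ + LED, for example; the
four columns CO₂/LED/EC/day-temp jointly saturate one 8-df plane). Raw
cell means of such a pair therefore absorb the aliased columns' main
effects: a perfectly additive response still draws bent raw profiles. The
package consequently reports two scores per pair:

- `score_db` — non-parallelism of the cell means of the *main-effects
  residual* S/N (observed minus the additive prediction). It is exactly
  zero on additive data, isolates genuine pairwise structure, and drives
  the ranking and the interacting flag.
- `raw_score_db` — non-parallelism of the raw cell means, i.e. what the
  plotted profile lines show. This is the quantity a visual
  parallel-lines judgment responds to.

On the study fixtures the EC × humidity pair has among the flattest raw
profiles of all 15 pairs for the fresh-leaf response of both species,
consistent with the study's conclusion that EC and relative humidity do
not act synergistically on growth. Note also that the six pairs inside the
saturated CO₂/LED/EC/day-temp plane have residual score exactly 0 by
construction — their interaction degrees of freedom are fully confounded
with main effects, so the design simply cannot assess them; this is a
property of any saturated L27 assignment, not of the data.

The interacting flag threshold defaults to 10 % of the larger of the two
factors' deltas — scale-free in the response units and comparable across
parameters — with a 1e-9 dB absolute floor so floating-point residue on
exactly additive data is never flagged. Screening is descriptive; with no
replicate-level error estimate an F-test would be unfounded.

## Chlorophyll equations

The assay module evaluates the study's printed equations verbatim
(coefficients 12.25/25.51, total = chl_b − chl_a), normalising by
V/(1000·W), the only dimensionally sensible reading of the printed
notation for a per-gram concentration. The printed total and coefficients
differ from the conventional spectrophotometric forms, so a `sum` mode
(chl_a + chl_b) is exposed alongside the literal `as_printed` default;
the package reports which mode produced a number rather than silently
correcting the source. Negative concentrations (possible when one
absorbance dominates) are flagged, never clamped.

## Synthetic data generator

`simulate_responses` draws y = baseline · 10^(Σ effects + ε) on the
design, with zero-sum main-effect offsets, doubly-centered pairwise
interaction tables and ε ~ N(0, σ²) on the log₁₀ scale. Log₁₀-additive
effects are exactly additive in the n = 1 larger-is-better S/N
(20·log₁₀ y), so the generator produces the regime in which the additive
optimum prediction is provably exact — making "the method recovers the
truth when its assumptions hold" a testable statement rather than a hope.
Log-normal noise keeps responses positive, as the S/N domain requires.

Defaults: baseline 20 g (a typical lettuce fresh-leaf mass in the study
tables), one active factor (EC — the dominant factor in the study) with
offsets (−0.1, 0, +0.1), i.e. a 4 dB S/N spread matching the lettuce
fresh-leaf EC delta, and σ = 0.05 on the log₁₀ scale. All randomness flows
from NumPy's seeded `default_rng`; `recovery_experiment` derives one child
seed per replicate from a `SeedSequence`, records them, and reports
per-factor best-level recovery fractions, recovered-level counts and the
fraction of replicates whose delta ordering matches the true
effect-magnitude order (compared only over strictly ordered pairs).

What the generator does *not* emulate: replicate-level measurement
structure, correlated responses across parameters, non-log-normal noise,
or any mechanistic plant physiology. Passing recovery tests therefore
demonstrates correctness of the analysis machinery under its own
assumptions, not that real crops respond log-additively.

## Numerical and reporting choices

- Problem sizes: Monte-Carlo tests use 500 replicates for the recovery
  bound and 3000 for the null-uniformity chi-square; both complete in well
  under a minute on one core and give binomial standard errors below 1 %.
- Artifacts (`main_effects.csv`, `predictions.csv/json`,
  `interactions.csv`, `reproduction.json`) embed the package version and
  SHA-256 checksums of the input tables; timestamps go only to the log, so
  repeated runs are byte-identical.
- `reproduction.json` compares computed optimal physical levels for the
  fresh-leaf response of each species against the study's stated optima
  (lettuce EC 0.9 dS m⁻¹, LED WRF244, day/night 15/10 °C, RH 75 %; basil
  EC 1.2 dS m⁻¹, LED WRF244, day/night 26/20 °C, RH 55 %). The published
  per-parameter rank tables are rendered as figures in the source and are
  not machine-readable, so prose-stated optima are the reproduction
  surface; the published optimum-setting S/N column is likewise not
  re-derivable from published data and is not targeted.

## Known limitations

- With one value per run, the S/N carries no within-run variability;
  smaller-is-better and nominal-is-best are implemented and tested but
  unused by the packaged reproduction.
- The additive prediction has no uncertainty interval (none is derivable
  without replicate data).
- Interaction confounding on the saturated design (above) is reported, not
  resolved; resolving it would require a larger or differently assigned
  array.
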