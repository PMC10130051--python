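# Fixture provenance notes

The four response CSVs transcribe the study's published per-treatment mean
tables (three replicates per treatment, only the means are published). The
source tables are typeset without column delimiters, so a few cells admit
more than one digit grouping; each such cell was resolved by column
plausibility (dry mass below fresh mass, chlorophyll within the range of
neighbouring runs) and is recorded here.

## Resolved cells — growth/chlorophyll table

- run 1, lettuce, `...1.82 0.321 1.32`: read as fresh_root 1.82,
  dry_root 0.321, chlorophyll 1.32 (chlorophyll 11.32 would be ~3x the
  column maximum).
- run 6, lettuce, `...2.67 0.421 2`: read as dry_root 0.421,
  chlorophyll 2.0 (matches run 9, an otherwise similar treatment; the
  alternative 0.42 / 12 is far outside the chlorophyll range).
- run 24, lettuce, fresh_root printed as bare `2`: read as 2.0 g.
- Lettuce dry_root is printed with three decimals for most runs
  (0.321, 0.367, ...); groupings were chosen to keep that precision
  consistent down the column.

## Resolved cells — element table

- run 12, basil, boron printed `2a3.80` (typographic artifact): read as
  23.80 mg kg^-1, consistent with the neighbouring basil boron values.

## Confirmation-test table

`confirmation.csv` transcribes the published confirmation-test summary:
the reported optimum-setting S/N, the confirmation-run ("expected") value,
the additive-model ("predicted") value and the reported error percentage,
all exactly as printed.

- basil calcium row (expected 5.63, predicted 3.59, error 0.98 %) is not
  arithmetically self-consistent as printed (the stated values imply a 36 %
  error); it is kept verbatim here but excluded from numeric cross-checks.
- Several error-percent entries are printed at lower precision (3.0, 2.5,
  1.4); cross-checks compare at the printed precision.
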