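# Methods

## Scope and model

The package re-implements, as a tested library, the data-processing chain of a
targeted polarity-switching LC–MS lipidomics assay and the statistics of a
four-diet ruminant-fat dose–response study (3.6 / 6.3 / 9.0 / 11.7 % beef
tallow, 8–9 rats per group, liver tissue). Quantitation is single-point:
analyte peak area is normalised to a deuterated internal standard spiked at a
known working concentration (5 µM); there are no calibration curves, no
profile-mode centroiding, no cross-run alignment and no MS/MS identification.

## Lipid nomenclature

Species are identified at the summed-composition level, `Class_(C:D)` — total
fatty-acyl carbons and total double bonds. Acyl-carnitine names prefix the
carbon count with `C` and count only the acyl chain (the carnitine backbone is
excluded). `-OH` and `-2COOH` suffixes and the single ether dialect
`PC_C18(plas)-18:1` (parsed as PC, 36 carbons, 1 double bond, plasmalogen
modifier) are supported. Parsing records the zero-padding of the source name
(`CL_(66:02)`) so formatting round-trips bit-identically over the packaged
table.

Odd/even chain parity uses the summed carbon count: an odd total implies at
least one odd-chain acyl group. This is the standard proxy for "contains an
odd-chain fatty acid" at summed-composition resolution; it cannot see an
even total composed of two odd chains, a known limitation of shorthand-level
annotation.

Acyl-carnitines carry two internal standards (butyryl-d7 and
hexadecanoyl-d3). The split is by acyl chain length with a configurable
cutoff, default ≤ 8 carbons → the short-chain standard, matching the polarity
and elution behaviour of short versus long acyl-carnitines.

## Mass computation

Monoisotopic masses use a pinned in-code constants table (C 12, H 1.0078250319,
D 2.0141017780, N 14.0030740052, O 15.9949146221, P 30.97376151,
Na 22.98976928, K 38.9637064864) so results are bit-stable. Charge-carrier
deltas follow the electron-corrected proton convention: [M+H]⁺ +1.007276,
[M−H]⁻ −1.007276, [M+Na]⁺ +22.989218, [M+K]⁺ +38.963158, [M+NH₄]⁺ +18.033823,
[M+H−H₂O]⁺ +1.007276 − 18.010565. Deuterium-loss isotopologues step by
m(D) − m(H) = 1.006277 Da.

Each internal standard's EIC product list is configured explicitly as
(adduct, deuterium count) pairs in `data/internal_standards.csv` and every
m/z is computed from the elemental formula at run time; the CSV also carries
the published reference values for verification. Of the 83 published
products, 78 are reproduced to ≤ 0.6 mDa. Five published entries (the
protonated d30/d31 values of the sphingomyelin, phosphocholine and
phosphoethanolamine standards) are internally inconsistent with the sodiated
and potassiated entries of their own rows under *any* adduct/deuterium
assignment — the published series appear to have been extended with an
incorrect isotope spacing — and are excluded from the reproduction check with
an explicit in-test list. Each standard designates one reference product
(the full-label primary-adduct entry, or for the phosphocholine standard the
sodiated full-label entry) that the formula reproduces to ≤ 1 mDa; all 13
are verified. The sphingomyelin standard's products are assigned d30/d31
pairs: one deuterium is exchange-labile, so the most abundant observed form
carries 30 labels.

Endogenous-analyte formulas are out of scope: analyte target m/z values are
supplied directly in an analytes CSV, as a targeted assay would configure
them.

## EIC extraction and integration

Extraction sums, per scan of matching polarity, all centroid intensity within
±10 ppm (configurable) of each product m/z. The default window suits
Orbitrap-class resolution (25,000 at m/z 200). The peak apex is the trace
maximum within ±0.5 min of the expected retention time; an apex drifting more
than ±0.1 min (configurable) yields "Not Found" with zero area — absence is a
result, not an error. Integration bounds walk outward from the apex to the
nearest flanking local minima, clipped to ±0.2 min, and the area is the
trapezoidal integral. On the default sampling grid (0.25 s per polarity) a
Gaussian peak of σ = 0.04 min integrates to within 2 % of its closed-form
area.

Order of censoring rules: the retention-time rule is applied at integration
(it is an integration outcome), then blank correction operates on area
ratios — the threshold is 3× the mean blank ratio (configurable to max).
Values below it are censored to zero concentration; with no blanks the
correction is skipped with a warning recorded in provenance. Both decisions
(ratio-space correction; mean as the blank statistic) are choices where the
source workflow is ambiguous, and both are idempotent and monotone: raising
the blank level never un-censors a value. Censored outputs carry the rule
that censored them (`rt_drift`, `blank`, `not_found`, `missing_standard`).

Concentrations: fluids report ratio × standard concentration (molar); tissue
divides additionally by the extracted mass, reported as amount per mg with an
explicit unit field. The packaged study table is in nM/mg.

## Dose–response screen

Regression is of the four group *means* on beef-tallow percentage, not of
per-animal values, with df = n_groups − 2 = 2. This choice reproduces the
published per-lipid trendlines exactly and the published slope-significance
levels of the odd/even-chain totals (p = 0.197 and ≈ 0.0189 from the printed
slope ± SE pairs at df = 2). Group SDs use the n − 1 denominator. Degenerate
all-equal means return slope 0, R² 0, p 1 by convention.

The biomarker rule is the conjunction: two-sided slope p < 0.05, R² > 0.75
(strict), and strictly monotone group means. A missing (ND) group mean is a
censored observation, not zero: trends are still fitted when ≥ 3 groups are
observed, but the monotonicity criterion fails (an undetected group cannot be
ordered), so only complete rows are flaggable. Applied to the packaged
472-row table this yields exactly 100 flagged species (35 increasing, 65
decreasing), in row-by-row agreement with the published calls. No
multiple-testing correction is applied (matching the source analysis); the
report records the number of tests.

Comparison with printed values uses the table's printed precision: 3
significant figures for slope/intercept (2 decimals for R²), rounding half
away from zero — three intercepts in the table sit on exact decimal ties that
distinguish the conventions.

## Compositional (Mol%) analysis

`mol_percent` closes each sample row to 100 and is invariant to per-sample
rescaling; rows sum to 100 within 1e−9. The odd/even artifact contrast uses
the two-part closure (odd share + even share = 100), forcing fitted Mol%
slopes to be equal and opposite with identical R² and p — the signature of
the published symmetric ±0.0604 slopes. Mol% is closed per sample and then
averaged per group by default (configurable to closure on group means; for
the two-part case at the group level the two orders give the same contrast).
Log-ratio (CLR/ILR) methods are out of scope: the point made here is the
artifact itself, not an alternative coordinate system.

## Synthetic data

The concentration generator draws value = max(0, intercept + slope × dose +
ε), ε ~ N(0, sd) per group (log-normal with matched CV available), with ND
censoring recorded as missing. Truncation at zero mirrors summary tables
whose SDs are comparable to their means; it slightly biases low-mean groups
upward, which the recovery tests accommodate. Defaults mirror the study:
doses 3.6/6.3/9.0/11.7, nine animals per group.

The scan generator renders each analyte as a Gaussian elution profile at each
of its product m/z values across polarity-switching centroid scans
(default 10-min run, 0.25 s per polarity), amplitude proportional to amount,
with a half-normal noise floor; blanks keep the internal standards (spiked in
practice) and scale analytes to a contamination fraction. It emulates none of
the hard parts of real data — matrix effects, ion suppression, isobaric
interference, retention drift within a run, natural-abundance isotope
patterns — so passing recovery tests demonstrates correctness of the
processing chain, not robustness to real instrument behaviour.

Test problem sizes are scaled to the property under test: recovery and
censoring checks use 4–6 runs of 4.5 min at 0.6 s per polarity with two
standards and four analytes; replicate-based properties use 100 seeded
replicates of the 4 × 9 design; the null screen uses 1000 zero-slope species.
The artifact demonstration generates parity *totals* with ~3 % within-group
CV — totals aggregate hundreds of species, so their relative noise is far
below per-species CVs — with constant odd totals and an even-chain decline of
about 25 % across the dose range.

The packaged study table ships with a recorded SHA-256 checksum, verified on
load.

## Known limitations

* Summed-composition parity cannot detect odd-chain content hidden in an
  even total.
* The published p-values for the total-lipid trends were evidently computed
  from unrounded slope/SE; recomputation from the printed pairs matches to
  ~1 % (0.0188 vs 0.0189), not to the last printed digit.
* Peak-bound detection by flanking minima assumes well-separated peaks; no
  deconvolution of overlapping elution profiles is attempted.
* The blank rule censors to zero rather than propagating a detection-limit
  value; downstream trend fits treat such zeros as data, as the source
  workflow does.
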