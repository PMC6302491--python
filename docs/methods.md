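# Methods

## Scope and data model

The package analyzes flat PSM tables (one row per candidate
peptide-to-spectrum correlation) against a FASTA protein library whose
headers carry a gene-symbol annotation (`>ACCESSION GN=SYMBOL`).  It does
not parse raw spectra or emulate search-engine scoring: spectrum files,
retention times and the SEQUEST/X!TANDEM internals are upstream of the
interface, and their search settings travel only as provenance metadata.
All intermediate products are TSV; a YAML manifest echoes the full
configuration, package versions and the row count at every filter stage, so
a run can be reproduced from its manifest alone.

## PSM acceptance

1. **Intensity threshold.**  Strictly greater than 1e4 counts by default.
   The threshold is the working definition of "real" precursor signal: it
   sits at the 99th percentile of the noise intensity distribution, so ~1%
   of pure-noise spectra survive this stage (they are removed later by the
   tryptic-context check).
2. **Best fit per spectrum.**  Within a spectrum, candidates are ordered by
   score (descending), then charge (+2 before +3), then peptide string
   (ascending); the first survives.  The total order makes the selection
   deterministic under score ties.  Selection is global per `spectrum_id`
   by default; a `within_engine` flag keys the selection by (engine,
   spectrum) instead, and an `engine` option restricts the run to one
   engine, so both readings of cross-engine deduplication are testable.
   The simulator assigns each spectrum to exactly one engine, under which
   the two defaults coincide and spectrum ids stay unique after selection.
3. **Tryptic validity and pools.**  A peptide is fully tryptic in a protein
   when its context is preceded by K, R or the N-terminus and it ends in K,
   R or at the C-terminus.  The same simple K/R rule (no proline exception)
   drives both in-silico digestion and validity checking, so the two can
   never disagree.  STYP = any phospho-S/T/Y modification present, else
   TRYP; the pools partition the accepted set.
4. **Gene symbols.**  Accessions collapse to distinct gene symbols; a
   peptide spanning several symbols contributes one count to each and is
   flagged `degenerate` in every report.

## Frequency correction and the pseudocount chi-square

Counts are per (gene symbol, treatment) within a pool.  For a contrast the
control column is scaled by the ratio of treatment totals (control scaled
to the disease total, so the tabulated disease counts stay raw).  Because
the totals are the column sums of the same matrix, the corrected deltas sum
to zero exactly — the quantile diagnostic (sorted deltas against standard
normal quantiles) must pass through zero at its mean for a null cohort, and
demonstrably does not when the correction is skipped under sampling-depth
imbalance.

The per-symbol statistic is `(D − C̃)² / (C̃ + 1)`.  The `+1` pseudocount
protects against never-observed control symbols (D, 0) → D², at the cost of
the statistic not being exactly chi-square distributed under the null.  The
package follows the field convention of reporting df = 1 upper-tail
p-values, and additionally reports a simulation-based exceedance rate
(`null_exceedance_rate`) rather than asserting either calibration.  On the
default null scenarios the fraction of symbols with χ² ≥ 15 is below a few
percent and stable across seeds.

Selection rules: the screening rule is strict (Δ > 15 and χ² > 15), the
headline rule uses χ² ≥ 60; both are exposed as `SelectionRule` instances
and the 60-list is a subset of the 15-list by construction.  Gene lists are
exported newline-delimited for external network/enrichment services, which
are out of scope (they depend on a live database version).

Cumulative protein p-values combine peptide-level corrected chi-square
p-values per symbol by Fisher's method (−2Σln p against chi-square with 2k
df); Stouffer's inverse-normal combination is a strategy switch.  Exact
zeros are clamped to the smallest positive float with a warning rather than
propagated as −∞.  BH q-values are computed within pool.

## Intensity ANOVA

Per gene symbol, log10 intensities are fit by sequential (type-I) least
squares in the fixed order `Peptide_Sequence`, `Treatment_ID`, interaction.
The implementation grows the design matrix block by block and takes each
term's sum of squares as the drop in residual SS and its df as the rank
increment, so missing cells and aliased interaction columns lose df
automatically instead of inflating a term.  A single-peptide gene drops the
peptide and interaction terms.  Zero residual df yields NaN F/p with a
warning.  Tests hold the decomposition to an independent projection-matrix
oracle (1e-8 relative) and to statsmodels' type-I table on full-rank
designs.

Tukey–Kramer HSD compares all treatment pairs with
`|m_i − m_j| / sqrt((MS_resid/2)(1/n_i + 1/n_j))` against the studentized
range quantile q(α, k, df); with k = 2 this reduces exactly to the pooled
two-sided t-test (q = √2·t), which the suite verifies decision-by-decision.
Letters come from the insert-and-absorb algorithm, guaranteeing that two
treatments share a letter iff their difference is not significant.
**Design choice:** letters are computed on raw per-treatment means with the
two-way model's residual MS.  Least-squares means are ill-defined under the
missing-cell designs this data model produces, and the report tables print
raw summaries (mean, SD, SE = SD/√n, n; SD/SE reported as NA at n = 1)
alongside the letters; a `one_way_letters` flag substitutes a one-way
residual for sensitivity analysis.  n = 1 treatments join the comparisons
through the unequal-n SE — they are not excluded.

A normal QQ diagnostic (`qq_normality`) reports theoretical-vs-sample
quantile pairs and their correlation; constant samples are flagged
degenerate instead of dividing by zero.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the physics: no m/z peaks, retention times or scoring internals.

* **Sampling model.**  Per (sample, fraction) recording, each spectrum is
  noise with probability `noise_fraction` (default 0.88, matching a ~12%
  overall assignment rate); signal spectra draw peptides without
  replacement from the library's zero-missed-cleavage tryptic pool via
  Gumbel top-k weighted sampling.  Symbol weights are equal at baseline and
  split evenly across a symbol's peptides, so a symbol's expected share is
  independent of its peptide count; planted effects multiply the weight in
  their target treatment, acute-phase symbols are elevated in every
  disease-class treatment, and ice-cold treatments binomially thin the
  signal count by a global detection scale.  Equal baseline weights are the
  deliberate null: the downstream invariants characterize the statistic
  under a known null, and an abundance spread would only add a nuisance
  dimension those checks do not need.
* **Intensities.**  Log-normal throughout.  The noise location is derived
  from the calibration constraint that its 99th percentile equal the
  acceptance threshold (1e4 counts); the signal location sits 2 log10 units
  higher (median signal/noise ≈ 100), with a static per-peptide response
  offset (SD 0.25) plus per-observation scatter (SD 0.35).  Planted
  intensity shifts add to the target treatment's log10 mean.
* **Redundancy.**  ~30% of signal spectra emit a second candidate row at
  the other charge state with a strictly lower score and the same precursor
  intensity, exercising best-fit filtering; noise rows carry a random
  non-tryptic peptide and a real accession, so they pass parsing, can pass
  the intensity gate (~1%), and are eliminated only by the tryptic-context
  check — with `noise_fraction = 1` nothing survives the funnel.
* **Phosphopeptides.**  STYP-pool treatments phosphorylate one random
  S/T/Y position in 90% of eligible signal PSMs; the remainder stay TRYP,
  mirroring parallel searches of the same recordings.
* **Seeding.**  One integer seed fans out through `SeedSequence` substreams
  per treatment/sample/fraction, with the peptide-selection stream separate
  from the intensity/score stream.  Selection therefore uses common random
  numbers across effect settings, making planted-count monotonicity in the
  multiplier exact, not just in expectation.
* **Truth log.**  Each planted effect appears exactly once, with the
  no-saturation multinomial expectation of its count.  Because sampling is
  without replacement within a fraction, realized counts saturate when a
  symbol's per-fraction weight share approaches its peptide count; the
  validation scenarios keep the per-fraction draw well below the pool size
  so this bias stays small, and the recovery study reports the measured
  planted counts rather than trusting the expectation.
* **Peptide counts per symbol.**  No empirical shape is asserted; the
  count is a tunable distribution, geometric with mean 4 by default.

What passing tests on this generator do **not** show about real data:
plasma abundance spans many orders of magnitude (equal baseline weights do
not), engine scores correlate with correctness (uniform scores do not),
and modification chemistry is richer than one phospho per peptide.  The
statistical guarantees tested — correction centredness, selection-rule
recovery, ANOVA decomposition, Tukey calibration — do not depend on those
features.

## Validation scenarios and problem sizes

`plasmapep.validation` fixes two reference studies used by both the test
suite and the reproduction script, sized to run in about a minute on one
CPU:

* **Correction balance:** 500 symbols, two null treatments, one recorded
  2.45× deeper (the ratio of the reference whole-cohort accepted totals),
  5 samples × 10 fractions × 420 spectra.  Corrected |mean Δ|/SD is zero to
  float precision; uncorrected exceeds 0.5 by an order of magnitude.
* **Recovery:** 100 replicate cohorts, 50 symbols, three symbols planted at
  5× in the disease treatment (measured mean disease count ≈ 100 ≥ 30);
  the (χ² > 15, Δ > 15) rule recovers ≥ 95% of planted (symbol, replicate)
  pairs while selecting < 10% of null symbols.

## Numerical conventions

* Quantile axes use the (i − 0.5)/n plotting positions with standard
  normal quantiles.
* Sample SD uses the n − 1 denominator everywhere; SE = SD/√n.
* Sequential-SS negatives from floating cancellation are clipped at zero;
  rank detection relies on `numpy.linalg.lstsq`.
* The studentized-range quantile is cached per (α, k, df).
* TSV serialization is byte-deterministic for a fixed seed (verified by
  hashing a double run).

## Known limitations

* The chi-square p-values inherit the pseudocount statistic's approximate
  null calibration; treat q-values as a ranking device, as the screening
  thresholds (Δ, χ²) do the selection work.
* Degenerate peptides double-count across symbols (flagged, not resolved);
  symbol-level inference on heavily shared peptides should consult the
  `degenerate` flag.
* The ANOVA assumes independent observations; repeated measures within a
  sample/fraction are not modelled (no mixed effects by design).
* Accession-level chi-square averaging (an optional view of the headline
  table) shares the symbol-level machinery and is only as meaningful as
  the accession annotation.
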