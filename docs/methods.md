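# Methods

This note records the models, conventions and numerical choices behind
`mirpress`, and what the synthetic generators do and do not emulate.

## Read-to-mature assignment

Reads are compared to mature references 5′-anchored and gapless.  A read is
accepted when it has at most 2 mismatches within reference positions 1–17;
positions 18 to the reference end are unconstrained, and up to 4 read
nucleotides extending past the reference 3′ end are ignored (treated as
non-templated additions; longer overhangs reject).  Reads shorter than
17 nt are rejected, `N` mismatches everything, and DNA `T` is read as `U`.
This is a deterministic re-statement of seed-mismatch-limited short-read
mapping for mature references with 3′-variable isomiRs; no indels are
modeled.  Reads exactly contained in a blacklist sequence (tRNA/rRNA) are
discarded before scoring.

Multi-mapping reads are split fractionally (1/k to each of the k accepting
references), which conserves total counts; a whole-count `all` policy is
available.  Assignment is order-independent and memoized per distinct read,
so collapsed read files (`>id_xN`) are processed at cost proportional to
the number of distinct sequences.

## Normalization and arm calls

RPM = 10⁶ · count / denominator.  The default denominator is the total
count assigned to mature miRNAs in that replicate (so per-replicate RPM
sums to 10⁶); a genome-mapped denominator can be supplied per replicate
instead, which rescales all values by the ratio of totals.  Replicates are
normalized first, then averaged; the SD across replicate RPM values is
reported.  Zero-count miRNAs get RPM 0, and all downstream log transforms
add a configurable pseudocount (default 0.5 RPM) so they remain finite.

For each hairpin the star (passenger) arm is the less abundant arm when the
arm-abundance ratio strictly exceeds 4:1 ("exceeds" is read strictly, so a
ratio of exactly 4 yields no star call).  A missing arm counts as 0, giving
an infinite ratio; two undetected arms give ratio 1 and no call.

## Repression from plate values

For construct c on day d, q_{c,d} = (Renilla/firefly)_{c,d} divided by the
same ratio for the empty vector on day d.  Repression % = 100·(1 − mean_d
q_{c,d}).  Day-level effects (transfection efficiency, reagent batches)
multiply all wells of a day and cancel in this normalization — repression
is invariant to rescaling a day's luminescence by any constant.  Negative
repression (de-repression) is reported, never clamped.  Significance is a
two-sided one-sample t-test of the q_{c,d} against 1, pairing construct and
empty vector by transfection day; α = 0.05, no multiple-testing correction
across the panel.  Sidedness and pairing unit are package conventions where
the underlying assay protocol leaves them open.

## Seed sites, TSA and junction screens

The target-side motif is the reverse complement of miRNA positions 2–8
(the minimal 7-nt canonical seed reading; the 7mer-A1 variant and G:U
wobble pairing are deliberately not implemented).  Scanning is exact,
single-strand, on the mRNA/reporter sense strand, with overlapping matches
and 0-based half-open coordinates; `N` never matches.  Per gene, site
counts are taken per UTR isoform and combined by maximum.  Target-site
abundance is TSA(m) = Σ_g expr(g) · max_sites(m, g) — linear in expression
and monotone in counts; genes lacking expression values contribute 0 with a
warning.

Junction screens scan the reporter insert plus exactly 6 nt of vector flank
on each side for every miRNA's motif.  Additive expression sums each
matching miRNA's mean RPM once, however many sites it matches; the designed
miRNA is included by default (configurable), since the summed expression is
meant to be correlated with observed repression.

## Duplex free energy

Reporter target sites are perfect complements, so the MFE structure of the
miRNA:target duplex is the fully paired helix and its energy is a closed
form: helix initiation (+4.09 kcal/mol) + one nearest-neighbor stack per
adjacent pair + 0.45 kcal/mol per terminal A:U pair, using the bundled
Watson–Crick RNA/RNA table (`xia1998`).  Dangling ends and the
self-complementarity correction are omitted.  A hybridization DP is
unnecessary in this regime, and absolute values are parameter-set
dependent; the package supports relative and correlation analyses, which is
also why the ΔG-vs-repression surfaces are checked as sign/rank properties
rather than absolute values.  Unit tests cross-check the energies against
ViennaRNA's `RNAduplex` on the same duplexes (r > 0.99, absolute agreement
within ~1 kcal/mol).

## The expression–repression model

Ordinary least squares of repression (%) on log₁₀(RPM + pseudocount); the
95% CI on the slope comes from the t quantile on the OLS standard error.
Pearson r is reported for the same pair (with the convention r = 0 for
constant repression), and separately on the untransformed RPM scale.  The
predicted repression change for an expression fold change f is
slope · log₁₀(f), additive in log-fold.  Expression-corrected repression is
repression / log₁₀(RPM + pseudocount), undefined (NaN, excluded downstream)
when the denominator is not strictly positive.  Occupancy analysis
correlates log₁₀ cellular vs log₁₀ Ago-1-RIP RPM and reports per-miRNA
occupancy ratios (ago/cell, defined for positive cellular RPM) plus the
correlation of log₁₀ Ago-1 RPM with repression.  Printed correlations use
means over replicates, not pooled replicates.

## Synthetic generators

The generators encode the study conditions the pipeline targets; where no
noise model is implied by those conditions, the distributions below are
package conventions chosen to look like realistic data, fixed once:

- **Panels.** Each hairpin contributes one 5p and one 3p mature sequence
  (21–23 nt, random, pairwise dissimilar — no shared seed 7-mer unless
  requested).  log₁₀ abundance is stratified-uniform over [0, 6]: one draw
  per equal-width stratum, shuffled.  Stratification tiles the range the
  way a deliberately representative panel would, and guarantees ≥ 5 decades
  of span for panels of ≥ 16 hairpins.
- **True repression.** clamp(intercept + slope·log₁₀(RPM) + ε, 0, ceiling)
  with slope 10.4%/decade, intercept 10%, ceiling 80%, and ε ~ N(0, 19%).
  The noise SD was set by Monte-Carlo calibration so the median log-scale
  Pearson r on 32-miRNA panels is ≈ 0.71.  An optional planted stability
  effect adds a term proportional to the z-scored duplex ΔG, for
  sign-recovery tests of the ΔG/GC analyses.
- **Luciferase plates.** Firefly ~ 10⁵ × lognormal day factor × lognormal
  per-well transfection noise (CV 0.05 at day level); Renilla = firefly ×
  base ratio 2.0 × (1 − repression/100) × lognormal well noise (CV 0.01).
  Ratio-based readouts have scale-proportional error, hence multiplicative
  noise throughout.  Day-level and firefly noise cancel in the empty-vector
  normalization, so round-trip recovery error is set by the Renilla well
  CV: mean absolute error ≈ 0.4% over three days.
- **Ago-1 counts.** log₁₀(ago) = log₁₀(cell) + offset + N(0, 0.35); the SD
  calibrated so the median log-log r on 32-miRNA panels is ≈ 0.98.
- **Reads.** Exact copies of mature sequences (no sequencing error or
  adapters, by design), emitted multinomially, Poisson, or deterministically
  proportional to abundance; the emission ledger is the quantification
  oracle.
- **UTR sets.** Backgrounds are rejection-sampled to contain no seed match
  for any panel miRNA; Poisson(site_rate) sites per gene per miRNA are then
  planted at non-overlapping positions and the whole UTR is re-verified so
  planting never spawns spurious matches of another motif.  The planted-site
  ledger is therefore an exact oracle for the scanner.
- **Study-scale stand-in.** `study_like_panel` scripts a 16-hairpin panel
  whose ground truth encodes the qualitative facts of the reporter study
  this pipeline targets: five low-abundance null constructs, a ~50-fold
  bantam arm ratio with the minor arm the stronger repressor, two equally
  expressed miRNAs differing by > 40% repression, two miRNAs repressing
  equally across a > 100-fold expression gap, and a top tier saturating
  below the 80% ceiling.  Non-anchored arms tile log₁₀ RPM ∈ [1, 5] and
  follow the log-linear law with N(0, 6%) noise, floored at 10% so every
  non-null construct is a true repressor.  The anchored extremes make this
  panel's emergent fitted slope steeper (~12–13%/decade) than the law used
  for the free arms; tests on it assert the planted discrete facts, while
  slope/correlation recovery is checked on the calibrated random panels.

What passing tests on synthetic data do **not** show: robustness to
sequencing error, adapter read-through, ligation bias, plate-position
effects, or cross-hybridizing miRNA families — none of which the generators
emulate.

## Problem sizes and determinism

Simulated studies use 16-hairpin panels (32 mature miRNAs), two replicate
libraries of ~2 million reads (processed in collapsed form), three plate
days, and 25-panel replication for median statistics; property checks use
10⁵ read/reference pairs, 10⁴ scan strings, 500 panels for CI coverage and
100 seeds for plate round-trips.  Every stochastic step takes an explicit
seed (NumPy `default_rng`), identical seeds give bit-identical outputs, and
every output table carries the package version and a config hash.

## Known limitations

- Reads are never genome-aligned; genome-mapped totals enter only as
  user-supplied denominators.
- Gapless matching cannot place reads from edited or indel-bearing isomiRs.
- Seed prediction ignores conservation, context scores and 3′-supplementary
  pairing; it is deliberately the minimal canonical method.
- The duplex model covers perfectly complementary helices only; bulged or
  seed-only sites are out of scope.
- The paired t-test with three days has low power; non-significance of a
  weak construct is expected behavior, not evidence of no repression.
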