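# mirpress

How strongly does an endogenous microRNA repress its targets, given how
abundant it is?  `mirpress` is a Python package for answering that question
quantitatively in small-RNA + reporter-assay experiments, built around the
*Drosophila* S2-cell setting: cellular and Ago-1-RIP small-RNA libraries
measured against miRBase-style mature references, dual-luciferase reporters
carrying a single perfectly complementary target site, and a panel of
guide/passenger (miRNA*) arm pairs spanning 5–6 orders of magnitude of
expression.

The pipeline covers:

- **Small-RNA quantification** — reads are assigned to mature references
  5′-anchored and gapless, tolerating ≤ 2 mismatches in reference positions
  1–17 and any mismatch from position 18 on (isomiR-aware), with a
  user-supplied tRNA/rRNA blacklist, fractional multi-mapping, RPM
  normalization (miRNA-mapped or genome-mapped denominators) and 4:1
  guide/star arm classification.
- **Dual-luciferase repression** — per day of transfection, the construct's
  *Renilla*/firefly ratio is normalized to the empty vector's ratio;
  repression % = 100·(1 − mean ratio), with a paired t-test against the
  empty vector.
- **Canonical seed targeting** — 7-nt seed sites (reverse complement of
  miRNA positions 2–8) scanned over 3′UTR sets; per-gene maxima over UTR
  isoforms; target-site abundance TSA(m) = Σ_g expr(g) · max_sites(m, g);
  and a cloning-junction screen for adventitious sites created in reporter
  construction, with the summed expression of all co-targeting miRNAs.
- **Duplex stability** — closed-form nearest-neighbor free energy of the
  fully paired miRNA:target helix (bundled RNA/RNA parameter table), plus
  GC content.
- **The expression–repression model** — OLS of repression on
  log₁₀(RPM + pseudocount): slope (% repression per decade), t-based 95%
  CI, Pearson r on log and linear scales, refits excluding named miRNAs,
  predicted Δrepression for a fold change, expression-corrected repression
  (repression / log₁₀ RPM), and Ago-1 occupancy analysis.
- **Synthetic data** — generators for every input (panels, plates, reads,
  Ago-1 counts, UTR sets with planted sites) with explicit ground truth, so
  each stage is testable end to end without external data.

## The model

For miRNA *i* with mean expression RPMᵢ and measured repression Rᵢ (%):

    Rᵢ = β₀ + β₁ · log₁₀(RPMᵢ) + εᵢ

β₁ is the repression gained per 10-fold increase in abundance.  At the
study conditions this package is calibrated to, β₁ ≈ 10%/decade — i.e., a
2-fold expression change moves repression by only ~3% — with an observed
repression ceiling of 80%.

## Worked example

```
$ mirpress simulate --out demo --seed 3 --n-hairpins 16 --depth 300000
wrote synthetic inputs and demo/config.yaml
$ mirpress run --config demo/config.yaml
# mirpress 0.1.0 (config e92eb8b8adef)
miRNAs profiled: 32
constructs assayed: 32
log-linear fit: slope 11.77%/decade (95% CI 8.25..15.29), intercept 8.33%, r(log) = 0.780, n = 32
r(linear RPM) = 0.417
non-significant constructs (3): syn-mir-001-3p, syn-mir-003-5p, syn-mir-016-5p
star arms called: 11
fit excluding non-significant: slope 10.62%/decade, r = 0.730, n = 29
r_deltag_corrected = 0.026
r_gc_corrected = 0.006
r_tsa_corrected = 0.162
r(log cell, log Ago-1) = 0.985
r(log Ago-1, repression) = 0.756
```

Reading this: 32 mature miRNAs were quantified from two simulated
libraries; all 32 reporter constructs were scored against the empty vector.
The fitted slope (11.8%/decade, CI covering the generating truth of
10.4%/decade) says a 10-fold abundance increase buys ~12% more repression
on this panel; log transformation improves the correlation (0.78 vs 0.42).
Three low-abundance constructs are indistinguishable from the empty vector;
removing them barely changes the fit.  Cellular and Ago-1-associated
levels correlate at r = 0.985, so RISC loading tracks abundance.  The
near-zero ΔG/GC correlations are expected here: this simulation planted no
duplex-stability effect on repression.

Every stage is also callable as a library function
(`mirpress.quantify`, `mirpress.repression_from_raw`,
`mirpress.fit_loglinear`, …) or as a CLI subcommand
(`quant`, `repression`, `targets`, `junctions`, `duplex`, `fit`,
`occupancy`, `simulate`, `run`).

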