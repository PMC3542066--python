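# Methods

## Scope and data model

phosvar analyzes a phospho-site quantification table — one row per
modified S/T/Y residue with six normalized phosphorylation ratios for the
cell-cycle phases G1, G1/S, early S, late S, G2 and M — together with
per-protein FASTA sequences, PsiPred secondary-structure predictions,
DISOPRED disorder predictions and (optionally) rate4site evolutionary
rates and a kinase-motif file. Coordinates are 1-based and inclusive
throughout; missing ratios are NA in memory and on disk, never zero.

## Variability statistic

The per-site variability is the sample standard deviation (n−1
denominator) of the observed phase ratios. The n−1 convention matches the
default of the common statistical tooling for this statistic; a
population-SD switch (`ddof=0`) exists for sensitivity analysis. Ratios
are used as given — they are assumed to be already normalized by the
protein-level change — with an optional log2 transform that is off by
default. Sites need at least two observed phases for a defined value; the
primary analysis set requires all six ("complete" filter), and robustness
subsets can be defined as "at least k" or "exactly k" observed phases
(both interpretations are supported because the subset definition is
ambiguous in common usage; "at least k" is the default, which makes the
subsets nested).

The low/high split used by the flank analyses is an empirical quantile
split, default the median. The threshold uses linear interpolation
(numpy's default, type-7) and ties at the threshold go to the *low* set,
which keeps the split deterministic under heavily tied variabilities.

## Structural categories

A site's category is read at exactly the modified residue's position (no
window vote): H/E + ordered → REGULAR; C + ordered → IRREGULAR; C +
disordered → DISORDERED. A helix/sheet residue flagged disordered is an
inter-predictor conflict; disorder dominates (the three categories must
partition the sites) and the number of conflicts is logged as a warning.
Coil segments are maximal runs of C-state residues, split wherever the
disorder flag changes; "ordered coils" (turns, short loops) are therefore
structurally distinct from long disordered regions, and their length
distributions can be compared directly with the rank-sum test.

## Statistical primitives

All primitives are implemented from their definitions in
`phosvar.stats_core` and are cross-checked in the test suite against both
brute-force oracles (ECDF scans, pair counting, explicit sum-of-squares,
hypergeometric enumeration) and independent library implementations.

* **KS two-sample**: D is the exact sup-distance of the ECDFs; the
  two-sided p uses the asymptotic Kolmogorov distribution evaluated at
  $\sqrt{nm/(n+m)}\,D$. Exact small-sample p-values are deliberately not
  implemented: the analysis sets here have hundreds to thousands of
  sites, well inside the asymptotic regime.
* **One-way ANOVA**: classical F with (k−1, N−k) df. A zero within-group
  sum of squares with unequal means returns F = ∞, p = 0 with a
  `degenerate` flag instead of raising.
* **Mann–Whitney**: U for the first sample counts pairs x > y (ties ½);
  p from the normal approximation with midranks and tie-corrected
  variance, no continuity correction.
* **Fisher's exact test**: the odds-ratio estimate is the conditional MLE
  under the noncentral hypergeometric model (solved by root-finding on
  the conditional mean), matching R's `fisher.test`; the sample ad/bc
  ratio is reported as a secondary descriptive column. The two-sided p
  sums hypergeometric probabilities ≤ (1+1e−7)× the observed table's
  probability (probability-mass ordering, R's convention). Zero-margin
  tables are rejected. The Woolf log-normal CI (Haldane 0.5 correction on
  zero cells) accompanies the estimate where an interval is needed.
* **Benjamini–Hochberg**: classical step-up adjusted values,
  order-preserving.

## Flank analyses

Windows span ±6 residues around the site; positions beyond the termini
are MISSING and excluded column-wise. The two-sample logo compares, for
each (offset ≠ 0, amino acid), the binary indicator vectors of the two
site sets with a Welch (unequal-variance) t-test; when both vectors are
constant the t-test is undefined and a two-proportion z-test is used
instead, preserving the frequency-difference intent on degenerate
columns. Flags use uncorrected α = 0.05 by default (a Bonferroni switch
exists); Δf = f_low − f_high is always reported, and per offset the Δf
values sum to zero when no slots are missing.

Composition profiling reports (P−Q)/Q per amino acid over the window
residues (center excluded) with a percentile bootstrap CI over windows;
residues absent from the background are reported as undefined rather than
dividing by zero.

Neighbor enrichment: a site has a neighbor at distance w if another
phospho-site of the same protein lies within ±w residues. The candidate
neighbor pool defaults to the analysis set itself and can be widened to
all detected sites (`neighbor_pool="all-sites"`), since a site excluded by
the completeness filter can still serve as a neighbor. Tables are nested
across w by construction (neighbor at w implies neighbor at w+1).

## Motif grammar and 2D enrichment

Motifs are `NAME<TAB>PATTERN` lines; `-`-separated tokens over single
residues, `X` (any), `[SET]`s and `/`-alternatives, with exactly one
`p`-prefixed phospho-accepting center token (S/T/Y only), e.g.
`R-R-X-pS/pT`. Matching requires every token's slot to be present
(non-MISSING) and allowed.

The 2D enrichment score per dimension is
$s = 2(\bar R_m − (n+1)/2)/(n−m)$ over midranks, bounded in [−1, 1] and
invariant under monotone transforms of the attribute. The joint test is a
rank-based Hotelling-type statistic: the two standardized mean-rank
z-scores (exact finite-population variance of a without-replacement mean
over the tied rank population) with their Spearman-correlation-adjusted
covariance, referred to a chi-square with 2 df, then BH-corrected across
motifs at FDR 0.01. The z-scores are asymptotically normal by the finite
population CLT, so the chi-square reference is an approximation; its
realized type-I error is verified by simulation in the test suite. The
disorder dimension uses the DISOPRED probability at the site when
available and falls back to the binary call, which midranks handle
without special cases.

The bundled motif file contains two *synthetic* textbook-style patterns
(a proline-directed `pS/pT-P` and a basophilic `R-R-X-pS/pT`) for testing
and demonstration only; real analyses should supply curated motif
definitions.

## Conservation

Controls are all never-phosphorylated S/T/Y residues of the same
proteins, stratified by the 2-level structural background taken from the
disorder call (the ordered/disordered dichotomy is a disorder-predictor
concept, so the disorder track — not the secondary-structure states — defines
the background). rate4site scores are consumed as-is, with no
re-normalization; lower = more conserved. Three MWW contrasts are
reported: phospho vs control within each background, and phospho ordered
vs phospho disordered.

## Synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions the pipeline is validated against:

| parameter | default | meaning |
|---|---|---|
| n_proteins / mean length | 1,059 / 400 aa | protein panel (gamma-distributed lengths, min 60) |
| n_sites | 5,173 | fully quantified sites |
| class quota | 145 / 353 / 4,675 | REGULAR / IRREGULAR / DISORDERED (largest-remainder rounding, exact) |
| median variability | 1.65 / 1.83 / 2.22 | per-class targets for the realized median SD |
| neighbor OR | 1.9 at w = 4 | planted disordered-vs-ordered clustering odds ratio |
| ordered pair fraction | 0.25 | fraction of ordered sites in a planted neighbor pair |
| conservation means | −0.38 / −0.28 / 0.14 / 0.22 | phospho/control × ordered/disordered stratum means |
| conservation SD | 0.5 | within-stratum score spread |
| missingness | 0.0 | per-ratio NA probability |

Mechanics and calibration:

* **Structure**: alternating ordered/disordered segments (geometric
  lengths, means 40/50); ordered segments are built from H/E runs (mean 8)
  joined by short coils (mean 4), so ordered coils are systematically
  shorter than disordered regions. Disorder probabilities are Beta(8,2)
  in disordered and Beta(2,8) in ordered stretches.
* **Ratios**: $r_t = \max(0,\, 1 + k_c\,\sigma_i\,\varepsilon_{it})$ with
  per-site $\sigma_i$ log-normal around the class target (spread 0.25)
  and $\varepsilon$ standard normal. Because the zero-truncation shrinks
  the realized SD nonlinearly, the class scale $k_c$ is root-found so
  that the realized class-median of the per-site SD equals the target
  exactly on the drawn noise — the class medians are calibrated
  quantities, not emergent ones.
* **Clustering**: primary sites sit on a 21-residue spacing grid, so no
  two independently placed sites are within ±5 of each other and the
  proximity structure is exactly the planted clustering. A fraction of
  sites per class receives a companion at a uniform distance 1..5 (the
  companion's residue is rewritten to the primary's structural class so
  the drawn distance is always honored); the disordered pair fraction is
  solved analytically from the target odds ratio at the calibration
  distance. With uniform distances the population odds-ratio curve rises
  with w (≈1.66 at w = 1 to ≈2.02 at w = 5 under the defaults); realized
  curves wobble around it because the ordered class holds only ~500
  sites, so validation asserts the planted value's CI coverage at w = 4
  and the end-to-end rising trend (OR(5) > OR(1)), not strict
  monotonicity per step.
* **Motifs**: planted per class with probabilities (REGULAR, IRREGULAR,
  DISORDERED) = (0.01, 0.03, 0.18) for the proline-directed pattern and
  (0.10, 0.08, 0.04) for the basophilic one. The proline-directed pattern
  additionally carries a variability tilt (acceptance probability ∝ the
  site's within-class variability quantile, mean-preserving), mimicking
  cell-cycle kinases preferring dynamically regulated substrates; without
  it the motif's rank signal would be nearly invisible because ~90% of
  all sites are disordered anyway.
* **Conservation**: residue scores are normal with the stratum mean
  (phospho positions override their background mean) and SD 0.5. The SD
  default is chosen so that the planted mean differences (0.08–0.10) are
  recoverable at the module's validation sample size of 500 records per
  stratum — with SD 1 the sign pattern of differences this small is a
  coin flip at that n, which would validate nothing. Real rate4site
  scores are heavier-tailed and more dispersed; the generator makes no
  claim to reproduce their full distribution, only the stratum ordering.
* Sequences are i.i.d. uniform over the 20 amino acids apart from planted
  motif residues, written S/T/Y centers (0.86/0.12/0.02), and a mild
  proline excess (+0.05) in disordered stretches.
* The seed is mandatory; one `numpy` Generator drives everything and the
  same config yields byte-identical output files.

### What the generator does *not* emulate

Real phosphoproteome data have correlated phase profiles (cyclic
trajectories, not i.i.d. noise), non-uniform amino-acid composition,
length- and abundance-biased detection, predictor errors (the generator's
"predictions" are its own ground truth), and proteins without any
detected site. Passing the recovery tests therefore shows the *pipeline*
is correct and sensitive at realistic effect sizes and sample sizes — not
that the biological conclusions would survive those confounders.

## Validation problem sizes

The test suite validates: the full default dataset (5,173 sites) once;
neighbor-OR CI coverage over 100 generator replicates; 2D-enrichment
power over 200 replicates at n = 1,000 / m = 100 with a +1 SD shift;
conservation sign-pattern recovery over 200 replicates at 500 records per
stratum; null calibration over 2,000 simulations per test (KS at
1,000 + 1,000, ANOVA at 3×50, Fisher at margins 2,000, the 2D test at
n = 1,000 / m = 50) against the two-sided binomial CI around α = 0.05.
The null sizes sit deliberately in each test's asymptotic regime: the KS
limiting distribution and Fisher's discrete p are conservative at small
samples, which is a property of those tests, not an implementation error.

## Known limitations

* The exact reference implementation of the 2D enrichment's joint
  significance test is not published in detail; the score s is exact, the
  chi-square p is this package's documented choice and may differ from
  other implementations (simulation-calibrated here).
* KS p-values are asymptotic only; very small analysis sets should not
  rely on them.
* The logo's per-cell tests are uncorrected by design (matching the
  α = 0.05 convention for two-sample logos); with 240 cells, ~12 flags are
  expected under the null. Use the Bonferroni switch for conservative
  reporting.
* The composition-profiling background here is simply a second window
  set; structure-matched background construction is left to the caller.
* `run_all` reproducibility is per-input-byte: editing a float's
  formatting in an input TSV changes the outputs' bytes even when values
  are equal.
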