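# Methods

This note documents the statistical models implemented in `rilqtl`, the
assumptions behind the synthetic-data generator, the numerical choices,
and the limitations a user should keep in mind.

## Traits and experimental design

Al tolerance is scored in nutrient solution: net root growth
NRG = FRL − IRL (cm) per plot, under control and Al treatments, and
relative net root growth RNRG = 100 · NRG_Al / NRG_c (%), computed per
(line, replicate) pair and averaged into line means. Plots are the unit of
analysis (plants within a plot are collapsed to the plot mean). The
one-way completely-randomized ANOVA on plot values gives MSG and MSE with
g − 1 and N − g degrees of freedom; with 118 lines and 2 replicate plots
this is 117/118/235. Genetic parameters follow the family-mean
conventions:

- σ²g = (MSG − MSE) / r, σ²e = MSE
- h² (family mean) = (MSG − MSE) / MSG = σ²g / (σ²g + σ²e / r), truncated to [0, 1]
- CVe = 100·√MSE / ȳ, CVg = 100·√σ²g / ȳ, and their ratio CVg/CVe

The family-mean h² formula is used because it reproduces the package's
reference pairs (562.80, 36.13) → 0.94 and (864.00, 67.30) → 0.92 at two
decimals;
negative σ²g estimates are floored at zero with a warning. RNRG is
undefined when control growth is non-positive; such records are flagged
NaN and excluded.

## Genotypes, QC and imputation

Genotypes are calls over {A, H, B, N}: homozygous for either parent,
heterozygous, or missing, with markers named `S{chr}_{bp}`. QC follows
the GBS conventions: a marker is kept iff its missing fraction is
strictly below 0.20 and its MAF (H counting half to each allele) is at or
above the threshold for its chromosome — 0.40 by default, relaxable
per chromosome (e.g. 0.30 on a distorted chromosome 10). Imputation
precedes filtering by default, and order is configurable.

Imputation is a k-nearest-neighbour vote (defaults k = 5, window
half-width 10 markers): for each missing call, lines are ranked by
mismatch fraction over shared non-missing calls in the window and the k
closest lines with an observed call vote by majority. Observed calls are
never changed; calls with no informative neighbour stay missing. In a RIL
population the local haplotype identifies the founder segment, so
accuracy is high away from recombination breakpoints and intrinsically
ambiguous at them (~96% observed at 20% missingness on the default
density). Segregation distortion is tested per marker by a 1-df χ² on the
two homozygote counts against 1:1 (H excluded, no continuity correction).

## The QTL model

The engine regresses line-level traits on allele indicators
x ∈ {0, 0.5, 1} for {A, H, B}; a coefficient is therefore the difference
between homozygote classes, the scale on which effects are reported.
Dense RIL marker coverage substitutes observed marker genotypes for QTL
genotypes; no hidden-genotype probabilities are modelled.

1. **Scan**: per marker, OLS with a two-sided t-test on n − 2 df.
2. **Forward stepwise selection** at α = 0.001: each round adds the
   marker with the smallest partial-F p-value conditional on the current
   model (equivalently the added coefficient's t-test); ties break on
   smallest (chromosome, bp); collinear candidates are skipped; the
   search stops when the best remaining p ≥ α. There is no backward
   elimination and no genome-wide multiple-testing correction — the
   pointwise threshold means spurious entries occur at a measurable rate,
   a property the test suite documents against an independent oracle.
3. **Variance partition** by nested residual sums of squares:
   R²_P = 1 − SSE_full/SSE_reduced per selected SNP (reduced = all other
   selected SNPs), R²_T = 1 − SSE_full/SST. R²_P values are not additive
   and may sum above R²_T.
4. **Epistasis**: every pair among model SNPs, and model × non-model
   pairs, tested by adding the product term to the additive model
   (partial-F at the same α; k(k−1)/2 + k(m−k) eligible pairs; degenerate
   product columns are counted as untested).
5. **Peaks and intervals**: the peak is the marker with the highest
   conditional −log₁₀(P) on the focal chromosome (other model SNPs as
   covariates); the default interval spans all markers within 1.0
   −log₁₀(P) unit of the peak (a 95%-like support interval), with a
   case-resampling bootstrap (percentile 2.5/97.5 of re-located peaks) as
   an alternative since no exact construction is canonical.

**Declared QTLs.** Forward-only selection can tag one causal region with
two correlated SNPs: an early proxy pick plus the better tag that later
makes it conditionally non-significant. The report therefore declares a
QTL as a *region*: model SNPs that remain significant in the final model
(conditional p < α) are merged on a chromosome when their support
intervals overlap or one peak lies inside the other's interval, and the
most significant SNP represents the region. The complete selection path
remains available in `QtlResults.qtls`. Lines missing a genotype at a
fitted marker are dropped casewise for that fit.

## Panel mixed model

y = Xt + Zg + Wb + e with experiments fixed and genotypes/blocks random,
i.i.d. with homogeneous variances; blocks are nested within experiments
(the block factor is the experiment:block pair). Common checks are
ordinary genotypes and connect the experiments; a bipartite connectivity
check fails fast with the disconnected groups named. REML maximizes the
restricted log-likelihood directly (L-BFGS-B on (σ²g, σ²b, σ²e) bounded
at zero, relative tolerance 1e-8, max 500 iterations, derivative-free
polish on difficult surfaces); Henderson's mixed-model equations at the
optimum give BLUPs and PEV. A variance component in which the restricted
likelihood is flat (e.g. a block factor fully confounded with the mean)
is pruned to zero rather than left at an arbitrary value. PEV is computed
for the *predicted genotypic value* μ + g (contrast: average experiment
effect + genotype), so uncertainty that is inseparable between the mean
and the genotype average cancels instead of inflating every genotype —
this makes PEV → 0 on noise-free data and keeps the empirical coverage of
(μ + g) ± 1.96·SEP at the nominal 95%. Accuracy is √(1 − PEV/σ²g)
(0 when σ²g = 0); broad-sense h² = σ²g/(σ²g + σ²b + σ²e). Pairwise
comparisons call two genotypes different iff their CIs are disjoint;
touching endpoints count as overlap.

## qPCR quantification

Pure ddCT with a fixed per-cycle amplification factor of 2:
ΔCt = mean Ct(target) − mean Ct(reference) per sample and assay,
ΔΔCt subtracts the calibrator sample, RQ = 2^(−ΔΔCt). Dispersion is the
SD of replicate-level RQ values (each replicate pairing its own target
and reference Ct). Copy number applies the same arithmetic against a
single-copy control assay and multiplies by the calibrator's copy count;
two assays (e.g. CNV2/CNV4) are reported separately and as an arithmetic
mean consensus, rounded to an integer only in the summary column and
withheld when the assays disagree more than 2-fold.

## Synthetic-data generator

The generator fixes the study conditions once:

- **Map**: 10 chromosomes with maize-like physical spans (301…150 Mbp),
  1 cM ≈ 1 Mbp, 2,000 evenly spaced markers per chromosome — a
  scaled-down density that keeps the simulations comfortably fast while
  preserving near-complete tagging of any causal position.
- **Meiosis**: Haldane model — crossover counts Poisson in map distance,
  no interference; between adjacent markers a gamete switches haplotype
  with probability r = (1 − e^(−2d/100))/2. RILs are produced from a
  fully heterozygous F1 by 7 rounds of selfing with independent gamete
  formation, so heterozygosity decays as (1/2)^g and the RIL recombinant
  fraction approaches 2r/(1 + 2r).
- **Phenotypes**: line genetic value = 30 (baseline) + Σ effect ×
  indicator, with the five reference QTLs (9.14, 13.11, 9.82, 14.21,
  10.43 on chromosomes 2, 3, 5, 6, 8 at their reference positions); the
  baseline puts the grand mean near the ~58% implied by the published
  CVs. Plot noise σ²e is solved from the target family-mean h² = 0.94 at
  r = 2 using the realized genetic variance. Plot records are emitted as
  IRL/FRL pairs whose derived RNRG reproduces the simulated values
  exactly; plants within plots are not modelled individually.
- **Degradation**: i.i.d. missingness at 0.20 (GBS-like), and segregation
  distortion on chromosome 10 by re-weighting founder assignments to an
  allele frequency of 0.25 — emulating selection favouring one parent,
  at the cost of exaggerated marker-to-marker correlation of the
  distortion signal on that chromosome.
- **Expression**: line-level traits with eQTL effect sizes back-solved
  from target variance fractions at the realized dosage variance
  (e.g. a cis eQTL at 70.9%).
- **qPCR**: target Ct shifted by −log₂(quantity ratio) per doubling
  (general efficiency supported), Gaussian Ct noise.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: polygenic background variance (all genetic
variance sits in the planted QTLs, so model R²_T ≈ h², unlike real
populations where many small QTLs stay unmapped), genotyping error beyond
missingness, linkage-map/physical-map nonlinearity, selection during line
development, and within-plot variation.

## Numerical choices

- −log₁₀(P) is computed from `t.logsf`, so enormous t statistics do not
  underflow; an exact fit reports +inf and support intervals collapse to
  the perfect-LD block of the causal marker.
- Collinearity: residualized predictor variance below 1e-9 marks a
  candidate unusable (skipped, or counted untested in epistasis).
- Variance components are floored at zero; σ²e is kept at a tiny positive
  floor for numerical stability; a perfect-fit boundary solution is
  accepted as converged.
- MAF uses non-missing calls only; an all-missing marker has MAF 0 and is
  removed by the missingness rule first.
- Coordinates are 1-based closed intervals in bp; Mbp = bp/10⁶ reported
  to 2 decimals (1 decimal for introgression segment lengths). Segment
  boundaries default to midpoints between the outermost donor-allele
  markers and their flanking recurrent-allele markers; the outermost
  convention is selectable.
- Determinism: every stochastic routine takes a mandatory seed; pipeline
  outputs embed the package version, seed and config hash, and reruns are
  byte-identical.

## Problem sizes

The default simulations use 118 lines × 20,000 markers for the mapping
experiment (about 10 s per seed end-to-end), 500–2,000 markers for
focused unit experiments, and panels of 40–100 genotypes for the mixed
model. These sizes make the full test suite and the acceptance script
each run in minutes on a single CPU while leaving every statistical
property measurable.
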