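# Methods

## The model

`crossvar` treats a biparental cross panel as n strains measured m times
(m = Σ replicates). The phenotype vector y follows

    y = Xβ + Z a + Z i + Z p + e,

with Z the m×n incidence matrix of measurements to strains and independent
Gaussian random effects

    a ~ N(0, σ²_a A),   i ~ N(0, σ²_i A∘A),   p ~ N(0, σ²_p I_n),   e ~ N(0, σ²_e I_m).

`A` is the additive GRM; `A∘A`, its entrywise (Hadamard) square, is the
natural covariance of pairwise locus-product effects because for mean-zero
±1 genotypes E[(g_j g_k)(g'_j g'_k)] factorizes across loci; the entrywise
cube extends this to three-way interactions and is available as an optional
component. σ²_p absorbs any strain-level covariance not captured by A and
A∘A (higher-order interactions, micro-environment shared by replicates);
σ²_e is replicate-level measurement error. Reported quantities are variance
*fractions* σ²_c / Σσ²; their standard errors come from the delta method on
the inverse average-information matrix.

### GRM convention

A is the raw cross-product (1/M)·G·Gᵀ on ±1 codes, so the diagonal is
exactly 1 and "fraction of genome shared" is (A+1)/2. An allele-frequency
centred/scaled GRM (as produced by rrBLUP's `A.mat`) differs from this by an
affine map when allele frequencies are ≈0.5, as in a cross; the map is
absorbed by the intercept and the variance scale, so fractions are
unaffected while Hadamard identities ((A∘A)_jk = A²_jk exactly) are kept
exact. Absolute σ² values are convention-dependent and not comparable
across conventions.

`pair_product_grm` (explicit significant pairs) excludes self-pairs j=j,
whereas the Hadamard square implicitly includes the same-marker "pair"
diagonal term; the discrepancy is O(1/M) and negligible for dense maps
(a unit test pins down the exact algebraic relation at small M).

## AI-REML

The restricted likelihood of V = Σ_c σ²_c Z K_c Zᵀ + σ²_p ZZᵀ + σ²_e I_m is
maximised by Newton-type average-information (AI) steps. Numerical choices:

- **Initialisation**: var(y) split equally over all components.
- **First step**: one EM-REML update before switching to AI; AI is unstable
  far from the optimum.
- **Monotonicity**: a proposed step is accepted only if the restricted
  log-likelihood does not decrease; otherwise the AI step is halved
  (several times), then an EM step is tried. Accepted iterations are
  therefore monotone; if no step improves, the fit stops at the current
  point.
- **Boundary**: components are clamped at 1e−6·var(y). A clamped component
  is dropped from the AI system while its score is non-positive and
  re-enters when the score turns positive.
- **Convergence**: |Δ restricted log-likelihood| < 1e−4 (configurable);
  non-convergence within `max_iter` is flagged on the result, not raised.
- **Standard errors**: square roots of the diagonal of the inverse AI
  matrix at convergence (the average-information approximation to the
  Fisher information).
- **Balanced reduction**: with equal replicate counts and strain-constant
  fixed effects the model factorizes exactly into an n-dimensional model on
  strain means (covariance rG + σ²_e I) plus an independent within-strain
  chi-square block carrying (m−n) error degrees of freedom. The engine uses
  this reduction whenever it applies — the restricted likelihood is
  identical to the m-dimensional form (verified to machine precision in the
  tests) — and falls back to the full m-dimensional form for unbalanced
  designs.
- **Degenerate input**: a constant phenotype yields all components at the
  boundary and a finite likelihood.

BLUPs are û_c = σ̂²_c K_c Zᵀ V̂⁻¹(y − Xβ̂), computed in the reduced space via
the identity ZᵀV⁻¹ = (rG + σ²_e I)⁻¹Zᵀ.

## Genome scans

**Additive.** For each chromosome the polygenic additive term is replaced by
a_loco built from all other chromosomes (the interaction GRM stays
genome-wide: only the additive term risks absorbing the tested signal, and
keeping A∘A intact retains power). BLUP residuals — y minus the additive-LOCO
and interaction BLUPs and minus any fixed peak-marker effects — are averaged
per strain and scanned with LOD = −n·ln(1−r²)/(2 ln10) (r² capped at
1 − 1e−12). Thresholds are the ⌈(1−α)·n_perm⌉-th smallest chromosome-wide
maximum over permutations of residuals against strain labels, recomputed
every round on the current residuals. The forward search adds one peak per
chromosome per round (ties break to the lowest marker index), conditions on
it as a fixed effect, and stops when nothing passes; a per-chromosome round
cap (default 30) guards against pathological inputs. Support intervals are
the widest contiguous run with LOD ≥ peak − 1.5.

**Interactions.** Residuals come from the additive-only polygenic model
(components A, strain, error); only the additive BLUP is subtracted —
subtracting the strain BLUP would absorb exactly the interaction signal
being sought. The scan statistic applies the same LOD formula to the
product g_j·g_k, restricted to pairs ≥ 50 genome-order indices apart
(suppressing linkage-driven artefacts; inter-chromosome pairs closer than
50 indices across a boundary are conservatively excluded too — a negligible
sliver of the search space). All pair correlations reduce to two M×M Gram
products, so the full 2D scan is two BLAS calls; a memory cap refuses
M > 12,000 unless tiling is requested. 2D peaks are extracted greedily:
take the highest remaining pair, suppress everything within ±50 indices in
*both* coordinates, repeat down to a reporting floor (LOD 3). FDR(t) is the
mean permutation peak count ≥ t divided by the observed count ≥ t, with the
observed distinct peak LODs as the candidate grid; the smallest t with
FDR ≤ 10% is the threshold. Peak classification (both/one/neither member an
additive QTL) uses peak-marker identity within ±50 indices.

All permutation seeds derive deterministically from one base seed via
CRC-32 of (seed, trait, chromosome/scan, round), so reruns are bit-identical
and independent stages do not share streams.

## Variance capture and effect sizes

Captured additive variance refits y = Xβ + Za + Zp + e with A built only
from peak markers and compares against the all-marker fit. Interaction
partition swaps A∘A for A_QTL∘A_QTL, A_QTL∘A or the explicit
significant-pair GRM QQ, always alongside the full additive term; the ratio
of the QQ (or QTL×QTL) fraction to the genome×genome fraction is computed
per trait and the median over traits is taken. Background controls re-fit
the reduced strain-mean model (repeatability term excluded) for 50 random
draws of N markers or N separated pairs and report the median captured
fraction. Per-locus effect sizes are sequential (entry-order) sums of
squares over the fixed-effect regression on peak markers then pair
products — sequential SS depends on the order, which is defined as detection
order; aliased columns are dropped with a warning and contribute zero.

## The synthetic cross

Genotypes: each segregant starts each chromosome in either parental state
with probability 1/2; a Poisson number of crossovers (genome mean 65 —
mid-envelope of the 25–105 breakpoint QC range — apportioned over
chromosomes by marker span) is placed uniformly; no crossover interference.
Chromosome count defaults to 16 with relative lengths of the yeast nuclear
genome. Observed breakpoint counts slightly undercount crossovers on sparse
maps (double crossovers inside one marker interval cancel), which is also
true of real marker data.

Phenotypes: additive loci are placed uniformly at random with
equal-magnitude random-sign effects, rescaled so the sample variance of
their sum hits the target additive fraction; interacting pairs are drawn
from combinations of the additive loci (overflow pairs go to loci with no
marginal effect) and act through the ±1 genotype product, rescaled to the
target interaction fraction. The genetic value g is the sum of the two
scaled parts; the total implied phenotypic variance is var(g)/H², strain
effects and replicate errors are drawn to fill their fractions of it (for
strain_var = 0 the error variance is (1−H²)/H²·var(g)). Replicates default
to 2. Error is drawn independently per replicate measurement; the strain
effect is the only non-genetic structure shared within a strain.

What the generator does *not* emulate: missing genotypes, segregation
distortion, crossover interference, tetrad structure, non-Gaussian or
heteroskedastic measurement error, shared plate/batch effects, and
unequal-magnitude effect distributions. Passing tests therefore demonstrate
correctness of the estimators and scan machinery under the assumed model,
not robustness to those real-data features.

## Scale of the built-in checks

The test suite and the acceptance script run everything at workstation
scale, chosen so each check still has the statistical resolution it needs:
variance-component recovery and scans use 800–1,000 strains with 600–2,000
markers and duplicate measurements; the architecture-grid recovery check
uses the full QTL-count × additive-fraction grid (counts 0/1/5/10/50/500,
broad-sense 0.75, additive steps of 0.15, three seeds per cell) on one
1,000×2,000 panel; null calibration uses 500 traits × 300 permutations.
Cells whose interaction variance is concentrated in a single large-effect
pair are excluded from the grid regression (defined here as one pair
carrying ≥ 0.30 of phenotypic variance): a single product locus is then the
entire interaction kernel, the Hadamard GRM is a poor basis for it, and
estimates are known to be wildly unstable — real traits do not show such
architectures. At these scales the scans detect the handful of loci the
simulated effects make detectable; sub-percent per-locus effects, which
dominate full-size panels, require thousands of segregants (see the power
module) and are deliberately out of reach of the desk-scale runs.

## Known limitations

- Variance fractions for interaction vs repeatability are weakly separated
  at n ≤ 1,000 with duplicate replicates: single-trait estimates can
  collapse one of the two to the boundary, which is why median-over-traits
  summaries are reported.
- The LOCO model leaves the interaction GRM genome-wide; the alternative
  (excluding the focal chromosome from A∘A as well) would cost one Hadamard
  product per chromosome and differs negligibly for 16 chromosomes.
- Sequential ANOVA effect sizes depend on term order (detection order used).
- The FDR permutation count (5) follows the standard practice for
  2D scans; the resulting threshold is coarse by construction.
- `import_rdata` (conversion of deposited RData objects) needs the optional
  `pyreadr` dependency and is exercised only when it is installed.
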