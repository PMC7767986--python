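# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limits of what the package's tests demonstrate.

## Synthetic population

**Allele frequencies.** Ancestral frequencies are uniform on a configurable
interval (default (0.05, 0.95)); each breed's frequency at a locus is an
independent Balding–Nichols draw, `Beta(p(1−F)/F, (1−p)(1−F)/F)`, which has
mean `p` and variance `F·p(1−p)` for divergence `F` (default fst = 0.1,
clipped to [0.001, 0.999]; `F = 0` short-circuits to the ancestral vector).
Realized between-breed FST, estimated Hudson-style from purebred samples, is
tested to land within 20% of the configured value.

**Genotypes.** Loci are independent — there is no recombination map and no
within-breed LD. Purebreds are Binomial(2, p_breed) per locus (HWE); an F1
receives one gamete from each breed's frequencies; backcrosses (75:25,
25:75) receive one purebred gamete and one gamete sampled allele-by-allele
from a simulated F1 parent. This reproduces exact breed fractions
{1, ¾, ½, ¼, 0} and the expected dosage gradients, but deliberately not
LD structure (see Limitations).

**QTL effects.** `n_qtl` loci (default 300 of 5,000) are drawn uniformly;
effects come from the non-null components of the same four-component
mixture the Bayesian model assumes (renormalized proportions, variances
`fraction·σ²g`), then all effects are rescaled so the empirical variance of
true breeding values (TBV) in the pure-H group equals `σ²g` exactly. TBV is
the dosage-weighted effect sum.

**DRP phenotypes.** Each cow gets a record count n ~ U{1..10}, each bull a
daughter count p ~ U{20..300} (defaults). Reliability is
`r² = n·h²/(1+(n−1)t)` for cows and `r² = p/(p+(4−h²)/h²)` for bulls, and
DRP = TBV + fixed effects + ε with `Var(ε) = σ²g(1−r²)/r²`. The fixed part
is a sex effect (0.25) and a breed mean shift proportional to the Jersey
fraction (0.5), which makes the model's sex and breed-group fixed effects
identifiable. Record counts are trait-independent, so the three milk traits
(milk, fat, protein) share weights and differ only in the noise draw; they
share the genetic architecture, i.e. they behave as perfectly genetically
correlated traits.

A deliberate and consequential property of this emulation: the weights
assume a fraction c = 0.2 of genetic variance not captured by markers, but
the simulated DRP contains no such component (markers explain all genetic
variance). The model's assumed residual variance per animal,
`σ²e/w = σ²g(c + (1−r²)/r²)`, therefore overstates the simulated noise by
`c·σ²g`, which shrinks GEBV slightly too hard and pushes validation
regression slopes above 1 (verified: slopes return to ≈1.0 when c-consistent
weights are used). See Limitations for what this means for the bias
contrasts.

**Reference designs.** A shared validation set (10% of the cows of each of
the five breed groups, minimum 2) is carved out first; all designs exclude
it. Ref1/Ref2 are all pure H / pure J animals; Ref3 their union; Ref4 (and
Ref4p) score validation animals as breed-fraction-weighted averages of the
Ref1 and Ref2 predictions (fractions from PCA group calls, or continuous
admixture fractions for Ref4p); Ref5 adds all crossbred cows to Ref3;
Ref6 equalizes H and J bulls and purebred cows; Ref7 keeps the same bulls
and replaces the purebred cows by the same number of crossbred cows (side
backcross groups capped by the smaller pool, remainder from the 50:50
group); Ref8 unions Ref6 and Ref7. Subsets are seeded random samples.
Default group sizes (450/110 H/J bulls, 800/400 H/J cows, 600/550/160
crossbred cows, ≈3,070 animals) scale the published H-dominated structure
down by roughly one twelfth.

## Weighted GBLUP

Fixed effects are intercept + sex + breed group (first level reference;
columns aliased with earlier ones are dropped left-to-right with a warning).
With one record per animal, Z is a selection matrix and the mixed-model
equations

```
[ X'E⁻¹X   X'E⁻¹Z        ] [b]   [X'E⁻¹y]
[ Z'E⁻¹X   Z'E⁻¹Z + G⁻¹λ ] [u] = [Z'E⁻¹y]
```

are assembled densely and solved by Cholesky factorization; unphenotyped
(validation) animals have zero incidence rows and receive GEBV through the
`G⁻¹` coupling, which equals the conditional mean given the reference
solutions. `G` gets a 1e-6 diagonal ridge before inversion (configurable;
the GBLUP↔SNP-BLUP oracle uses 1e-8 so the comparison isn't limited by the
ridge). In the default "fixed" variance mode `σ²e = σ²g(1−h²)/h²`, so
`λ = (1−h²)/h²`; this makes the weighted residual variance of animal i
exactly `σ²g(c + (1−r²)/r²)`, the scale on which the cow/bull weights are
derived. An EM-REML mode (updates of σ²g from `û'G⁻¹û` plus its
prediction-error trace, σ²e from the weighted residual inner product,
relative tolerance 1e-6, 200 iterations) is available when variance
components should be estimated instead. A multi-trait entry point
factorizes the coefficient matrix once for traits sharing weights.

## Mixture-prior SNP model

The sampler state is the residual vector, updated incrementally. Each
iteration: (i) fixed effects are drawn from their weighted least-squares
conditional (flat prior); (ii) SNPs are visited in a freshly shuffled,
seeded order; for each SNP the 4-way component indicator is sampled from
the conditional posterior computed from the marginal likelihood of the
SNP's weighted least-squares estimate (`r_ls ~ N(0, σ²k + σ²e/C_j)` per
component, with the null component a point mass), then the effect from its
conditional normal. DRP weights enter as inverse residual-variance
multipliers throughout, mirroring the GBLUP residual structure. σ²g and σ²e
are fixed from the config (the residual-update option is off by default);
mixing proportions are fixed. The EM warm start runs
conditional-expectation sweeps (responsibility-weighted posterior-mean
updates per SNP, refreshed fixed effects per sweep) until the largest
effect change is below 1e-7 or 2,200 sweeps, with a divergence guard.
Default protocol: warm start once, then five chains (seeds base+0..4),
10,000 iterations, 2,000 burn-in, posterior means and component
probabilities averaged across chains. Hot loops are numba-compiled; a chain
is a pure function of its arguments and seed.

Oracles: a single-SNP chain agrees with direct numerical integration of the
four-component posterior (intercept integrated out by projection) to well
under 0.02; with all prior mass on one non-null component the posterior
means correlate ≥ 0.999 with ridge regression at matched shrinkage.

## Breed assignment

PCA scores are `eigvec·sqrt(eigval)` of the GRM, components in decreasing
eigenvalue order, sign fixed by the largest-magnitude loading (orientation
to "H high" is applied where pedigree anchors exist). Group allocation
computes pedigree-anchored per-group PC1 means, requires them monotone in
Holstein fraction (flipping the axis if reversed), places boundaries at
midpoints of adjacent means, and assigns every animal by score — so
mislabeled or unlabeled animals are corrected.

Admixture (k = 2 only) maximizes the binomial likelihood with EM block
updates of Q (per-animal simplex) and F (per-population frequencies,
clipped to [0.001, 0.999]). Q is initialized from PC1 rescaled to [0, 1], F
from sample frequencies with seeded ±0.05 noise. Plain EM approaches the
boundary optima sublinearly, so each cycle applies SQUAREM extrapolation
from two EM steps, accepted only when it does not decrease the
log-likelihood — the recorded trajectory is therefore monotone by
construction (asserted per iteration in tests). Convergence is a
log-likelihood gain below 1e-6 within 500 cycles; non-convergence sets a
flag rather than raising. Flat likelihoods (e.g. zero divergence) are
detected by comparing against the single-population fit: if the k = 2 gain
is below the extra parameter count (n + m), the result is flagged
unidentifiable. Population labels are mapped to H/J by correlating F rows
with pedigree-purebred sample frequencies.

At the tested divergence (fst 0.1, 2,000 SNPs) a per-animal ancestry
estimate carries sampling noise of sd ≈ 0.035, so recovery is asserted on
group means (purebreds ≥ 0.95 own-breed, F1 mean in [0.45, 0.55]);
individual purebreds a few SD off the boundary are expected, not errors.

## Marker QC and panels

MAF filtering removes SNPs with minor allele frequency strictly below the
threshold (0.002 in the pipeline), computed over the analysis animal set.
LD pruning slides a 100-SNP window with step 50 in position order, drops
the lower-priority member of any pair with dosage r² above 0.95 (tie: the
later SNP; monomorphic SNPs are skipped and kept), and repeats passes over
the survivors to a fixed point, making the operation idempotent. The GRM is
VanRaden method 1, `G = MM'/(2Σp(1−p))`, with centering frequencies
recomputed from each design's reference + validation animals — this is what
makes across-breed relationship distributions shift with reference
composition, and it is exercised by a dedicated test.

Panels: `tag` holds markers only (the conventional-chip analogue — with
independent loci it carries no causal signal by construction),
`causal_enriched` holds 90% of the QTL plus markers to the same total size,
`pruned_dense` is the LD-pruned full set. Design contrasts are computed on
the pruned dense panel; the tag/causal-enriched contrast is run within
breed.

## Evaluation grid

Each (design, method, panel, trait) cell restricts genotypes to the
design's reference + validation animals, re-applies the MAF filter there,
rebuilds the GRM or standardized matrix with that animal set's frequencies,
fits, predicts the validation animals, and scores accuracy (Pearson r of
GEBV with DRP) and bias (slope of DRP on GEBV) per validation breed group;
per-trait rows are accompanied by across-trait arithmetic means. Cells that
fail are recorded with a status message and NaN metrics; the grid
continues. All seeds are derived from a single base seed and the grid is
bit-for-bit reproducible (tested).

Problem sizes: the replicated design study uses 10 seeded replicates of the
default ≈3,070-animal, 5,000-SNP, 300-QTL population with three traits
averaged, which keeps the full grid a few minutes on one CPU; unit tests
use smaller draws of the same generator.

## Known limitations

* **No LD.** Loci are independent, so mechanisms that run through
  LD-phase differences between breeds — the main driver of across-breed
  overdispersion (validation slopes below 1) in real multi-breed data — are
  absent. In this generator, across-breed transfer is limited only by
  allele-frequency differences and reference composition.
* **Bias regime.** Because of the c-mismatch described above, simulated
  predictions sit in a mild *under*-dispersion regime (slopes above 1).
  Contrasts whose real-data direction depends on starting from
  overdispersion — the weighted-average combination being closer to slope 1
  than the joint reference, and the breed-balanced reference reducing the
  Jersey slope deviation — do not reproduce here and their acceptance
  checks are left failing by design rather than re-tuned. Accuracy-based
  orderings (within- vs across-breed, the value of crossbred reference
  cows, causal-enriched vs tag panels) do reproduce.
* **Desk scale.** With ≈250 validation cows, per-group slope estimates have
  sampling sds comparable to the real-data effect sizes; replicate-majority
  checks near their threshold can flip with the seed.
* **Simplified pedigree.** No recorded sires/dams, no selection, no
  heterosis or dominance; the breed fixed effect is a mean shift linear in
  breed fraction. Validation/reference separation enforces disjointness
  only, not half-sib bookkeeping.
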