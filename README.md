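# crossgp

Genomic prediction for multi-breed and crossbred dairy populations.

Dairy cattle in several countries — New Zealand prominently — are a mix of
Holstein (H), Jersey (J) and their crosses, yet genomic reference
populations are usually dominated by one breed. `crossgp` is a study
pipeline for the question that raises: **how should the reference population
and the marker panel be composed to predict purebred and crossbred cows
well, and how biased are the resulting predictions?** Because the industry
data this question is usually studied on are access-restricted, the package
ships a first-class synthetic-population generator and answers the question
on simulated Holstein/Jersey-like data, with every modelling step exposed as
a tested library function.

It is aimed at animal-breeding researchers and statistical geneticists who
want a transparent, reproducible sandbox for multi-breed reference design.

## What it implements

**Weighted GBLUP on deregressed proofs (DRP).** The mixed model

```
y = Xb + Zu + e,   Var(u) = G σ²g,   Var(e) = E σ²e,  diag(E)_i = 1/w_i
```

where `y` are DRP, `X` carries mean, sex and breed-group effects, `G` is the
VanRaden (method 1) genomic relationship matrix and the DRP weights are

```
w_cow  = (1 − h²) / ( c·h² + [1 + (n−1)·t]/n − h² )
w_bull = (1 − h²) / ( c·h² + (4 − h²)/p )
```

with heritability h² = 0.33, repeatability t = 0.56, unexplained-marker-
variance fraction c = 0.2, n cow records and p bull daughters. Validation
animals enter the equations with zero incidence and are predicted through
the G-inverse coupling.

**A four-component mixture-prior Bayesian SNP model** (BayesR family with an
approximate-EM warm start): `y = Xb + Wv + e` with standardized genotypes
`W` and each SNP effect a priori from
`π = (0.94, 0.049, 0.01, 0.001)` normals with variances
`(0, 10⁻⁴, 10⁻³, 10⁻²) · σ²g` — i.e. a 94% prior chance of a null SNP.
Five Gibbs chains are launched from the EM solution and averaged.

**Breed assignment.** Animals are allocated to five breed groups
(H, 75%H:25%J, 50%H:50%J, 25%H:75%J, J) from PC1 of the GRM anchored by
pedigree breed codes, and continuous breed fractions are estimated with a
k = 2 admixture model (binomial likelihood, EM block updates with monotone
log-likelihood, SQUAREM acceleration).

**Reference designs and scoring.** Eight reference sets (purebred H, purebred
J, joint, breed-proportion-weighted purebred combinations WA-GEBV, joint +
crossbreds, and three size-matched breed-balanced sets) share one validation
cow set spanning all five groups. Accuracy is the Pearson correlation of
GEBV with DRP; bias is the slope of DRP regressed on GEBV (1 = unbiased).
Marker-panel contrasts (conventional tag panel vs causal-enriched panel vs
pruned dense panel) are represented through panels that exclude or include
the simulated causal variants.

## Worked example

```python
import numpy as np
import crossgp as cg

params = cg.WeightParams(h2=0.33, t=0.56, c=0.2)
print(f"cow weight, 1 lactation record : {cg.cow_weight(params, 1):.3f}")
print(f"cow weight, 8 records          : {cg.cow_weight(params, 8):.3f}")
print(f"bull weight, 100 daughters     : {cg.bull_weight(params, 100):.3f}")

cfg = cg.SimConfig(seed=7, n_snp=1500, n_qtl=100,
                   group_sizes={"H_bull": 120, "H_cow": 600,
                                "J_bull": 40, "J_cow": 240,
                                "75H25J_cow": 200, "50H50J_cow": 200,
                                "25H75J_cow": 80})
pop = cg.simulate_population(cfg)
drp = cg.simulate_drp(pop, cfg, seed=8)
designs, validation = cg.build_reference_designs(pop, seed=9)
ref3 = next(d for d in designs if d.name == "Ref3")   # joint purebred ref

ids = np.concatenate([ref3.reference_ids, ref3.validation_ids])
gm = cg.filter_maf(pop.genotypes.subset_animals(ids), 0.002)
fit = cg.fit_wgblup(drp.subset(ref3.reference_ids), cg.build_grm(gm),
                    params=params, sigma2_g=cfg.sigma2_g)
gebv = fit.gebv.loc[list(ref3.validation_ids)]
drp_val = drp.subset(ref3.validation_ids)
for group in ("H", "50H50J", "J"):
    sel = drp_val.breed_group == group
    print(f"Ref3 -> {group:7s} validation: "
          f"accuracy {cg.accuracy(gebv.to_numpy()[sel], drp_val.y[sel]):.3f}, "
          f"bias {cg.bias(gebv.to_numpy()[sel], drp_val.y[sel]):.2f} "
          f"(n={sel.sum()})")
```

prints

```
cow weight, 1 lactation record : 0.910
cow weight, 8 records          : 1.909
bull weight, 100 daughters     : 6.524
Ref3 -> H       validation: accuracy 0.388, bias 1.21 (n=60)
Ref3 -> 50H50J  validation: accuracy 0.737, bias 2.15 (n=20)
Ref3 -> J       validation: accuracy 0.368, bias 0.82 (n=24)
```

The weights say a single cow lactation carries slightly less information
than one ideal record (0.91), eight records almost double that, and a
100-daughter bull proof is worth about 6.5 records. The design comparison
says the H-dominated joint reference predicts both purebred groups at
moderate accuracy but leaves crossbred predictions visibly miscalibrated
(slope 2.15 instead of 1) — the kind of effect the reference-design study
quantifies systematically.

## The analysis

Numbered drivers under `analysis/` walk through the study on the default
~3,000-animal population and write tables under `results/`:

1. `01_simulate_population.py` — population, DRP tables, truth tables.
2. `02_marker_qc.py` — MAF filter, LD pruning, GRM, frequency-source effect.
3. `03_breed_assignment.py` — PCA allocation vs admixture fractions.
4. `04_reference_designs.py` — composition of the eight reference sets.
5. `05_prediction_experiment.py` — the full design × panel × method grid.

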