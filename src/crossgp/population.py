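"""Synthetic two-breed + crossbred dairy population.

Generates the stand-in for a restricted industry data set: two diverged
breeds (H, J) with Balding-Nichols allele-frequency divergence, crossbred
cows at 75:25 / 50:50 / 25:75 H:J composition, sparse QTL effects drawn from
a four-component mixture prior, deregressed-proof (DRP) phenotypes with
reliabilities implied by record/daughter counts, and the family of
reference/validation designs used to compare prediction strategies.

Loci are simulated independently (no recombination map); marker-panel
contrasts are therefore represented by whether a panel includes the causal
variants, not by map distance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayesr import MixturePrior
from .gblup import (DRPTable, WeightParams, bull_reliability, bull_weight,
                    cow_reliability, cow_weight)
from .markers import GenotypeMatrix

__all__ = [
    "SimConfig",
    "Population",
    "ReferenceDesign",
    "BREED_GROUPS",
    "GROUP_FRACTIONS",
    "draw_breed_allele_freqs",
    "simulate_genotypes",
    "assign_qtl_effects",
    "simulate_population",
    "simulate_drp",
    "build_reference_designs",
]

#: breed groups ordered by Holstein fraction
BREED_GROUPS = ("J", "25H75J", "50H50J", "75H25J", "H")
#: nominal (fH, fJ) per breed group
GROUP_FRACTIONS = {
    "H": (1.0, 0.0),
    "75H25J": (0.75, 0.25),
    "50H50J": (0.5, 0.5),
    "25H75J": (0.25, 0.75),
    "J": (0.0, 1.0),
}

_DEFAULT_GROUP_SIZES = {
    # roughly a 1:12 scale-down of the real H-dominated population structure
    "H_bull": 450,
    "J_bull": 110,
    "H_cow": 800,
    "J_cow": 400,
    "75H25J_cow": 600,
    "50H50J_cow": 550,
    "25H75J_cow": 160,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults give ~3,000 animals on 5,000 independent SNPs with 300 QTL and
    the dairy-trait variance structure h2 = 0.33, repeatability t = 0.56 and
    unexplained-marker-variance fraction c = 0.2.
    """

    seed: int = 0
    n_snp: int = 5000
    n_qtl: int = 300
    fst: float = 0.1
    ancestral_freq_range: tuple = (0.05, 0.95)
    group_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_SIZES))
    h2: float = 0.33
    t: float = 0.56
    c: float = 0.2
    sigma2_g: float = 1.0
    j_mean_shift: float = 0.5   # breed fixed effect: added to DRP as shift * fJ
    sex_effect: float = 0.25    # bull - cow fixed-effect difference on the DRP
    records_range: tuple = (1, 10)     # cow record counts n (inclusive)
    daughters_range: tuple = (20, 300)  # bull daughter counts p (inclusive)

    def __post_init__(self):
        if not 0.0 <= self.fst <= 0.5:
            raise ValueError(f"fst must be in [0, 0.5], got {self.fst}")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0,1)")
        if not self.h2 <= self.t < 1.0:
            raise ValueError("repeatability t must be in [h2, 1)")
        if not 0.0 <= self.c < 1.0:
            raise ValueError("c must be in [0,1)")
        if self.n_qtl > self.n_snp:
            raise ValueError("n_qtl cannot exceed n_snp")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_freq_range must lie inside (0,1)")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")

    @property
    def weight_params(self) -> WeightParams:
        return WeightParams(self.h2, self.t, self.c)


@dataclass
class Population:
    """Simulated animals with genotypes, truth values and group labels."""

    genotypes: GenotypeMatrix
    tbv: np.ndarray                 # true breeding values (marker sum)
    qtl_effects: np.ndarray         # per-SNP, zero for non-QTL
    qtl_indices: np.ndarray
    breed_fractions_true: np.ndarray  # (n, 2): columns fH, fJ
    sex: np.ndarray                 # "bull" / "cow"
    breed_group_true: np.ndarray
    config: SimConfig | None = None

    @property
    def animal_ids(self) -> np.ndarray:
        return self.genotypes.animal_ids

    def ids_of(self, group: str, sex: str | None = None) -> np.ndarray:
        mask = self.breed_group_true == group
        if sex is not None:
            mask &= self.sex == sex
        return self.animal_ids[mask]


@dataclass
class ReferenceDesign:
    """A named reference/validation split.

    ``combine_rule`` is "direct" (one model on the reference) or
    "weighted_average" (per-breed GEBV from the two ``component_designs``
    combined by breed fractions from ``breed_fraction_source``).
    """

    name: str
    reference_ids: np.ndarray
    validation_ids: np.ndarray
    combine_rule: str = "direct"
    component_designs: tuple = ()
    breed_fraction_source: str = "truth"

    def __post_init__(self):
        self.reference_ids = np.asarray(self.reference_ids, dtype=object)
        self.validation_ids = np.asarray(self.validation_ids, dtype=object)
        if set(self.reference_ids) & set(self.validation_ids):
            raise ValueError(f"{self.name}: reference and validation overlap")
        if self.combine_rule == "weighted_average" and len(self.component_designs) != 2:
            raise ValueError("weighted_average designs need exactly two components")
        if self.combine_rule not in ("direct", "weighted_average"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")


def draw_breed_allele_freqs(p_ancestral, fst: float, seed: int):
    """Breed allele frequencies under the Balding-Nichols model.

    Each breed frequency is an independent Beta draw with mean p and variance
    fst*p*(1-p); results are clipped to [0.001, 0.999]. fst = 0 returns the
    ancestral frequencies unchanged for both breeds.
    """
    p = np.asarray(p_ancestral, dtype=np.float64)
    if not np.isfinite(p).all() or np.any((p <= 0) | (p >= 1)):
        bad = int(np.flatnonzero(~np.isfinite(p) | (p <= 0) | (p >= 1))[0])
        raise ValueError(f"ancestral frequency at index {bad} outside (0,1)")
    if not np.isfinite(fst) or not 0.0 <= fst <= 0.5:
        raise ValueError(f"fst must be finite and in [0, 0.5], got {fst}")
    if fst == 0.0:
        return p.copy(), p.copy()
    rng = np.random.default_rng(seed)
    scale = (1.0 - fst) / fst
    out = []
    for _ in range(2):
        q = rng.beta(p * scale, (1.0 - p) * scale)
        out.append(np.clip(q, 0.001, 0.999))
    return out[0], out[1]


def _gamete(rng, p):
    """One haploid gamete sampled from population allele frequencies."""
    return (rng.random(len(p)) < p).astype(np.int8)


def _parent_gamete(rng, g1, g2):
    """Gamete from a simulated parent with haplotypes g1, g2 (independent loci)."""
    pick = rng.random(len(g1)) < 0.5
    return np.where(pick, g1, g2).astype(np.int8)


def simulate_genotypes(freqs_by_breed: dict, group_sizes: dict, seed: int) -> Population:
    """Simulate dosages for purebred and crossbred groups.

    Purebreds are Binomial(2, p_breed) per locus (Hardy-Weinberg). A 50:50
    animal receives one gamete from H frequencies and one from J; a 75:25
    animal one H gamete and one gamete from a simulated F1 parent (25:75 is
    symmetric). Group keys are ``{H,J}_bull``, ``{H,J}_cow`` and
    ``{75H25J,50H50J,25H75J}_cow``.
    """
    if not group_sizes:
        raise ValueError("empty group map")
    pH = np.asarray(freqs_by_breed["H"], dtype=np.float64)
    pJ = np.asarray(freqs_by_breed["J"], dtype=np.float64)
    m = len(pH)
    rng = np.random.default_rng(seed)

    rows, ids, sexes, groups, fracs = [], [], [], [], []

    def add(prefix, k, sex, group, maker):
        for i in range(k):
            rows.append(maker())
            ids.append(f"{prefix}{i:05d}")
            sexes.append(sex)
            groups.append(group)
            fracs.append(GROUP_FRACTIONS[group])

    order = ["H_bull", "J_bull", "H_cow", "J_cow",
             "75H25J_cow", "50H50J_cow", "25H75J_cow"]
    for key in order:
        k = int(group_sizes.get(key, 0))
        if k == 0:
            continue
        breed, sex = key.rsplit("_", 1)
        if breed in ("H", "J"):
            p = pH if breed == "H" else pJ
            add(key + "_", k, sex, breed,
                lambda p=p: rng.binomial(2, p).astype(np.int8))
        elif breed == "50H50J":
            add(key + "_", k, sex, breed,
                lambda: (_gamete(rng, pH) + _gamete(rng, pJ)).astype(np.int8))
        elif breed == "75H25J":
            def make_backcross_h():
                f1 = (_gamete(rng, pH), _gamete(rng, pJ))
                return (_gamete(rng, pH) + _parent_gamete(rng, *f1)).astype(np.int8)
            add(key + "_", k, sex, breed, make_backcross_h)
        elif breed == "25H75J":
            def make_backcross_j():
                f1 = (_gamete(rng, pH), _gamete(rng, pJ))
                return (_gamete(rng, pJ) + _parent_gamete(rng, *f1)).astype(np.int8)
            add(key + "_", k, sex, breed, make_backcross_j)
        else:
            raise ValueError(f"unknown group key {key!r}")

    if not rows:
        raise ValueError("all group sizes are zero")
    dosages = np.vstack(rows)
    gm = GenotypeMatrix(
        dosages,
        np.array(ids, dtype=object),
        np.array([f"snp{j:06d}" for j in range(m)], dtype=object),
        np.ones(m, dtype=np.int64),
        np.arange(1, m + 1, dtype=np.int64) * 1000,
    )
    return Population(
        genotypes=gm,
        tbv=np.zeros(len(ids)),
        qtl_effects=np.zeros(m),
        qtl_indices=np.array([], dtype=np.int64),
        breed_fractions_true=np.array(fracs, dtype=np.float64),
        sex=np.array(sexes, dtype=object),
        breed_group_true=np.array(groups, dtype=object),
    )


def assign_qtl_effects(
    n_snp: int,
    n_qtl: int,
    prior: MixturePrior,
    sigma2_g: float,
    seed: int,
    dosages_h: np.ndarray | None = None,
):
    """Draw sparse QTL effects from the non-null mixture components.

    ``n_qtl`` SNP indices are chosen uniformly without replacement; each QTL
    effect comes from the non-null components (proportions renormalized) with
    variance fraction_k * sigma2_g. If ``dosages_h`` (pure-H dosage block) is
    given, effects are rescaled so the empirical variance of the pure-H true
    breeding values equals ``sigma2_g`` exactly.

    Returns (effects, qtl_indices).
    """
    if sigma2_g <= 0:
        raise ValueError("sigma2_g must be positive")
    if n_qtl > n_snp:
        raise ValueError("n_qtl cannot exceed n_snp")
    rng = np.random.default_rng(seed)
    effects = np.zeros(n_snp)
    qtl = np.sort(rng.choice(n_snp, size=n_qtl, replace=False))
    if n_qtl == 0:
        return effects, qtl
    pi = np.asarray(prior.proportions, dtype=np.float64)
    fr = np.asarray(prior.variance_fractions, dtype=np.float64)
    nonnull = fr > 0
    pnz = pi[nonnull] / pi[nonnull].sum()
    comp = rng.choice(np.flatnonzero(nonnull), size=n_qtl, p=pnz)
    effects[qtl] = rng.normal(0.0, np.sqrt(fr[comp] * sigma2_g))
    if dosages_h is not None and len(dosages_h):
        tbv_h = dosages_h @ effects
        v = tbv_h.var()
        if v > 0:
            effects *= np.sqrt(sigma2_g / v)
    return effects, qtl


def simulate_population(config: SimConfig) -> Population:
    """Full population draw: frequencies, genotypes, QTL effects, TBV."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, config.n_snp)
    pH, pJ = draw_breed_allele_freqs(p_anc, config.fst, config.seed + 1)
    pop = simulate_genotypes({"H": pH, "J": pJ}, config.group_sizes,
                             config.seed + 2)
    h_rows = pop.genotypes.dosages[pop.breed_group_true == "H"]
    effects, qtl = assign_qtl_effects(
        config.n_snp, config.n_qtl, MixturePrior(), config.sigma2_g,
        config.seed + 3, dosages_h=h_rows,
    )
    pop.qtl_effects = effects
    pop.qtl_indices = qtl
    pop.tbv = pop.genotypes.dosages @ effects
    pop.config = config
    return pop


def simulate_drp(population: Population, config: SimConfig, seed: int,
                 trait: str = "milk") -> DRPTable:
    """DRP-like phenotypes: TBV + fixed effects + reliability-calibrated noise.

    Cows receive n records uniform in ``records_range``; bulls p daughters in
    ``daughters_range``. Reliability is n*h2/(1+(n-1)t) for cows and
    p/(p+(4-h2)/h2) for bulls; the DRP noise variance is
    sigma2_g*(1-r2)/r2, so the matching weight (Eqs. for cow/bull weights)
    calibrates the residual structure of the prediction models.
    """
    return simulate_drp_traits(population, config, seed, traits=(trait,))[0]


def simulate_drp_traits(population: Population, config: SimConfig, seed: int,
                        traits=("milk", "fat", "protein")) -> list:
    """One DRPTable per trait, sharing record counts (hence weights).

    A cow's record count and a bull's daughter count do not depend on the
    trait, so the per-animal reliability and weight are common to all traits;
    only the noise draw differs. Traits share the population's genetic
    architecture (the same TBV), emulating a set of highly genetically
    correlated yield traits.
    """
    rng = np.random.default_rng(seed)
    params = config.weight_params
    n_animals = len(population.animal_ids)
    is_bull = population.sex == "bull"

    n_eff = np.empty(n_animals, dtype=np.int64)
    n_eff[~is_bull] = rng.integers(config.records_range[0],
                                   config.records_range[1] + 1,
                                   size=int((~is_bull).sum()))
    n_eff[is_bull] = rng.integers(config.daughters_range[0],
                                  config.daughters_range[1] + 1,
                                  size=int(is_bull.sum()))
    r2 = np.where(is_bull, bull_reliability(params, n_eff),
                  cow_reliability(params, n_eff))
    if np.any(r2 <= 0):
        raise ValueError("zero DRP reliability: every animal needs information")
    noise_var = config.sigma2_g * (1.0 - r2) / r2
    weight = np.where(is_bull, bull_weight(params, n_eff),
                      cow_weight(params, n_eff))
    fJ = population.breed_fractions_true[:, 1]
    base = (population.tbv + config.j_mean_shift * fJ
            + config.sex_effect * is_bull.astype(float))
    tables = []
    for trait in traits:
        eps = rng.normal(0.0, np.sqrt(noise_var))
        tables.append(DRPTable(population.animal_ids.copy(), base + eps,
                               population.sex.copy(),
                               population.breed_group_true.copy(),
                               n_eff.copy(), weight.copy(), trait=trait))
    return tables


def _sample(rng, ids, k):
    ids = np.asarray(ids, dtype=object)
    if k > len(ids):
        raise ValueError(f"requested {k} animals but only {len(ids)} available")
    return ids[np.sort(rng.choice(len(ids), size=k, replace=False))]


def build_reference_designs(
    population: Population,
    seed: int = 0,
    validation_fraction: float = 0.1,
    scheme: str = "table1",
):
    """Scaled-down analogues of the eight reference designs plus validation.

    One shared validation set of cows spanning all five breed groups is carved
    out first (``validation_fraction`` of each cow group) and is disjoint from
    every reference. Designs follow the published composition logic:

    * Ref1 / Ref2: all pure H / pure J animals.
    * Ref3: union of Ref1 and Ref2.
    * Ref4 (and Ref4p): same animals as Ref3 but combined per validation
      animal as a breed-fraction-weighted average of the Ref1/Ref2 GEBV
      (fractions from PCA groups for Ref4, continuous admixture for Ref4p).
    * Ref5: Ref3 plus all crossbred cows.
    * Ref6: equal numbers of H and J bulls and of pure H and J cows.
    * Ref7: the same bulls plus only crossbred cows, matching Ref6's total.
    * Ref8: Ref6 cows + Ref7 cows + the shared bulls.

    Subsets for Refs 6-8 are sampled randomly (seeded).
    """
    if scheme != "table1":
        raise ValueError(f"unknown design scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    pop = population
    cow_groups = {g: pop.ids_of(g, "cow") for g in BREED_GROUPS}
    for g, ids in cow_groups.items():
        if len(ids) == 0:
            raise ValueError(f"validation set: no cows available in group {g}")
    validation = {}
    for g in BREED_GROUPS:
        k = max(2, int(round(validation_fraction * len(cow_groups[g]))))
        validation[g] = _sample(rng, cow_groups[g], k)
    val_ids = np.concatenate([validation[g] for g in BREED_GROUPS])
    val_set = set(val_ids)

    def ref_cows(g):
        return np.array([a for a in cow_groups[g] if a not in val_set], dtype=object)

    h_bulls = pop.ids_of("H", "bull")
    j_bulls = pop.ids_of("J", "bull")
    for name, ids in (("Ref1", h_bulls), ("Ref2", j_bulls)):
        if len(ids) == 0:
            raise ValueError(f"{name}: no bulls available in required group")

    ref1 = np.concatenate([h_bulls, ref_cows("H")])
    ref2 = np.concatenate([j_bulls, ref_cows("J")])
    ref3 = np.concatenate([ref1, ref2])
    cross = {g: ref_cows(g) for g in ("75H25J", "50H50J", "25H75J")}
    ref5 = np.concatenate([ref3] + [cross[g] for g in cross])

    nb = min(len(h_bulls), len(j_bulls))
    bulls6 = np.concatenate([_sample(rng, h_bulls, nb), _sample(rng, j_bulls, nb)])
    nc = min(len(ref_cows("H")), len(ref_cows("J")))
    cows6 = np.concatenate([_sample(rng, ref_cows("H"), nc),
                            _sample(rng, ref_cows("J"), nc)])
    ref6 = np.concatenate([bulls6, cows6])

    total_cows7 = 2 * nc
    n75, n50, n25 = (len(cross[g]) for g in ("75H25J", "50H50J", "25H75J"))
    if n75 + n50 + n25 < total_cows7:
        raise ValueError("Ref7: not enough crossbred cows for a size-matched design")
    # side groups capped by the smaller of the two backcross pools, remainder
    # from the 50:50 pool, spilling back to the sides if 50:50 runs short
    t_side = min(n75, n25, total_cows7 // 3)
    t50 = min(n50, total_cows7 - 2 * t_side)
    spill = total_cows7 - 2 * t_side - t50
    t75 = t_side + min(spill, n75 - t_side)
    t25 = t_side + (spill - (t75 - t_side))
    if t25 > n25:
        raise ValueError("Ref7: not enough crossbred cows for a size-matched design")
    cows7 = np.concatenate([
        _sample(rng, cross["75H25J"], t75),
        _sample(rng, cross["50H50J"], t50),
        _sample(rng, cross["25H75J"], t25),
    ])
    ref7 = np.concatenate([bulls6, cows7])
    ref8 = np.concatenate([bulls6, cows6, cows7])

    designs = [
        ReferenceDesign("Ref1", ref1, val_ids),
        ReferenceDesign("Ref2", ref2, val_ids),
        ReferenceDesign("Ref3", ref3, val_ids),
        ReferenceDesign("Ref4", ref3, val_ids, combine_rule="weighted_average",
                        component_designs=("Ref1", "Ref2"),
                        breed_fraction_source="pca"),
        ReferenceDesign("Ref4p", ref3, val_ids, combine_rule="weighted_average",
                        component_designs=("Ref1", "Ref2"),
                        breed_fraction_source="admixture"),
        ReferenceDesign("Ref5", ref5, val_ids),
        ReferenceDesign("Ref6", ref6, val_ids),
        ReferenceDesign("Ref7", ref7, val_ids),
        ReferenceDesign("Ref8", ref8, val_ids),
    ]
    return designs, validation
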