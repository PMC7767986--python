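"""Validation scoring and the reference-design experiment grid.

Accuracy is the Pearson correlation between GEBV and DRP in the validation
set; bias is the regression coefficient of DRP on GEBV (unbiased = 1). The
grid runner refits each (design, method, panel, trait) cell from scratch --
rebuilding the panel genotypes and the GRM with allele frequencies from that
design's reference + validation animals -- and scores every validation breed
group separately, plus across-trait averages.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .bayesr import BayesRConfig, predict_gebv, run_embayesr
from .breeds import BreedComposition, allocate_groups, estimate_admixture, pca_of_grm
from .gblup import DRPTable, WeightParams, fit_wgblup_traits
from .markers import build_grm, filter_maf, ld_prune, standardize
from .population import BREED_GROUPS, Population, ReferenceDesign

log = logging.getLogger(__name__)

__all__ = [
    "accuracy",
    "bias",
    "wa_gebv",
    "build_panels",
    "run_experiment",
]

EVAL_COLUMNS = ["design", "method", "panel", "trait", "validation_group",
                "accuracy", "bias", "n_validation", "status"]


def accuracy(gebv, drp) -> float:
    """Pearson correlation between GEBV and DRP (NaN if either is constant)."""
    gebv = np.asarray(gebv, dtype=np.float64)
    drp = np.asarray(drp, dtype=np.float64)
    if len(gebv) < 2 or len(gebv) != len(drp):
        raise ValueError("need two aligned vectors with >= 2 animals")
    if not (np.isfinite(gebv).all() and np.isfinite(drp).all()):
        raise ValueError("non-finite values in GEBV or DRP")
    if gebv.std() == 0.0 or drp.std() == 0.0:
        warnings.warn("zero variance: accuracy undefined, returning NaN")
        return float("nan")
    return float(np.corrcoef(gebv, drp)[0, 1])


def bias(gebv, drp) -> float:
    """Slope of DRP regressed on GEBV: cov(drp, gebv) / var(gebv)."""
    gebv = np.asarray(gebv, dtype=np.float64)
    drp = np.asarray(drp, dtype=np.float64)
    v = gebv.var()
    if v == 0.0:
        warnings.warn("zero GEBV variance: bias undefined, returning NaN")
        return float("nan")
    return float(np.cov(drp, gebv)[0, 1] / gebv.var(ddof=1))


def wa_gebv(gebv_H: pd.Series, gebv_J: pd.Series,
            fractions: BreedComposition, target_ids=None) -> pd.Series:
    """Breed-proportion-weighted average of per-breed GEBV.

    GEBV_i = fH_i * gebv_H_i + fJ_i * gebv_J_i with fractions on the simplex.
    """
    if target_ids is None:
        target_ids = list(gebv_H.index)
    frac = {a: f for a, f in zip(fractions.animal_ids, fractions.fractions)}
    out = np.empty(len(target_ids))
    for i, a in enumerate(target_ids):
        if a not in gebv_H.index or a not in gebv_J.index:
            raise KeyError(f"missing component GEBV for animal {a!r}")
        if a not in frac:
            raise KeyError(f"missing breed fractions for animal {a!r}")
        fH, fJ = frac[a]
        out[i] = fH * gebv_H[a] + fJ * gebv_J[a]
    return pd.Series(out, index=list(target_ids))


def build_panels(population: Population, seed: int = 0,
                 panel_size: int | None = None,
                 qtl_share_enriched: float = 0.9) -> dict:
    """SNP masks for the three marker-panel analogues.

    * ``tag``: markers only (no QTL) -- the conventional-chip analogue; with
      independent loci this panel carries no causal signal by construction.
    * ``causal_enriched``: most QTL plus markers to the same total size -- the
      causal-variant-enriched custom panel analogue.
    * ``pruned_dense``: all SNPs, LD-pruned at r2 > 0.95 -- the pruned
      high-density analogue.
    """
    rng = np.random.default_rng(seed)
    m = population.genotypes.n_snps
    qtl = population.qtl_indices
    non_qtl = np.setdiff1d(np.arange(m), qtl)
    if panel_size is None:
        panel_size = min(len(non_qtl), max(1, int(0.4 * m)))
    panel_size = min(panel_size, len(non_qtl))

    tag_idx = np.sort(rng.choice(non_qtl, size=panel_size, replace=False))
    n_qtl_in = int(round(qtl_share_enriched * len(qtl)))
    qtl_in = np.sort(rng.choice(qtl, size=n_qtl_in, replace=False)) if n_qtl_in else qtl[:0]
    n_fill = max(panel_size - len(qtl_in), 0)
    fill = np.sort(rng.choice(non_qtl, size=min(n_fill, len(non_qtl)), replace=False))
    enr_idx = np.sort(np.concatenate([qtl_in, fill]))

    pruned = ld_prune(population.genotypes, r2_threshold=0.95)
    pruned_ids = set(pruned.snp_ids)
    dense_mask = np.array([s in pruned_ids for s in population.genotypes.snp_ids])

    def mask_of(idx):
        z = np.zeros(m, dtype=bool)
        z[idx] = True
        return z

    return {"tag": mask_of(tag_idx), "causal_enriched": mask_of(enr_idx),
            "pruned_dense": dense_mask}


def _pca_breed_fractions(population: Population, seed: int,
                         n_core_snps: int = 1500) -> BreedComposition:
    """PCA group allocation on a low-density core SNP subset.

    Emulates calling breed groups from PC1 of a GRM built on the core chip
    shared by all animals, anchored by (true, here) pedigree codes.
    """
    rng = np.random.default_rng(seed)
    m = population.genotypes.n_snps
    core = np.sort(rng.choice(m, size=min(n_core_snps, m), replace=False))
    gm = filter_maf(population.genotypes.subset_snps(core), 0.002)
    grm = build_grm(gm)
    pc1 = pca_of_grm(grm, 1)[:, 0]
    pedigree = dict(zip(population.animal_ids, population.breed_group_true))
    return allocate_groups(pc1, population.animal_ids, pedigree)


def _admixture_breed_fractions(population: Population, seed: int,
                               n_core_snps: int = 1500) -> BreedComposition:
    rng = np.random.default_rng(seed)
    m = population.genotypes.n_snps
    core = np.sort(rng.choice(m, size=min(n_core_snps, m), replace=False))
    gm = filter_maf(population.genotypes.subset_snps(core), 0.002)
    pedigree = dict(zip(population.animal_ids, population.breed_group_true))
    return estimate_admixture(gm, k=2, seed=seed, pedigree_groups=pedigree)


def _truth_fractions(population: Population) -> BreedComposition:
    return BreedComposition(
        population.animal_ids.copy(), population.breed_fractions_true.copy(),
        population.breed_group_true.copy(), source="truth",
    )


def _fit_cells(method, gm_panel, design, drp_tables, params, sigma2_g,
               bayes_cfg, maf_threshold=0.002):
    """Fit one (design, method) for every trait; returns {trait: GEBV Series}.

    Genotypes are restricted to the design's reference + validation animals,
    MAF-filtered over that set, and that same set supplies the centering /
    standardization frequencies. Traits share the one expensive
    factorization (GBLUP) or standardized matrix (mixture model).
    """
    ids = np.concatenate([design.reference_ids, design.validation_ids])
    gm = filter_maf(gm_panel.subset_animals(ids), maf_threshold)
    refs = [drp.subset(design.reference_ids) for drp in drp_tables]
    val = list(design.validation_ids)
    out = {}
    if method == "gblup":
        grm = build_grm(gm, freq_source_label=f"{design.name}_ref_val")
        fits = fit_wgblup_traits(refs, grm, params=params, sigma2_g=sigma2_g)
        for drp, fit in zip(drp_tables, fits):
            out[drp.trait] = fit.gebv.loc[val]
    elif method == "embayesr":
        W = standardize(gm)
        row = gm.animal_index(design.reference_ids)
        vrow = gm.animal_index(design.validation_ids)
        for drp, ref in zip(drp_tables, refs):
            fit = run_embayesr(ref, W[row], config=bayes_cfg,
                               sigma2_g=sigma2_g, h2=params.h2)
            out[drp.trait] = pd.Series(predict_gebv(fit, W[vrow]), index=val)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def run_experiment(
    population: Population,
    drp_tables: list[DRPTable] | DRPTable,
    designs: list[ReferenceDesign],
    validation_groups: dict,
    methods=("gblup",),
    panels: dict | None = None,
    params: WeightParams | None = None,
    sigma2_g: float = 1.0,
    base_seed: int = 0,
    bayes_config: BayesRConfig | None = None,
    breed_fractions: dict | None = None,
) -> pd.DataFrame:
    """Run the full (design x method x panel x trait) grid and score it.

    ``validation_groups`` maps breed group -> validation animal ids (shared
    across designs). Weighted-average designs pull their component fits from
    the direct designs named in ``component_designs``, which must also be in
    ``designs``. Failed cells are recorded with a status message and NaN
    metrics rather than aborting the grid.
    """
    if isinstance(drp_tables, DRPTable):
        drp_tables = [drp_tables]
    params = params or WeightParams()
    panels = panels or {"all": np.ones(population.genotypes.n_snps, dtype=bool)}
    breed_fractions = dict(breed_fractions or {})
    breed_fractions.setdefault("truth", _truth_fractions(population))

    needed_sources = {d.breed_fraction_source for d in designs
                      if d.combine_rule == "weighted_average"}
    if "pca" in needed_sources and "pca" not in breed_fractions:
        breed_fractions["pca"] = _pca_breed_fractions(population, base_seed + 101)
    if "admixture" in needed_sources and "admixture" not in breed_fractions:
        breed_fractions["admixture"] = _admixture_breed_fractions(
            population, base_seed + 102)

    rows = []
    direct = [d for d in designs if d.combine_rule == "direct"]
    weighted = [d for d in designs if d.combine_rule == "weighted_average"]
    for panel_name, mask in panels.items():
        gm_panel = population.genotypes.subset_snps(np.asarray(mask))
        cache = {}  # (design, method) -> {trait: GEBV Series}
        for design in direct:
            for method in methods:
                try:
                    by_trait = _fit_cells(method, gm_panel, design, drp_tables,
                                          params, sigma2_g, bayes_config)
                    cache[(design.name, method)] = by_trait
                    for drp in drp_tables:
                        rows += _score(design, method, panel_name, drp,
                                       by_trait[drp.trait], validation_groups)
                except Exception as e:  # fail-soft
                    log.warning("cell failed: %s/%s/%s: %s", design.name,
                                method, panel_name, e)
                    for drp in drp_tables:
                        rows += _failed_rows(design, method, panel_name, drp,
                                             validation_groups, str(e))
        for design in weighted:
            comp_h, comp_j = design.component_designs
            frac = breed_fractions[design.breed_fraction_source]
            for method in methods:
                key_h, key_j = (comp_h, method), (comp_j, method)
                for drp in drp_tables:
                    if key_h not in cache or key_j not in cache:
                        rows += _failed_rows(design, method, panel_name, drp,
                                             validation_groups,
                                             "missing component fits")
                        continue
                    try:
                        combined = wa_gebv(cache[key_h][drp.trait],
                                           cache[key_j][drp.trait], frac,
                                           target_ids=list(design.validation_ids))
                        rows += _score(design, method, panel_name, drp,
                                       combined, validation_groups)
                    except Exception as e:
                        log.warning("cell failed: %s/%s/%s/%s: %s", design.name,
                                    method, panel_name, drp.trait, e)
                        rows += _failed_rows(design, method, panel_name, drp,
                                             validation_groups, str(e))
    table = pd.DataFrame(rows, columns=EVAL_COLUMNS)
    if len(drp_tables) > 1:
        mean = (table[table.status == "ok"]
                .groupby(["design", "method", "panel", "validation_group"],
                         as_index=False)
                .agg(accuracy=("accuracy", "mean"), bias=("bias", "mean"),
                     n_validation=("n_validation", "first")))
        mean["trait"] = "(mean)"
        mean["status"] = "ok"
        table = pd.concat([table, mean[EVAL_COLUMNS]], ignore_index=True)
    return table


def _score(design, method, panel_name, drp, gebv_val, validation_groups):
    drp_map = dict(zip(drp.animal_ids, drp.y))
    rows = []
    for group in BREED_GROUPS:
        ids = [a for a in validation_groups.get(group, []) if a in gebv_val.index]
        if len(ids) < 2:
            continue
        g = gebv_val.loc[ids].to_numpy()
        y = np.array([drp_map[a] for a in ids])
        rows.append({
            "design": design.name, "method": method, "panel": panel_name,
            "trait": drp.trait, "validation_group": group,
            "accuracy": accuracy(g, y), "bias": bias(g, y),
            "n_validation": len(ids), "status": "ok",
        })
    return rows


def _failed_rows(design, method, panel_name, drp, validation_groups, msg):
    return [{
        "design": design.name, "method": method, "panel": panel_name,
        "trait": drp.trait, "validation_group": group,
        "accuracy": float("nan"), "bias": float("nan"),
        "n_validation": len(validation_groups.get(group, [])),
        "status": f"failed: {msg}",
    } for group in BREED_GROUPS]
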