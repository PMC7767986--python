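"""Breed-group allocation and two-breed admixture estimation.

Animals are allocated to the five H:J breed groups from the first principal
component of the GRM, with pedigree breed codes anchoring the group
boundaries; continuous breed fractions come from a k = 2 admixture model
(binomial likelihood in per-animal ancestry fractions Q and per-population
allele frequencies F, maximized by EM block updates, which makes the
log-likelihood non-decreasing by construction).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .markers import GRM, GenotypeMatrix, build_grm
from .population import BREED_GROUPS, GROUP_FRACTIONS

log = logging.getLogger(__name__)

__all__ = ["BreedComposition", "pca_of_grm", "allocate_groups", "estimate_admixture"]


@dataclass
class BreedComposition:
    """Per-animal (fH, fJ) fractions with a discrete group call."""

    animal_ids: np.ndarray
    fractions: np.ndarray   # (n, 2): columns fH, fJ, rows on the 2-simplex
    group: np.ndarray
    source: str             # pedigree | pca | admixture | truth
    converged: bool = True
    flat_likelihood: bool = False
    loglik_history: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        self.group = np.asarray(self.group, dtype=object)
        if np.max(np.abs(self.fractions.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("breed fractions must sum to 1 per animal")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("breed fractions must lie in [0, 1]")

    def fH(self) -> np.ndarray:
        return self.fractions[:, 0]

    def as_dict(self) -> dict:
        return dict(zip(self.animal_ids, self.fractions))


def _nearest_group(fH: np.ndarray) -> np.ndarray:
    nominal = np.array([GROUP_FRACTIONS[g][0] for g in BREED_GROUPS])
    idx = np.argmin(np.abs(fH[:, None] - nominal[None, :]), axis=1)
    return np.array([BREED_GROUPS[i] for i in idx], dtype=object)


def pca_of_grm(grm: GRM, n_components: int = 2) -> np.ndarray:
    """Principal-component scores of the GRM (eigvec * sqrt(eigval)).

    Components are ordered by decreasing eigenvalue; each column's sign is
    fixed by making its largest-magnitude loading positive (breed orientation
    is handled downstream where labels are available).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    G = grm.matrix
    if not np.isfinite(G).all():
        raise ValueError("GRM contains non-finite entries")
    n = G.shape[0]
    k = min(n_components, n)
    vals, vecs = linalg.eigh(G, subset_by_index=[n - k, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scores = vecs * np.sqrt(np.maximum(vals, 0.0))
    for j in range(scores.shape[1]):
        lead = np.argmax(np.abs(scores[:, j]))
        if scores[lead, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def allocate_groups(pc1_scores, animal_ids, pedigree_groups: dict) -> BreedComposition:
    """Assign every animal to a breed group by its PC1 score.

    Pedigree-labeled animals anchor per-group PC1 means; boundaries sit at
    midpoints of adjacent group means (groups ordered by Holstein fraction).
    The axis is flipped if needed so pure H has the largest mean; group means
    that are not monotone along PC1 raise an error. All animals -- including
    unlabeled or mislabeled ones -- are then assigned by score, and receive
    the nominal fractions of their assigned group.
    """
    pc1 = np.asarray(pc1_scores, dtype=np.float64)
    animal_ids = np.asarray(animal_ids, dtype=object)
    groups_present = [g for g in BREED_GROUPS
                      if any(pedigree_groups.get(a) == g for a in animal_ids)]
    if not groups_present:
        raise ValueError("no pedigree-labeled animals among the scores")
    means = []
    for g in groups_present:
        sel = np.array([pedigree_groups.get(a) == g for a in animal_ids])
        means.append(pc1[sel].mean())
    means = np.array(means)
    if len(means) > 1:
        diffs = np.diff(means)
        if np.all(diffs < 0):
            pc1 = -pc1
            means = -means
        elif not np.all(diffs > 0):
            raise ValueError(
                "pedigree-anchored group means are not monotone along PC1; "
                "inconsistent anchoring"
            )
    boundaries = (means[:-1] + means[1:]) / 2.0
    idx = np.searchsorted(boundaries, pc1)
    group = np.array([groups_present[i] for i in idx], dtype=object)
    fractions = np.array([GROUP_FRACTIONS[g] for g in group], dtype=np.float64)
    return BreedComposition(animal_ids, fractions, group, source="pca")


def estimate_admixture(
    genotypes: GenotypeMatrix,
    k: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    pedigree_groups: dict | None = None,
) -> BreedComposition:
    """Two-population admixture fractions by EM on the binomial likelihood.

    Maximizes sum_ij [ x_ij log g_ij + (2 - x_ij) log(1 - g_ij) ] with
    g_ij = sum_k q_ik f_kj over per-animal ancestry rows Q (on the simplex)
    and per-population frequencies F (clipped to [0.001, 0.999]). Q is
    initialized from PC1 of the GRM rescaled to [0, 1]; F from overall sample
    frequencies with seeded +-0.05 noise. Population labels are mapped to
    H/J by correlating F with pedigree-purebred sample frequencies when
    ``pedigree_groups`` is provided.

    Non-convergence sets a warning flag rather than raising; a flat
    likelihood (indistinguishable populations) also sets a flag.
    """
    if k != 2:
        raise ValueError("only k = 2 (two ancestral breeds) is supported")
    # SNPs monomorphic in this sample carry no ancestry information and are
    # dropped up front (the MAF-filter precondition covers the usual case)
    p_obs = genotypes.allele_freq()
    poly = (p_obs > 0.0) & (p_obs < 1.0)
    if not poly.any():
        raise ValueError("all SNPs monomorphic: cannot estimate admixture")
    if not poly.all():
        genotypes = genotypes.subset_snps(poly)
    X = genotypes.dosages.astype(np.float64)
    n, m = X.shape
    rng = np.random.default_rng(seed)

    grm = build_grm(genotypes)
    pc1 = pca_of_grm(grm, 1)[:, 0]
    span = np.ptp(pc1)
    q1 = np.full(n, 0.5) if span == 0 else (pc1 - pc1.min()) / span
    q1 = np.clip(q1, 0.05, 0.95)
    Q = np.column_stack([q1, 1.0 - q1])
    p_all = X.mean(axis=0) / 2.0
    F = np.clip(p_all[None, :] + rng.uniform(-0.05, 0.05, size=(2, m)),
                0.001, 0.999)

    def loglik(Q_, F_):
        Gm = np.clip(Q_ @ F_, 1e-9, 1.0 - 1e-9)
        return float(np.sum(X * np.log(Gm) + (2.0 - X) * np.log1p(-Gm)))

    def em_step(Q_, F_):
        # E-step: expected allele counts per ancestry; M-step: block updates
        Gm = np.clip(Q_ @ F_, 1e-9, 1.0 - 1e-9)
        a = Q_[:, :, None] * F_[None, :, :] / Gm[:, None, :]          # alt
        b = Q_[:, :, None] * (1.0 - F_)[None, :, :] / (1.0 - Gm)[:, None, :]
        alt = X[:, None, :] * a
        ref = (2.0 - X)[:, None, :] * b
        Qn = (alt + ref).sum(axis=2) / (2.0 * m)
        Qn = np.clip(Qn, 1e-12, 1.0)
        Qn /= Qn.sum(axis=1, keepdims=True)
        denom = (alt + ref).sum(axis=0)
        Fn = np.where(denom > 0, alt.sum(axis=0) / np.maximum(denom, 1e-300), F_)
        Fn = np.clip(Fn, 0.001, 0.999)
        return Qn, Fn

    def project(Q_, F_):
        Q_ = np.clip(Q_, 1e-12, 1.0)
        Q_ = Q_ / Q_.sum(axis=1, keepdims=True)
        return Q_, np.clip(F_, 0.001, 0.999)

    # SQUAREM-accelerated EM: two plain EM steps define an extrapolated
    # proposal that is only accepted when it does not decrease the
    # log-likelihood, so the recorded trajectory stays monotone.
    ll_hist = [loglik(Q, F)]
    converged = False
    for _ in range(max_iter):
        Q1, F1 = em_step(Q, F)
        Q2, F2 = em_step(Q1, F1)
        rQ, rF = Q1 - Q, F1 - F
        vQ, vF = (Q2 - Q1) - rQ, (F2 - F1) - rF
        vnorm = np.sqrt(np.sum(vQ ** 2) + np.sum(vF ** 2))
        ll2 = loglik(Q2, F2)
        if vnorm > 0:
            alpha = -np.sqrt(np.sum(rQ ** 2) + np.sum(rF ** 2)) / vnorm
            alpha = min(alpha, -1.0)
            Qp, Fp = project(Q - 2 * alpha * rQ + alpha ** 2 * vQ,
                             F - 2 * alpha * rF + alpha ** 2 * vF)
            llp = loglik(Qp, Fp)
        else:
            llp = -np.inf
        if llp >= ll2:
            Q, F, ll = Qp, Fp, llp
        else:
            Q, F, ll = Q2, F2, ll2
        gain = ll - ll_hist[-1]
        ll_hist.append(ll)
        if gain < tol:
            converged = True
            break
    if not converged:
        log.warning("admixture EM hit max_iter=%d without converging", max_iter)

    # flat-likelihood check: a two-population model should beat the single-
    # population fit by far more than its extra parameter count; if it does
    # not, the populations are statistically indistinguishable (e.g. fst = 0)
    p_bar = np.clip(X.mean(axis=0) / 2.0, 1e-9, 1.0 - 1e-9)
    ll_one = float(np.sum(X * np.log(p_bar) + (2.0 - X) * np.log1p(-p_bar)))
    flat = bool((ll_hist[-1] - ll_one) < (n + m))
    if flat:
        log.warning("admixture likelihood is flat: populations indistinguishable")

    # map population labels to H/J
    if pedigree_groups:
        h_ids = [a for a in genotypes.animal_ids if pedigree_groups.get(a) == "H"]
        if h_ids:
            pH_obs = genotypes.allele_freq(h_ids)
            c0 = np.corrcoef(F[0], pH_obs)[0, 1]
            c1 = np.corrcoef(F[1], pH_obs)[0, 1]
            if c1 > c0:
                Q = Q[:, ::-1]
                F = F[::-1]

    fractions = np.clip(Q, 0.0, 1.0)
    fractions /= fractions.sum(axis=1, keepdims=True)
    group = _nearest_group(fractions[:, 0])
    return BreedComposition(
        genotypes.animal_ids.copy(), fractions, group, source="admixture",
        converged=converged, flat_likelihood=flat,
        loglik_history=np.asarray(ll_hist),
    )
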