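"""Marker quality control and genomic relationship matrices.

Holds the genotype container used throughout the package, the MAF filter and
LD-pruning steps applied before genomic prediction, column standardization of
dosages, and VanRaden (method 1) GRM construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "filter_maf",
    "ld_prune",
    "standardize",
    "build_grm",
]


@dataclass
class GenotypeMatrix:
    """Animal x SNP alternate-allele dosage matrix with marker metadata.

    dosages are integers in {0, 1, 2} (count of the alternate / "B" allele);
    loaders impute missing calls to the rounded mean before construction, so a
    valid instance never contains missing values.

    ``panels`` maps a panel label (e.g. ``tag``, ``custom``,
    ``causal_enriched``) to a boolean mask over SNPs.
    """

    dosages: np.ndarray
    animal_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray  # 1-based physical positions
    panels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        n, m = self.dosages.shape
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match dosage rows")
        if not (len(self.snp_ids) == len(self.chrom) == len(self.bp) == m):
            raise ValueError("SNP metadata length does not match dosage columns")
        if len(set(self.animal_ids)) != n:
            raise ValueError("animal ids must be unique")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp ids must be unique")
        d = self.dosages
        if not np.isin(np.unique(d), [0, 1, 2]).all():
            raise ValueError("dosages must be 0, 1 or 2 (impute missing at load)")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def animal_index(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"animal id {e.args[0]!r} not in genotype matrix") from e

    def allele_freq(self, animal_ids=None) -> np.ndarray:
        """Alternate-allele frequency per SNP over the given animal set."""
        if animal_ids is None:
            rows = self.dosages
        else:
            rows = self.dosages[self.animal_index(animal_ids)]
        if rows.shape[0] == 0:
            raise ValueError("cannot compute allele frequencies over zero animals")
        return rows.mean(axis=0) / 2.0

    def subset_snps(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        panels = {k: v[idx] for k, v in self.panels.items()}
        return GenotypeMatrix(
            self.dosages[:, idx], self.animal_ids, self.snp_ids[idx],
            self.chrom[idx], self.bp[idx], panels,
        )

    def subset_animals(self, ids) -> "GenotypeMatrix":
        idx = self.animal_index(ids)
        return GenotypeMatrix(
            self.dosages[idx], self.animal_ids[idx], self.snp_ids,
            self.chrom, self.bp, dict(self.panels),
        )


@dataclass
class GRM:
    """Genomic relationship matrix with the animal ids it indexes.

    ``freq_source`` records which animal set supplied the centering allele
    frequencies; relationships shift when that set changes, which is why it is
    carried as part of the object.
    """

    matrix: np.ndarray
    animal_ids: np.ndarray
    freq_source: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if len(self.animal_ids) != self.matrix.shape[0]:
            raise ValueError("animal_ids length does not match GRM size")
        if not np.isfinite(self.matrix).all():
            raise ValueError("GRM contains non-finite entries")

    def animal_index(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        return np.array([lookup[a] for a in ids], dtype=np.int64)

    def subset(self, ids) -> "GRM":
        idx = self.animal_index(ids)
        return GRM(self.matrix[np.ix_(idx, idx)], self.animal_ids[idx], self.freq_source)


def filter_maf(genotypes: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop SNPs with minor allele frequency strictly below ``threshold``.

    Frequencies are computed over all animals in the matrix. A SNP at exactly
    the threshold is retained (removal uses a strict inequality).
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    p = genotypes.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= threshold
    if not keep.any():
        raise ValueError("MAF filter removed every SNP")
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("filter_maf: removed %d of %d SNPs below MAF %g",
                 n_removed, genotypes.n_snps, threshold)
    return genotypes.subset_snps(keep)


def _window_r2(block):
    """Pairwise squared correlations of the columns of ``block``.

    Monomorphic columns get r2 = 0 against everything (undefined correlation,
    treated as no LD so they are never pruned).
    """
    x = block - block.mean(axis=0)
    sd = x.std(axis=0)
    safe = np.where(sd == 0.0, 1.0, sd)
    xn = x / safe
    r = (xn.T @ xn) / block.shape[0]
    r[sd == 0.0, :] = 0.0
    r[:, sd == 0.0] = 0.0
    return r * r


def _prune_pass(dos, keep, order, r2_threshold, priority, window, step):
    """One greedy sliding-window pass; returns True if anything was dropped."""
    m = len(order)
    dropped = False
    for start in range(0, max(m - 1, 1), step):
        win = order[start:start + window]
        r2 = _window_r2(dos[:, win])
        hot = np.argwhere(np.triu(r2 > r2_threshold, k=1))
        for a, b in hot:
            i, j = win[a], win[b]
            if not (keep[i] and keep[j]):
                continue
            # drop the lower-priority SNP; tie -> the later in order
            if priority[i] < priority[j]:
                keep[i] = False
            else:
                keep[j] = False
            dropped = True
        if start + window >= m:
            break
    return dropped


def ld_prune(
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.95,
    priority: np.ndarray | None = None,
    window: int = 100,
    step: int = 50,
) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on dosage correlations.

    For every pair of SNPs within a ``window``-SNP sliding window (advanced by
    ``step``) whose squared Pearson correlation exceeds ``r2_threshold``, the
    lower-priority SNP is dropped (tie: the later one in position order).
    Passes repeat over the survivors until a fixed point, so the operation is
    idempotent and no surviving within-window pair exceeds the threshold.
    Monomorphic SNPs have undefined correlation; they are skipped and always
    retained.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError(f"r2 threshold must be in (0, 1], got {r2_threshold}")
    m = genotypes.n_snps
    if priority is None:
        priority = np.zeros(m)
    priority = np.asarray(priority, dtype=np.float64)
    if len(priority) != m:
        raise ValueError("priority must be defined for every SNP")
    dos = genotypes.dosages.astype(np.float64)
    keep = np.ones(m, dtype=bool)
    # position order within chromosome blocks (input is kept in stored order,
    # which loaders guarantee to be position-sorted)
    while True:
        order = np.flatnonzero(keep)
        if not _prune_pass(dos, keep, order, r2_threshold, priority, window, step):
            break
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("ld_prune: removed %d of %d SNPs at r2 > %g", n_removed, m, r2_threshold)
    return genotypes.subset_snps(keep)


def standardize(genotypes: GenotypeMatrix, freq_source_ids=None) -> np.ndarray:
    """Center and scale dosages to unit variance: (x - 2p) / sqrt(2p(1-p)).

    ``p`` is the alternate-allele frequency computed over ``freq_source_ids``
    (default: all animals in the matrix).
    """
    p = genotypes.allele_freq(freq_source_ids)
    bad = (p <= 0.0) | (p >= 1.0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} SNP(s) monomorphic in the frequency source "
            "(first index {}): apply a MAF filter first".format(int(np.flatnonzero(bad)[0]))
        )
    denom = np.sqrt(2.0 * p * (1.0 - p))
    return (genotypes.dosages - 2.0 * p) / denom


def build_grm(genotypes: GenotypeMatrix, freq_source_ids=None,
              freq_source_label: str = "") -> GRM:
    """VanRaden method-1 GRM: G = M Mt / (2 * sum p(1-p)).

    M is the dosage matrix centered by twice the allele frequency of each SNP,
    with frequencies computed over ``freq_source_ids`` (default all animals).
    The matrix spans every animal in ``genotypes``.
    """
    if genotypes.n_animals < 2 or genotypes.n_snps < 2:
        raise ValueError("GRM needs at least 2 animals and 2 SNPs")
    p = genotypes.allele_freq(freq_source_ids)
    bad = (p <= 0.0) | (p >= 1.0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} SNP(s) monomorphic in the frequency source: "
            "apply a MAF filter first"
        )
    M = genotypes.dosages - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (M @ M.T) / denom
    G = 0.5 * (G + G.T)
    label = freq_source_label or (
        "all_animals" if freq_source_ids is None else f"{len(freq_source_ids)}_animals"
    )
    return GRM(G, genotypes.animal_ids, freq_source=label)
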