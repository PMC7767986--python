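"""File formats: PLINK text and VCF genotypes, TSV tables, GRM files, config.

Dosages are alternate-allele counts everywhere; in PLINK text the "B" allele
maps to the alternate allele. Positions are 1-based in both .map and VCF.
Missing calls are imputed to the rounded per-SNP mean at load, with the count
logged. Floats are serialized with 12 significant digits so round-trips are
loss-free at working precision.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayesr import BayesRConfig, MixturePrior
from .gblup import DRPTable, WeightParams
from .markers import GRM, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_plink_text",
    "write_vcf",
    "read_drp_table",
    "write_drp_table",
    "read_grm",
    "write_grm",
    "write_outputs",
    "load_config",
    "config_hash",
    "make_fixture",
    "FIXTURES",
]

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------- genotypes

def _impute_missing(dos: np.ndarray) -> tuple[np.ndarray, int]:
    """Mean-impute missing dosages (coded -1) to the rounded column mean."""
    missing = dos < 0
    n_missing = int(missing.sum())
    if n_missing:
        out = dos.astype(np.float64)
        out[missing] = np.nan
        col_mean = np.nanmean(out, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        fill = np.clip(np.rint(col_mean), 0, 2)
        idx = np.where(missing)
        out[idx] = fill[idx[1]]
        log.info("imputed %d missing genotype calls to rounded column means",
                 n_missing)
        return out.astype(np.int8), n_missing
    return dos.astype(np.int8), 0


def _read_plink_text(ped_path: Path, map_path: Path) -> GenotypeMatrix:
    snp_ids, chrom, bp = [], [], []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom.append(parts[0])
            snp_ids.append(parts[1])
            bp.append(int(parts[3]))
    m = len(snp_ids)
    ids, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f".ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m} (.map mismatch)"
                )
            ids.append(parts[1])
            alleles = parts[6:]
            row = np.empty(m, dtype=np.int8)
            for j in range(m):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    row[j] = -1
                else:
                    row[j] = (a1 == "B") + (a2 == "B")
            rows.append(row)
    dos, _ = _impute_missing(np.vstack(rows))
    gm = GenotypeMatrix(dos, np.array(ids, dtype=object),
                        np.array(snp_ids, dtype=object),
                        np.array(chrom, dtype=object),
                        np.array(bp, dtype=np.int64))
    return _ensure_sorted(gm)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    snp_ids, chrom, bp, rows = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        bp.append(var.POS)
        col = np.empty(len(ids), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a = [x for x in g[:2] if x >= 0]
            col[i] = sum(a) if len(a) == 2 else -1
        rows.append(col)
    if n_multi:
        log.info("skipped %d multi-allelic VCF records", n_multi)
    dos, _ = _impute_missing(np.vstack(rows).T)
    gm = GenotypeMatrix(dos, ids, np.array(snp_ids, dtype=object),
                        np.array(chrom, dtype=object),
                        np.array(bp, dtype=np.int64))
    return _ensure_sorted(gm)


def _ensure_sorted(gm: GenotypeMatrix) -> GenotypeMatrix:
    order = np.lexsort((gm.bp, gm.chrom.astype(str)))
    if not np.array_equal(order, np.arange(gm.n_snps)):
        log.warning("genotype positions were unsorted; applying a stable sort")
        return gm.subset_snps(order)
    return gm


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read PLINK text (.ped/.map prefix or .ped path) or VCF genotypes."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf",) else "plink_text"
    if fmt == "plink_text":
        prefix = path.with_suffix("") if path.suffix in (".ped", ".map") else path
        return _read_plink_text(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_plink_text(gm: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write .ped/.map with A = reference, B = alternate allele coding."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ped, mp = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    code = {0: "A A", 1: "A B", 2: "B B"}
    with open(mp, "w") as fh:
        for j in range(gm.n_snps):
            fh.write(f"{gm.chrom[j]}\t{gm.snp_ids[j]}\t0\t{gm.bp[j]}\n")
    with open(ped, "w") as fh:
        for i, aid in enumerate(gm.animal_ids):
            geno = "\t".join(code[int(d)] for d in gm.dosages[i])
            fh.write(f"{aid}\t{aid}\t0\t0\t0\t-9\t{geno}\n")
    return ped, mp


def write_vcf(gm: GenotypeMatrix, path) -> Path:
    """Write a minimal GT-only VCF 4.2 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    contigs = sorted(set(gm.chrom.astype(str)), key=str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(a) for a in gm.animal_ids) + "\n")
        for j in range(gm.n_snps):
            calls = "\t".join(gt[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.bp[j]}\t{gm.snp_ids[j]}\tA\tB\t.\t"
                     f"PASS\t.\tGT\t{calls}\n")
    return path


# ------------------------------------------------------------------- tables

def write_drp_table(drp: DRPTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    drp.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_drp_table(path, trait: str | None = None) -> DRPTable:
    df = pd.read_csv(path, sep="\t")
    if trait is not None:
        df = df[df["trait"] == trait]
    return DRPTable.from_frame(df)


def write_grm(grm: GRM, prefix) -> tuple[Path, Path]:
    """Square TSV plus a dense lower-triangle (id1 id2 value) text file."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    square = prefix.with_suffix(".grm.tsv")
    tri = prefix.with_suffix(".grm.tri.txt")
    pd.DataFrame(grm.matrix, index=grm.animal_ids,
                 columns=grm.animal_ids).to_csv(square, sep="\t",
                                                float_format=FLOAT_FMT)
    with open(tri, "w") as fh:
        for i, ai in enumerate(grm.animal_ids):
            for j in range(i + 1):
                fh.write(f"{ai}\t{grm.animal_ids[j]}\t"
                         f"{FLOAT_FMT % grm.matrix[i, j]}\n")
    return square, tri


def read_grm(square_path) -> GRM:
    df = pd.read_csv(square_path, sep="\t", index_col=0)
    return GRM(df.to_numpy(), np.array(df.index, dtype=object))


# ------------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Flat run configuration covering simulation, models and the grid."""

    sim: dict = field(default_factory=dict)
    weights: dict = field(default_factory=lambda: asdict(WeightParams()))
    prior: dict = field(default_factory=lambda: asdict(MixturePrior()))
    model: dict = field(default_factory=lambda: asdict(BayesRConfig()))
    panels: dict = field(default_factory=dict)
    design_scheme: str = "table1"
    base_seed: int = 0
    output_dir: str = "results"

    def weight_params(self) -> WeightParams:
        return WeightParams(**self.weights)

    def mixture_prior(self) -> MixturePrior:
        return MixturePrior(
            tuple(self.prior["proportions"]),
            tuple(self.prior["variance_fractions"]),
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_outputs(tables: dict, outdir, config: RunConfig | None = None,
                  seed: int | None = None, overwrite: bool = False) -> dict:
    """Write named DataFrames as TSVs plus a manifest of every artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config) if config is not None else ""
    written = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True)")
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        written[name] = path
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tconfig_hash\tseed\n")
        for name, path in sorted(written.items()):
            fh.write(f"{path.name}\t{chash}\t{'' if seed is None else seed}\n")
    written["manifest"] = manifest
    return written


# ----------------------------------------------------------------- fixtures

def _fixture_two_breeds_small(outdir: Path) -> dict:
    from .population import simulate_genotypes, draw_breed_allele_freqs

    rng = np.random.default_rng(20240613)
    p_anc = rng.uniform(0.1, 0.9, 300)
    pH, pJ = draw_breed_allele_freqs(p_anc, 0.1, 20240614)
    pop = simulate_genotypes(
        {"H": pH, "J": pJ},
        {"H_cow": 20, "J_cow": 20, "50H50J_cow": 20},
        20240615,
    )
    paths = {}
    paths["ped"], paths["map"] = write_plink_text(pop.genotypes,
                                                  outdir / "two_breeds_small")
    paths["vcf"] = write_vcf(pop.genotypes, outdir / "two_breeds_small.vcf")
    truth = pd.DataFrame({
        "animal_id": pop.animal_ids,
        "breed_group": pop.breed_group_true,
        "fH": pop.breed_fractions_true[:, 0],
        "fJ": pop.breed_fractions_true[:, 1],
        "sex": pop.sex,
    })
    truth_path = outdir / "two_breeds_small.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format=FLOAT_FMT)
    paths["truth"] = truth_path
    return paths


FIXTURES = {"two_breeds_small": _fixture_two_breeds_small}


def make_fixture(name: str, outdir) -> dict:
    """Regenerate a named micro-dataset on disk (bit-identical per name)."""
    if name not in FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return FIXTURES[name](outdir)
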