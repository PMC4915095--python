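"""Plain-text readers/writers: pedigree and phenotype CSV, PLINK-style
.ped/.map genotypes, QTL truth tables and result TSVs.

Genotype alleles are coded 1/2 in the .ped; the .map carries both the
genetic position (cM) and a physical position derived from the
1 cM = 1 Mb convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome_sim import GenomeSpec, Population

__all__ = [
    "write_pedigree_csv", "read_pedigree_csv",
    "write_phenotypes_csv", "read_phenotypes_csv",
    "write_plink", "read_plink",
    "write_qtl_truth", "read_qtl_truth",
]


def write_pedigree_csv(path, pop: Population) -> None:
    pop.pedigree_frame().to_csv(path, index=False)


def read_pedigree_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"id", "sire", "dam", "sex", "generation"}
    if not need.issubset(df.columns):
        raise ValueError(f"pedigree file missing columns {need - set(df.columns)}")
    return df


def write_phenotypes_csv(path, pop: Population) -> None:
    has = ~np.isnan(pop.phenotype)
    pd.DataFrame({
        "id": np.nonzero(has)[0] + 1,
        "phenotype": pop.phenotype[has],
    }).to_csv(path, index=False, float_format="%.6f")


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"id", "phenotype"}.issubset(df.columns):
        raise ValueError("phenotype file needs 'id' and 'phenotype' columns")
    return df


def write_plink(prefix, pop: Population, genome: GenomeSpec,
                rows: np.ndarray | None = None) -> None:
    """Write genotyped animals (or ``rows``) as PLINK text .ped/.map."""
    prefix = Path(prefix)
    if rows is None:
        rows = np.nonzero(pop.genotyped)[0]
    mk = genome.marker_index
    chrom = genome.chrom[mk]
    pos = genome.pos_cm[mk]
    with open(prefix.with_suffix(".map"), "w") as fh:
        for i, (c, p) in enumerate(zip(chrom, pos)):
            fh.write(f"{c}\tsnp{i + 1}\t{p:.6f}\t{int(round(p * 1e6))}\n")
    hap = pop.haps[rows][:, :, mk] + 1  # alleles 1/2
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for r, row in enumerate(rows):
            phe = pop.phenotype[row]
            phe_s = f"{phe:.6f}" if np.isfinite(phe) else "-9"
            lead = [f"FAM", f"{row + 1}", f"{pop.sire[row]}", f"{pop.dam[row]}",
                    f"{pop.sex[row]}", phe_s]
            geno = np.empty(2 * hap.shape[2], dtype=np.int64)
            geno[0::2] = hap[r, 0, :]
            geno[1::2] = hap[r, 1, :]
            fh.write(" ".join(lead) + " " + " ".join(map(str, geno)) + "\n")


def read_plink(prefix) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Read text .ped/.map; returns (sample table, dosage matrix of
    allele 2, map table)."""
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep="\t", header=None,
                     names=["chrom", "snp", "cm", "bp"])
    samples, dosages = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            samples.append(parts[:6])
            g = np.array(parts[6:], dtype=np.int8)
            dosages.append((g[0::2] - 1) + (g[1::2] - 1))
    sam = pd.DataFrame(samples, columns=["fid", "iid", "sire", "dam", "sex",
                                         "phenotype"])
    return sam, np.asarray(dosages, dtype=np.int8), mp


def write_qtl_truth(path, genome: GenomeSpec, effects, shares: np.ndarray) -> None:
    qi = genome.qtl_index
    df = pd.DataFrame({
        "chrom": genome.chrom[qi],
        "pos_cm": genome.pos_cm[qi],
        "n_alleles": genome.n_alleles[qi],
        "pvar": shares,
    })
    for a in range(4):
        df[f"effect_allele{a}"] = effects.effects[:, a]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_qtl_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
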