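"""Readers and writers for the standard file formats.

Pedigree, phenotype and breed-composition tables travel as CSV; phased
genotypes as a phased VCF (GT with '|') or a TSV haplotype matrix.  The
VCF written here is synthetic output: positions are placeholder ordinals on
chromosome 2 (the variants are assay-defined, not re-mapped coordinates).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import PhasedHaplotypes
from .pedigree import Pedigree
from .variants import SEGREGATING_VARIANTS, VARIANT_ALLELES


def write_pedigree_csv(ped: Pedigree, path):
    ped.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path))


def write_breed_composition_csv(comp: pd.DataFrame, path):
    comp.rename_axis("animal").to_csv(path)


def read_breed_composition_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="animal")


def write_haplotype_tsv(haps: PhasedHaplotypes, path):
    pat, mat = haps.haplotype_strings()
    pd.DataFrame({"animal": haps.animals,
                  "paternal": pat.values, "maternal": mat.values}) \
        .to_csv(path, sep="\t", index=False)


def read_haplotype_tsv(path) -> PhasedHaplotypes:
    df = pd.read_csv(path, sep="\t", dtype=str)
    pat = np.array([[int(c) for c in s] for s in df["paternal"]], dtype=np.int8)
    mat = np.array([[int(c) for c in s] for s in df["maternal"]], dtype=np.int8)
    return PhasedHaplotypes(animals=df["animal"].tolist(),
                            variants=list(SEGREGATING_VARIANTS),
                            paternal=pat, maternal=mat)


def _vcf_alleles(variant: str) -> tuple[str, str]:
    wt, mut = VARIANT_ALLELES[variant]
    if mut == "-":
        return wt, "<DEL>"
    if wt == "-":
        return "N", mut
    return wt, mut


def write_phased_vcf(haps: PhasedHaplotypes, path):
    """Phased VCF (one record per variant, GT with '|')."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mstnassoc-simulated\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write("##contig=<ID=2>\n")
        cols = "\t".join(map(str, haps.animals))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, v in enumerate(haps.variants):
            ref, alt = _vcf_alleles(v)
            gts = "\t".join(f"{p}|{m}" for p, m in
                            zip(haps.paternal[:, j], haps.maternal[:, j]))
            fh.write(f"2\t{6210000 + 100 * (j + 1)}\t{v}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_phased_vcf(path) -> PhasedHaplotypes:
    """Read a phased VCF via cyvcf2; unphased genotypes are rejected."""
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    animals = list(vcf.samples)
    variants, pat, mat = [], [], []
    for rec in vcf:
        variants.append(rec.ID)
        g = np.array(rec.genotypes)  # (n, 3): allele1, allele2, phased flag
        if not np.all(g[:, 2]):
            raise ValueError(f"unphased genotypes at {rec.ID}; phased input required")
        pat.append(g[:, 0])
        mat.append(g[:, 1])
    return PhasedHaplotypes(animals=animals, variants=variants,
                            paternal=np.array(pat, dtype=np.int8).T,
                            maternal=np.array(mat, dtype=np.int8).T)


def write_relationship_coordinates(rel, path, tol: float = 0.0):
    rel.to_coordinate_frame(tol).to_csv(path, sep="\t", index=False)
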