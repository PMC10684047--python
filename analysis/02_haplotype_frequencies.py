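#!/usr/bin/env python
"""Haplotype frequencies, carrier percentages and r2 LD.

Reads the simulated population from 01, restricts to purebred-verified
animals (>= 90% of breed fractions on one breed), and computes within-breed
and unweighted across-breed haplotype frequencies, per-variant carrier
percentages, and the pairwise r2 LD matrix among segregating variants.
Writes TSVs under results/haplotypes/ and prints the across-breed summary
next to the reference survey values the simulator's founder pools encode.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from mstnassoc import io as mio
from mstnassoc.covariates import purebred_flag
from mstnassoc.haplotypes import (carrier_percentages,
                                  detect_segregating_variants,
                                  haplotype_frequencies, ld_r2_matrix)
from mstnassoc.variants import (ALL_VARIANTS, reference_haplotype_frequencies,
                                HAPLOTYPES)

POP = Path(__file__).resolve().parents[1] / "results" / "population"
OUT = Path(__file__).resolve().parents[1] / "results" / "haplotypes"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    haps = mio.read_haplotype_tsv(POP / "haplotypes.tsv")
    comp = mio.read_breed_composition_csv(POP / "breed_composition.csv")

    flags = comp.apply(purebred_flag, axis=1)
    purebred = flags.dropna()
    print(f"purebred-verified animals: {len(purebred)} of {len(comp)} "
          f"({100*len(purebred)/len(comp):.0f}%)")

    genotypes = haps.genotype_table(all_variants=ALL_VARIANTS)
    seg = detect_segregating_variants(genotypes)
    print(f"segregating variants: {len(seg)} of {len(ALL_VARIANTS)}: {sorted(seg)}")

    gp = genotypes.loc[purebred.index]
    carriers = carrier_percentages(gp, purebred)
    carriers.round(0).to_csv(OUT / "carrier_percentages.tsv", sep="\t")

    sub = haps_subset(haps, purebred.index)
    cat = haplotype_frequencies(sub, purebred)
    cat.report().to_csv(OUT / "haplotype_frequencies.tsv", sep="\t")

    name_of = {"".join(map(str, v)): k for k, v in HAPLOTYPES.items()}
    ref = reference_haplotype_frequencies()
    print("\nacross-breed haplotype frequency, simulated vs survey reference:")
    for hap in cat.haplotypes[:6]:
        nm = name_of.get(hap, hap)
        refv = ref.loc[nm].mean() if nm in ref.index else float("nan")
        print(f"  {nm}: simulated {cat.across_breed_pct[hap]:5.1f}%  "
              f"reference {refv:5.1f}%")

    ld = ld_r2_matrix(sub, seg_order(sub, seg))
    ld.round(4).to_csv(OUT / "ld_r2_matrix.tsv", sep="\t")
    print(f"\nwritten to {OUT}")


def haps_subset(haps, animals):
    import numpy as np
    from mstnassoc.haplotypes import PhasedHaplotypes
    keep = [i for i, a in enumerate(haps.animals) if a in set(animals)]
    return PhasedHaplotypes(animals=[haps.animals[i] for i in keep],
                            variants=haps.variants,
                            paternal=haps.paternal[keep],
                            maternal=haps.maternal[keep])


def seg_order(sub, seg):
    return [v for v in sub.variants if v in set(seg)]


if __name__ == "__main__":
    main()
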