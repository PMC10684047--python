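"""Catalogue of the 21 named myostatin (MSTN/GDF8) variants and the common
haplotypes segregating in Irish cattle.

The mutant allele of each variant is written ``mh`` and the wild-type allele
``+`` throughout the package; genotypes are counts of the mutant allele
(0, 1, 2).  Ten of the 21 variants segregate in the twelve Irish beef and
dairy breeds surveyed; haplotypes are formed over those ten sites, in the
fixed order of :data:`SEGREGATING_VARIANTS`.

The reference frequency tables in this module (within-breed carrier
percentages and within-breed haplotype frequencies from the national
genotyped survey population) both seed the default founder haplotype pools
of the simulator and serve as worked inputs for the across-breed summary
arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The 12 surveyed breeds (Angus, Aubrac, Blonde d'Aquitaine, Belgian Blue,
#: Charolais, Friesian, Hereford, Holstein, Limousin, Salers, Shorthorn,
#: Simmental).
BREEDS = ["AA", "AU", "BA", "BB", "CH", "FR", "HE", "HO", "LM", "SA", "SH", "SI"]

#: variant -> (wild-type allele, mutant allele).  "-" denotes a deletion
#: allele.  Alleles are the literal sequence strings of the assay.
VARIANT_ALLELES: dict[str, tuple[str, str]] = {
    "C313Y": ("G", "A"),
    "D182N": ("G", "A"),
    "E226X": ("G", "T"),
    "E291X": ("G", "T"),
    "F140L": ("TTAAATT", "-"),
    "F94L": ("C", "A"),
    "L64P": ("T", "C"),
    "nt267": ("A", "G"),
    "nt324": ("C", "T"),
    "nt374_16": ("T", "-"),
    "nt374_50": ("G", "A"),
    "nt374_51": ("C", "T"),
    "nt387": ("G", "A"),
    "nt414": ("C", "T"),
    "nt419": ("TTAAATT", "AAGCATACAA"),
    "nt747+11": ("A", "G"),
    "nt747+7": ("G", "A"),
    "nt748_78": ("T", "-"),
    "nt821": ("ATGAACACTCC", "-"),
    "Q204X": ("C", "T"),
    "S105C": ("C", "G"),
}

ALL_VARIANTS = list(VARIANT_ALLELES)

#: The ten variants that segregate in the purebred survey populations, in
#: the column order used for haplotype strings.
SEGREGATING_VARIANTS = [
    "nt748_78", "F94L", "nt324", "nt267", "nt374_51",
    "nt374_50", "nt414", "Q204X", "E226X", "nt821",
]

# The 22 haplotypes with a within-breed frequency >= 1%, written as mutant
# indicators over SEGREGATING_VARIANTS (1 = mutant allele carried).
# Haplotype 1 is the all-wild-type haplotype.
HAPLOTYPES: dict[str, tuple[int, ...]] = {
    "hap01": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "hap02": (1, 0, 0, 0, 0, 1, 1, 0, 0, 0),
    "hap03": (0, 1, 0, 0, 0, 0, 0, 0, 0, 0),
    "hap04": (0, 0, 0, 0, 1, 0, 0, 0, 0, 1),
    "hap05": (0, 1, 0, 0, 1, 0, 0, 0, 0, 0),
    "hap06": (0, 0, 0, 0, 1, 0, 0, 0, 0, 0),
    "hap07": (1, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "hap08": (0, 0, 0, 1, 0, 0, 0, 0, 0, 0),
    "hap09": (1, 0, 0, 0, 0, 1, 1, 1, 0, 0),
    "hap10": (1, 0, 0, 0, 1, 1, 1, 0, 0, 0),
    "hap11": (1, 0, 0, 1, 0, 1, 1, 0, 0, 0),
    "hap12": (0, 1, 0, 0, 1, 0, 0, 0, 0, 1),
    "hap13": (0, 0, 0, 0, 1, 0, 0, 0, 1, 0),
    "hap14": (0, 0, 0, 0, 0, 1, 1, 0, 0, 0),
    "hap15": (1, 1, 0, 0, 0, 1, 1, 1, 0, 0),
    "hap16": (1, 1, 0, 0, 0, 1, 1, 0, 0, 0),
    "hap17": (0, 0, 1, 0, 0, 0, 0, 0, 0, 0),
    "hap18": (1, 0, 0, 0, 1, 0, 0, 0, 0, 1),
    "hap19": (0, 1, 1, 0, 1, 0, 0, 0, 0, 0),
    "hap20": (0, 0, 0, 1, 1, 0, 0, 0, 0, 0),
    "hap21": (1, 1, 0, 0, 0, 0, 0, 0, 0, 0),
    "hap22": (1, 1, 0, 0, 1, 1, 1, 1, 0, 0),
}

WILDTYPE_HAPLOTYPE = "hap01"

# Reference within-breed haplotype frequencies (%) in the purebred survey
# populations; columns follow BREEDS.  Zeros mean the haplotype was not seen
# at >= 1% in that breed.
_HAP_FREQ_ROWS = {
    "hap01": [66.4, 11.2, 59.9, 0.0, 52.4, 54.8, 36.1, 51.4, 10.1, 45.7, 71.1, 56.2],
    "hap02": [17.3, 0.0, 0.0, 0.0, 12.1, 35.3, 55.0, 42.3, 0.0, 31.9, 10.6, 21.1],
    "hap03": [0.0, 44.2, 1.9, 0.0, 6.7, 0.0, 0.0, 0.0, 51.1, 0.0, 0.0, 0.0],
    "hap04": [2.3, 0.0, 0.0, 97.7, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.6, 0.0],
    "hap05": [0.0, 30.3, 1.4, 0.0, 2.0, 0.0, 0.0, 0.0, 25.4, 0.0, 0.0, 0.0],
    "hap06": [6.6, 2.7, 33.6, 0.0, 3.1, 3.0, 1.0, 0.0, 1.1, 3.3, 4.1, 0.0],
    "hap07": [2.3, 0.0, 0.0, 0.0, 1.0, 3.7, 1.3, 3.1, 0.0, 1.6, 1.6, 1.4],
    "hap08": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 4.0, 0.0, 9.4],
    "hap09": [0.0, 0.0, 0.0, 0.0, 9.8, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    "hap10": [1.6, 0.0, 0.0, 0.0, 1.0, 1.5, 2.3, 0.0, 0.0, 2.7, 0.0, 0.0],
    "hap11": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 3.3, 0.0, 4.3],
    "hap12": [0.0, 3.8, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0],
    "hap13": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 5.7, 0.0],
    "hap14": [0.0, 0.0, 0.0, 0.0, 0.0, 1.3, 2.4, 0.0, 0.0, 1.3, 0.0, 0.0],
    "hap15": [0.0, 0.0, 0.0, 0.0, 1.9, 0.0, 0.0, 0.0, 2.4, 0.0, 0.0, 0.0],
    "hap16": [0.0, 0.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, 1.5, 0.0, 0.0, 0.0],
    "hap17": [0.0, 0.0, 0.0, 0.0, 1.3, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.6],
    "hap18": [0.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    "hap19": [0.0, 1.8, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    "hap20": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.6, 0.0, 0.0],
    "hap21": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.1, 0.0, 0.0, 0.0],
    "hap22": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.1, 0.0, 0.0, 0.0],
}

#: Reference within-breed carrier percentages (% of purebred animals with at
#: least one mutant allele) for the ten segregating variants.
_CARRIER_PCT_ROWS = {
    "E226X": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 14, 0],
    "F94L": [1, 98, 8, 0, 27, 0, 0, 0, 99, 1, 1, 1],
    "nt267": [1, 0, 2, 0, 0, 0, 0, 0, 0, 20, 0, 28],
    "nt324": [0, 7, 0, 0, 8, 0, 0, 0, 0, 0, 0, 7],
    "nt374_50": [38, 6, 0, 0, 53, 63, 18, 69, 15, 65, 25, 49],
    "nt374_51": [22, 64, 60, 100, 18, 9, 7, 3, 53, 19, 28, 3],
    "nt414": [37, 5, 0, 0, 53, 63, 84, 69, 13, 65, 25, 49],
    "nt748_78": [40, 7, 2, 3, 56, 66, 84, 72, 16, 66, 27, 50],
    "nt821": [6, 9, 0, 99, 0, 0, 0, 0, 6, 3, 7, 0],
    "Q204X": [0, 1, 0, 0, 27, 0, 0, 0, 8, 0, 0, 1],
}


def reference_haplotype_frequencies() -> pd.DataFrame:
    """Within-breed percentage frequencies of the 22 common haplotypes."""
    return pd.DataFrame.from_dict(_HAP_FREQ_ROWS, orient="index", columns=BREEDS)


def reference_carrier_percentages() -> pd.DataFrame:
    """Within-breed carrier percentages of the ten segregating variants."""
    return pd.DataFrame.from_dict(_CARRIER_PCT_ROWS, orient="index", columns=BREEDS, dtype=float)


def haplotype_matrix() -> np.ndarray:
    """(22, 10) mutant-indicator matrix over SEGREGATING_VARIANTS."""
    return np.array([HAPLOTYPES[h] for h in sorted(HAPLOTYPES)], dtype=np.int8)


def haplotype_string(name: str) -> str:
    """Allele string (wild/mutant sequence symbols) of a catalogue haplotype."""
    alleles = []
    for v, ind in zip(SEGREGATING_VARIANTS, HAPLOTYPES[name]):
        wt, mut = VARIANT_ALLELES[v]
        alleles.append(mut if ind else wt)
    return "/".join(alleles)


def default_founder_pools(min_freq: float = 0.01) -> dict[str, list[tuple[str, float]]]:
    """Per-breed founder haplotype pools from the reference frequencies.

    The printed within-breed frequencies omit haplotypes rarer than 1% and so
    do not sum to 100 exactly; each breed's column is renormalised to a
    proper probability distribution.
    """
    freq = reference_haplotype_frequencies()
    pools: dict[str, list[tuple[str, float]]] = {}
    for b in BREEDS:
        col = freq[b]
        col = col[col >= 100.0 * min_freq]
        total = col.sum()
        pools[b] = [(h, f / total) for h, f in col.items()]
    return pools
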