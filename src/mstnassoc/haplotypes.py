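"""Haplotype frequencies, carrier percentages and linkage disequilibrium.

Phase is consumed, not computed: phased haplotype pairs (one paternal, one
maternal allele string over the segregating variants) are the input to every
operation here.  Within-breed frequencies are haplotype counts over twice
the breed size; across-breed summaries are *unweighted* means of the
within-breed values (zeros included for breeds where a haplotype is absent)
so that unequal breed sample sizes do not bias the summary.

Reporting dialects: carrier percentages are printed as whole percent,
haplotype frequencies with one decimal; all internal values are kept at
full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PhasedHaplotypes:
    """Phased haplotypes for a set of animals.

    ``paternal``/``maternal`` are (n_animals, n_variants) mutant-allele
    indicator matrices over ``variants`` (0 wild-type, 1 mutant).
    """

    animals: list
    variants: list
    paternal: np.ndarray
    maternal: np.ndarray
    phased: bool = True

    def __post_init__(self):
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        if self.paternal.shape != (len(self.animals), len(self.variants)):
            raise ValueError("haplotype matrix shape does not match animals x variants")
        if self.paternal.shape != self.maternal.shape:
            raise ValueError("paternal and maternal matrices differ in shape")

    def genotype_table(self, all_variants: list | None = None) -> pd.DataFrame:
        """Mutant-allele counts (0/1/2) per animal; variants absent from the
        haplotype representation are monomorphic wild-type (0)."""
        g = pd.DataFrame(self.paternal + self.maternal,
                         index=self.animals, columns=self.variants, dtype=float)
        if all_variants is not None:
            g = g.reindex(columns=all_variants, fill_value=0.0)
        return g

    def haplotype_strings(self) -> tuple[pd.Series, pd.Series]:
        pat = pd.Series(["".join(map(str, r)) for r in self.paternal], index=self.animals)
        mat = pd.Series(["".join(map(str, r)) for r in self.maternal], index=self.animals)
        return pat, mat


@dataclass
class HaplotypeCatalog:
    """Haplotypes at >= min_freq in at least one breed, with within-breed
    percentage frequencies and their unweighted across-breed mean."""

    haplotypes: list[str]
    within_breed_pct: pd.DataFrame
    across_breed_pct: pd.Series
    carrier_counts: pd.DataFrame
    min_freq: float

    def report(self) -> pd.DataFrame:
        out = self.within_breed_pct.round(1)
        out["across_breed"] = self.across_breed_pct.round(1)
        return out


def across_breed_mean(values, decimals: int | None = None) -> float:
    """Unweighted mean of within-breed values (the survey's across-breed
    summary); optionally rounded to the reporting dialect."""
    m = float(np.mean(np.asarray(list(values), dtype=float)))
    if decimals is None:
        return m
    r = np.round(m, decimals)
    return float(r) if decimals else int(r)


def detect_segregating_variants(genotypes: pd.DataFrame) -> list:
    """Variants with at least one observed mutant allele in the population.

    ``genotypes`` holds 0/1/2 mutant-allele counts (NaN = missing)."""
    if len(genotypes) == 0:
        raise ValueError("cannot assess segregation in an empty population")
    counts = genotypes.sum(axis=0, skipna=True)
    return [v for v in genotypes.columns if counts[v] > 0]


def carrier_percentages(
    genotypes: pd.DataFrame, breed_labels: pd.Series
) -> pd.DataFrame:
    """Percent of animals per breed carrying >= 1 mutant allele per variant,
    plus the unweighted across-breed mean.

    Animals with a missing genotype at a variant are excluded from that
    variant's denominator.  Breeds without animals are excluded (warning).
    """
    breeds = [b for b in pd.unique(breed_labels) if (breed_labels == b).any()]
    out = {}
    for b in sorted(breeds, key=str):
        sub = genotypes.loc[breed_labels.index[breed_labels == b]]
        denom = sub.notna().sum(axis=0)
        if (denom == 0).all():
            import warnings
            warnings.warn(f"breed {b} has no genotyped animals; excluded")
            continue
        out[b] = 100.0 * (sub > 0).sum(axis=0) / denom.replace(0, np.nan)
    table = pd.DataFrame(out)
    table["across_breed"] = table.mean(axis=1)
    return table


def haplotype_frequencies(
    pairs: PhasedHaplotypes,
    breed_labels: pd.Series,
    min_freq: float = 0.01,
) -> HaplotypeCatalog:
    """Within-breed haplotype frequencies with the >= min_freq-in-any-breed
    filter and unweighted across-breed means (zeros counted)."""
    if not pairs.phased:
        raise ValueError("haplotype frequencies need phased input; supply phased data")
    pat, mat = pairs.haplotype_strings()
    labels = breed_labels.reindex(pairs.animals)
    breeds = sorted((b for b in labels.dropna().unique()), key=str)
    within = {}
    carriers = {}
    for b in breeds:
        members = labels.index[labels == b]
        haps = pd.concat([pat[members], mat[members]])
        within[b] = haps.value_counts() / float(len(haps))
        both = pd.DataFrame({"p": pat[members], "m": mat[members]})
        carr = {}
        for h in haps.unique():
            carr[h] = int(((both["p"] == h) | (both["m"] == h)).sum())
        carriers[b] = pd.Series(carr)
    freq = pd.DataFrame(within).fillna(0.0)
    keep = freq.index[(freq >= min_freq).any(axis=1)]
    freq = freq.loc[keep]
    order = freq.mean(axis=1).sort_values(ascending=False).index
    freq = freq.loc[order]
    pct = 100.0 * freq
    return HaplotypeCatalog(
        haplotypes=list(freq.index),
        within_breed_pct=pct,
        across_breed_pct=pct.mean(axis=1),
        carrier_counts=pd.DataFrame(carriers).fillna(0.0).reindex(freq.index).astype(int),
        min_freq=min_freq,
    )


def ld_r2(pairs: PhasedHaplotypes, variant_a: str, variant_b: str) -> float:
    """Pairwise r-squared LD from phased haplotype counts.

    r2 = D^2 / (p_a (1-p_a) p_b (1-p_b)) with D = p_ab - p_a p_b estimated
    over the 2n phased haplotypes; identical to the squared Pearson
    correlation of the two mutant-allele indicators across haplotypes.
    """
    if not pairs.phased:
        raise ValueError("r2 LD needs phased haplotypes")
    ia = pairs.variants.index(variant_a)
    ib = pairs.variants.index(variant_b)
    a = np.concatenate([pairs.paternal[:, ia], pairs.maternal[:, ia]]).astype(float)
    b = np.concatenate([pairs.paternal[:, ib], pairs.maternal[:, ib]]).astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError(
            f"r2 undefined: variant {variant_a if pa in (0, 1) else variant_b} is monomorphic")
    D = (a * b).mean() - pa * pb
    return float(D * D / (pa * (1 - pa) * pb * (1 - pb)))


def ld_r2_matrix(pairs: PhasedHaplotypes, variants: list | None = None) -> pd.DataFrame:
    """Symmetric r2 matrix over the segregating variants (NaN where a
    variant is monomorphic in the sample)."""
    vs = variants or pairs.variants
    out = pd.DataFrame(np.eye(len(vs)), index=vs, columns=vs)
    for i, va in enumerate(vs):
        for vb in vs[i + 1:]:
            try:
                r2 = ld_r2(pairs, va, vb)
            except ValueError:
                r2 = np.nan
            out.loc[va, vb] = out.loc[vb, va] = r2
    return out
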