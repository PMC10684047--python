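"""Fixed-effect covariates derived from breed composition and record data.

Crossbred animals are described by a 12-way breed-fraction vector.  The
general heterosis coefficient of a mating is the expected proportion of
loci with alleles from two different breeds, ``1 - sum_i sire_i * dam_i``;
the recombination-loss coefficient is ``1 - sum_i (sire_i^2 + dam_i^2)/2``,
the expected loss of parental epistatic combinations, which is 0 for any
purebred x purebred mating.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_SUM_TOL = 1e-6


def _check_composition(frac: pd.Series | dict, who: str = "animal") -> pd.Series:
    s = pd.Series(frac, dtype=float)
    if (s < -1e-12).any() or (s > 1 + 1e-12).any():
        raise ValueError(f"breed fractions of {who} outside [0, 1]")
    if abs(s.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"breed fractions of {who} sum to {s.sum():.6f}, not 1")
    return s


def heterosis_coefficient(sire: pd.Series | dict, dam: pd.Series | dict) -> float:
    """1 - sum_i sire_i * dam_i; 0 for same-breed purebred matings, 1 when
    sire and dam share no breed."""
    s = _check_composition(sire, "sire")
    d = _check_composition(dam, "dam")
    breeds = s.index.union(d.index)
    val = 1.0 - float((s.reindex(breeds, fill_value=0.0)
                       * d.reindex(breeds, fill_value=0.0)).sum())
    return min(max(val, 0.0), 1.0)


def recombination_loss(sire: pd.Series | dict, dam: pd.Series | dict) -> float:
    """1 - sum_i (sire_i^2 + dam_i^2) / 2.

    Defined so that every purebred x purebred mating scores 0 (the parental
    genomes carry no between-breed recombinant segments), the property that
    fixes the placement of the squares in the formula.
    """
    s = _check_composition(sire, "sire")
    d = _check_composition(dam, "dam")
    val = 1.0 - float((s ** 2).sum() + (d ** 2).sum()) / 2.0
    return min(max(val, 0.0), 1.0)


def heterosis_recombination_table(
    compositions: pd.DataFrame, sires: pd.Series, dams: pd.Series
) -> pd.DataFrame:
    """Vectorised heterosis/recombination coefficients for many animals.

    ``compositions`` is animals x breed-fraction columns; ``sires``/``dams``
    give each animal's parent ids (index = animal).  Animals with an unknown
    parent get NA coefficients.
    """
    comp = compositions.div(compositions.sum(axis=1), axis=0)
    out = pd.DataFrame(index=sires.index, columns=["heterosis", "recombination"], dtype=float)
    known = sires.notna() & dams.notna() & sires.isin(comp.index) & dams.isin(comp.index)
    sc = comp.reindex(sires[known]).to_numpy()
    dc = comp.reindex(dams[known]).to_numpy()
    out.loc[known, "heterosis"] = 1.0 - np.sum(sc * dc, axis=1)
    out.loc[known, "recombination"] = 1.0 - 0.5 * (np.sum(sc ** 2, axis=1) + np.sum(dc ** 2, axis=1))
    return out


def parity_age_class(
    parity: int,
    age_days: float,
    parity_medians: dict[int, float],
    band_days: int = 30,
    max_deviation: int = 425,
) -> str:
    """Class label for the parity-by-age interaction.

    The deviation of age at calving from the parity median is banded into
    ``band_days`` wide bins rounded away from zero: deviation 0 -> band 0,
    (0, band] -> +1, (band, 2 band] -> +2, and symmetrically for negative
    deviations.  Deviations beyond ``max_deviation`` are an upstream edit
    (records removed before modelling) and raise here.
    """
    if parity < 1:
        raise ValueError(f"parity must be >= 1, got {parity}")
    if parity not in parity_medians:
        raise ValueError(f"no age median defined for parity {parity}")
    dev = float(age_days) - float(parity_medians[parity])
    if abs(dev) > max_deviation:
        raise ValueError(
            f"age deviation {dev:+.0f} d exceeds the {max_deviation} d edit bound; "
            "such records are removed upstream")
    band = int(np.ceil(abs(dev) / band_days)) * (1 if dev > 0 else -1)
    if dev == 0:
        band = 0
    return f"{parity}:{band:+d}" if band else f"{parity}:0"


def age_sex_class(age_months: int, sex_class: str) -> str:
    """Slaughter-age (whole months) by sex-class interaction label."""
    return f"{sex_class}:{int(age_months)}"


def purebred_flag(composition: pd.Series | dict, threshold: float = 0.90) -> str | None:
    """The breed to which the animal is >= threshold purebred, else None.

    The threshold comparison is inclusive: exactly 90% counts as purebred.
    """
    s = _check_composition(composition)
    best = s.idxmax()
    return best if s[best] >= threshold else None
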