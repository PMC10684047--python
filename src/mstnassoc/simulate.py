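"""Synthetic cattle populations with known truth.

Generates pedigrees, breed compositions, phased myostatin genotypes
(Mendelian single-block transmission: the gene spans a few kb, so no
within-locus recombination), herd/date structure that yields valid
contemporary groups by construction, and phenotypes under the calving and
carcass mixed models with configurable true variance components and
genotype effects.

All randomness flows from one seed through a single generator
(numpy default_rng); per-operation substreams are spawned deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .haplotypes import PhasedHaplotypes
from .pedigree import Pedigree, inbreeding
from .variants import ALL_VARIANTS, HAPLOTYPES, SEGREGATING_VARIANTS


@dataclass
class SimulationConfig:
    """True parameters of a simulated study.

    ``variance_components`` holds cg, direct, maternal, pe and residual
    variances (score^2 or kg^2).  ``genotype_effects`` maps a variant to
    per-copy class effects for calf and dam, e.g.
    ``{"nt821": {"calf": {1: 0.13, 2: 0.37}, "dam": {1: 0.05, 2: 1.30}}}``.
    ``interaction_effects`` maps (variant, dam_copies, calf_copies) to a
    deviation from additivity.
    """

    n_founders: int = 100
    n_generations: int = 2
    breed_labels: list = field(default_factory=list)
    founder_haplotype_pools: dict = field(default_factory=dict)
    n_herds: int = 40
    records_per_herd_year: int = 45
    variance_components: dict = field(default_factory=lambda: {
        "cg": 0.02, "direct": 0.04, "maternal": 0.02, "pe": 0.01, "residual": 0.30})
    fixed_effects: dict = field(default_factory=dict)
    genotype_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for k, v in self.variance_components.items():
            if v < 0:
                raise ValueError(f"variance component {k!r} is negative")
        if len(self.breed_labels) > 12:
            raise ValueError("at most 12 breed labels")
        for breed, pool in self.founder_haplotype_pools.items():
            tot = sum(f for _, f in pool)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"haplotype pool of breed {breed!r} sums to {tot}")

    def to_yaml(self, path):
        d = {k: v for k, v in self.__dict__.items()}
        d["founder_haplotype_pools"] = {
            b: [[str(h), float(f)] for h, f in pool]
            for b, pool in self.founder_haplotype_pools.items()}
        d["variance_components"] = {k: float(v) for k, v
                                    in self.variance_components.items()}
        d["interaction_effects"] = {
            "|".join(map(str, k)): float(v)
            for k, v in self.interaction_effects.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        ia = d.get("interaction_effects", {})
        d["interaction_effects"] = {
            tuple(int(x) if x.isdigit() else x for x in k.split("|")): v
            for k, v in ia.items()}
        d["founder_haplotype_pools"] = {
            b: [(h, f) for h, f in pool]
            for b, pool in d.get("founder_haplotype_pools", {}).items()}
        return cls(**d)


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Deterministic named substream of the master seed (stable across
    processes: stream names are hashed with crc32, not Python's hash)."""
    import zlib
    key = zlib.crc32(stream.encode()) % (2 ** 31)
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig,
                      offspring_per_generation: int | None = None) -> pd.DataFrame:
    """Generic generational pedigree: founders then ``n_generations`` crops
    of offspring whose parents come from earlier generations."""
    if config.n_founders < 2:
        raise ValueError("need at least two founders (one sire, one dam)")
    if config.n_generations < 1:
        raise ValueError("need at least one generation of offspring")
    rng = rng_for(config.seed, "pedigree")
    n_off = offspring_per_generation or config.n_founders
    breeds = config.breed_labels or ["XX"]
    rows = []
    males, females = [], []
    nid = 0
    for i in range(config.n_founders):
        nid += 1
        a = f"F{nid:06d}"
        sex = "M" if i % 2 == 0 else "F"
        (males if sex == "M" else females).append(a)
        rows.append({"animal": a, "sire": None, "dam": None,
                     "birth_date": pd.Timestamp("2000-01-01"),
                     "sex": sex, "breed": breeds[i % len(breeds)]})
    if not males or not females:
        raise ValueError("founders must include both sexes")
    for g in range(1, config.n_generations + 1):
        new = []
        for _ in range(n_off):
            nid += 1
            a = f"G{g}{nid:06d}"
            sex = "M" if rng.random() < 0.5 else "F"
            rows.append({"animal": a,
                         "sire": males[int(rng.integers(len(males)))],
                         "dam": females[int(rng.integers(len(females)))],
                         "birth_date": pd.Timestamp(f"{2000 + g}-01-01"),
                         "sex": sex, "breed": None})
            new.append((a, sex))
        for a, s in new:
            (males if s == "M" else females).append(a)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _pool_to_arrays(pool) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype pool -> (indicator matrix, probabilities).  Entries may be
    catalogue names or 0/1 strings over the segregating variants."""
    mats, probs = [], []
    for hap, f in pool:
        if isinstance(hap, str) and hap in HAPLOTYPES:
            mats.append(HAPLOTYPES[hap])
        else:
            vec = tuple(int(c) for c in hap)
            if len(vec) != len(SEGREGATING_VARIANTS):
                raise ValueError(f"haplotype {hap!r} has wrong length")
            mats.append(vec)
        probs.append(f)
    return np.array(mats, dtype=np.int8), np.array(probs, dtype=float)


def simulate_genotypes(ped: Pedigree, founder_breeds: pd.Series,
                       founder_haplotype_pools: dict, rng: np.random.Generator,
                       carrier_founders: tuple | None = None,
                       ) -> PhasedHaplotypes:
    """Drop phased haplotypes through the pedigree.

    Founders draw two haplotypes from their breed pool; every non-founder
    receives one unrecombined haplotype from each parent, chosen uniformly.

    ``carrier_founders=(ids, variant)`` implements a carrier-sire progeny
    design: the named founders have their first haplotype drawn from their
    breed pool conditioned on carrying the mutant allele of ``variant``
    (falling back to any pool's carrier haplotype, then to the singleton
    mutant haplotype, for breeds where none segregates).
    """
    n = len(ped)
    pools = {}
    for b, pool in founder_haplotype_pools.items():
        pools[b] = _pool_to_arrays(pool)
    # global catalogue of distinct haplotypes in play
    cat_rows: list[tuple] = []
    cat_idx: dict[tuple, int] = {}
    pool_codes = {}
    for b, (mat, probs) in pools.items():
        codes = []
        for r in mat:
            key = tuple(r)
            if key not in cat_idx:
                cat_idx[key] = len(cat_rows)
                cat_rows.append(key)
            codes.append(cat_idx[key])
        pool_codes[b] = (np.array(codes), probs)

    carrier_set: set = set()
    carrier_col = -1
    if carrier_founders is not None:
        ids, variant = carrier_founders
        carrier_set = set(ids)
        carrier_col = SEGREGATING_VARIANTS.index(variant)

    def carrier_code(breed):
        for b in (breed, *pool_codes):
            codes, probs = pool_codes[b]
            ok = [(c, p) for c, p in zip(codes, probs) if cat_rows[c][carrier_col]]
            if ok:
                w = np.array([p for _, p in ok])
                return ok[int(rng.choice(len(ok), p=w / w.sum()))][0]
        single = tuple(1 if j == carrier_col else 0
                       for j in range(len(SEGREGATING_VARIANTS)))
        if single not in cat_idx:
            cat_idx[single] = len(cat_rows)
            cat_rows.append(single)
        return cat_idx[single]

    hap = np.zeros((n, 2), dtype=np.int32)
    u_parent = rng.integers(0, 2, size=(n, 2))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            b = founder_breeds.get(ped.ids[i])
            if b is None or b not in pool_codes:
                raise ValueError(f"founder {ped.ids[i]!r} has no haplotype pool (breed {b!r})")
            codes, probs = pool_codes[b]
            hap[i, 0] = codes[rng.choice(len(probs), p=probs)]
            hap[i, 1] = codes[rng.choice(len(probs), p=probs)]
            if ped.ids[i] in carrier_set and not (
                    cat_rows[hap[i, 0]][carrier_col] or cat_rows[hap[i, 1]][carrier_col]):
                hap[i, 0] = carrier_code(b)
        else:
            if s < 0 or d < 0:
                raise ValueError(f"animal {ped.ids[i]!r} has exactly one known parent; "
                                 "genotype dropping needs both or none")
            hap[i, 0] = hap[s, u_parent[i, 0]]
            hap[i, 1] = hap[d, u_parent[i, 1]]
    cat = np.array(cat_rows, dtype=np.int8)
    return PhasedHaplotypes(
        animals=list(ped.ids), variants=list(SEGREGATING_VARIANTS),
        paternal=cat[hap[:, 0]], maternal=cat[hap[:, 1]])


def genotype_counts(haps: PhasedHaplotypes, variant: str) -> pd.Series:
    """Mutant-allele count (0/1/2) per animal at one variant."""
    j = haps.variants.index(variant)
    return pd.Series(haps.paternal[:, j] + haps.maternal[:, j],
                     index=haps.animals, dtype=int)


# ---------------------------------------------------------------------------
# genetic effects
# ---------------------------------------------------------------------------

def sample_breeding_values(ped: Pedigree, sigma2: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Additive values with covariance A * sigma2 by Mendelian-sampling
    cascade: a_i = (a_s + a_d)/2 + sqrt(d_i sigma2) z_i, with the
    Meuwissen-Luo d_i, so the result is exactly N(0, A sigma2)."""
    _, d = inbreeding(ped)
    z = rng.standard_normal(len(ped))
    a = np.zeros(len(ped))
    sire, dam = ped.sire, ped.dam
    sd = np.sqrt(d * sigma2)
    for i in range(len(ped)):
        mu = 0.0
        if sire[i] >= 0:
            mu += 0.5 * a[sire[i]]
        if dam[i] >= 0:
            mu += 0.5 * a[dam[i]]
        a[i] = mu + sd[i] * z[i]
    return a


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _genotype_effect(copies: np.ndarray, effects: dict | None) -> np.ndarray:
    out = np.zeros(len(copies), dtype=float)
    if effects:
        for c, e in effects.items():
            out[copies == int(c)] = e
    return out


def simulate_calving_phenotypes(
    ped: Pedigree,
    haps: PhasedHaplotypes,
    skeleton: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    covariate_effects: dict | None = None,
) -> pd.DataFrame:
    """Continuous calving-difficulty scores under the animal-dam model.

    ``skeleton`` must carry calf, dam, herd, date, parity, age_days, sex,
    cg_true (the generative contemporary-group key) and the covariate
    columns (heterosis/recombination of calf and dam, breed fractions).
    The response is the sum of the configured fixed effects, the genotype
    class effects of calf and dam (plus any interaction deviation), and
    random cg / direct / maternal / pe / residual draws.
    """
    vc = config.variance_components
    n = len(skeleton)
    fx = dict(config.fixed_effects)
    eff = np.full(n, float(fx.get("intercept", 0.0)))
    sexmap = fx.get("sex", {})
    eff += skeleton["sex"].map(lambda s: sexmap.get(s, 0.0)).to_numpy()
    ce = covariate_effects or {}
    for col, b in ce.items():
        if col in skeleton.columns:
            eff += b * skeleton[col].to_numpy(dtype=float)
    parmap = fx.get("parity", {})
    eff += skeleton["parity"].map(lambda p: parmap.get(int(p), 0.0)).to_numpy()

    for variant, spec_eff in config.genotype_effects.items():
        gc = genotype_counts(haps, variant)
        calf_copies = gc.reindex(skeleton["calf"]).to_numpy()
        dam_copies = gc.reindex(skeleton["dam"]).to_numpy()
        eff += _genotype_effect(calf_copies, spec_eff.get("calf"))
        eff += _genotype_effect(dam_copies, spec_eff.get("dam"))
        for (v, dcop, ccop), dev in config.interaction_effects.items():
            if v == variant:
                eff += dev * ((dam_copies == dcop) & (calf_copies == ccop))

    a = sample_breeding_values(ped, vc["direct"], rng)
    m = sample_breeding_values(ped, vc["maternal"], rng)
    ci = ped.indices_of(skeleton["calf"])
    di = ped.indices_of(skeleton["dam"])
    cg_keys = skeleton["cg_true"].astype(str)
    cg_levels = sorted(cg_keys.unique())
    cg_eff = dict(zip(cg_levels,
                      rng.normal(0.0, np.sqrt(vc["cg"]), len(cg_levels))))
    dams = sorted(skeleton["dam"].unique(), key=str)
    pe_eff = dict(zip(dams, rng.normal(0.0, np.sqrt(vc["pe"]), len(dams))))
    y = (eff + a[ci] + m[di]
         + cg_keys.map(cg_eff).to_numpy()
         + skeleton["dam"].map(pe_eff).to_numpy()
         + rng.normal(0.0, np.sqrt(vc["residual"]), n))
    out = skeleton.copy()
    out["score"] = y
    return out


def simulate_carcass_phenotypes(
    ped: Pedigree,
    haps: PhasedHaplotypes,
    skeleton: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    covariate_effects: dict | None = None,
) -> pd.DataFrame:
    """Carcass phenotypes under the animal model: fixed contemporary group
    (drawn once per cg_true key), age-by-sex and parity effects, genotype
    class effect of the animal, direct genetic effect, residual."""
    vc = config.variance_components
    n = len(skeleton)
    fx = dict(config.fixed_effects)
    eff = np.full(n, float(fx.get("intercept", 0.0)))
    sexmap = fx.get("sex_class", {})
    eff += skeleton["sex_class"].map(lambda s: sexmap.get(s, 0.0)).to_numpy()
    eff += fx.get("age_slope", 0.0) * skeleton["age_months"].to_numpy(dtype=float)
    parmap = fx.get("parity", {})
    eff += skeleton["dam_parity"].map(lambda p: parmap.get(int(p), 0.0)).to_numpy()
    for col, b in (covariate_effects or {}).items():
        if col in skeleton.columns:
            eff += b * skeleton[col].to_numpy(dtype=float)

    for variant, spec_eff in config.genotype_effects.items():
        gc = genotype_counts(haps, variant)
        copies = gc.reindex(skeleton["animal"]).to_numpy()
        eff += _genotype_effect(copies, spec_eff.get("calf"))

    a = sample_breeding_values(ped, vc["direct"], rng)
    ai = ped.indices_of(skeleton["animal"])
    cg_keys = skeleton["cg_true"].astype(str)
    cg_levels = sorted(cg_keys.unique())
    cg_sd = float(fx.get("cg_sd", np.sqrt(max(vc.get("cg", 0.0), 0.0))))
    cg_eff = dict(zip(cg_levels, rng.normal(0.0, cg_sd, len(cg_levels))))
    y = (eff + a[ai] + cg_keys.map(cg_eff).to_numpy()
         + rng.normal(0.0, np.sqrt(vc["residual"]), n))
    out = skeleton.copy()
    out["weight"] = y
    return out


def discretize_scores(y: np.ndarray,
                      proportions=(0.909, 0.075, 0.013, 0.003)) -> np.ndarray:
    """Optional 1-4 discretisation of continuous scores at the empirical
    quantiles matching the national category proportions (robustness
    experiments only; the association models treat the score linearly)."""
    props = np.asarray(proportions, dtype=float)
    props = props / props.sum()
    cuts = np.quantile(y, np.cumsum(props)[:-1])
    return np.digitize(y, cuts) + 1
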