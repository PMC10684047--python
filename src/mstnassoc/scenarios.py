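"""Study designs for the simulation experiments.

A *design* is everything about a simulated study that does not depend on
the genotype or phenotype draw: the multi-herd pedigree, breed
compositions, herd/date structure, record edits and contemporary groups,
covariates, and the model specification.  Parameter-recovery experiments
share one design across replicates and redraw genotypes, genetic effects
and noise per replicate; inference is conditional on the design.

The calving design mirrors a seasonal-calving Irish suckler/dairy mix:
40 herds, three generations (founder dams and sires, replacement dams,
recorded calves), herd sire teams plus a handful of AI sires used across
herds, 2-5 parities per dam, three seasonal calving blocks per herd-year.
The Belgian Blue founder share is enriched so that homozygous nt821 dams
and calves are common enough for their effects to be estimable.

The carcass design is a two-generation progeny structure with slaughter
batches forming herd-year-sex groups.  For a focal variant, founder sires
are guaranteed carriers (a classic carrier-sire progeny design): at the
survey's population frequencies, homozygous Q204X animals would be a
handful per 10,000 and the homozygote effect would not be measurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import (assign_calving_contemporary_groups,
                      assign_carcass_contemporary_groups, edit_calving_records,
                      edit_carcass_records)
from .covariates import age_sex_class, parity_age_class
from .mixed_model import FixedTerm, MixedModel, ModelSpec, RandomTerm
from .pedigree import Pedigree
from .simulate import (SimulationConfig, rng_for, simulate_calving_phenotypes,
                       simulate_carcass_phenotypes, simulate_genotypes,
                       genotype_counts)
from .variants import default_founder_pools

CALVING_BREED_WEIGHTS = {"BB": 0.25, "CH": 0.15, "LM": 0.15, "AA": 0.15,
                         "HE": 0.10, "HO": 0.10, "SI": 0.05, "FR": 0.05}
CARCASS_BREED_WEIGHTS = {"CH": 0.30, "LM": 0.30, "AA": 0.15, "HE": 0.10,
                         "BB": 0.05, "SI": 0.05, "HO": 0.05}


def calving_recovery_config(seed: int, interaction: bool = False) -> SimulationConfig:
    """True parameters of the calving parameter-recovery study.

    Genotype effects are the published single-locus nt821 estimates used as
    simulation truth; variance components are realistic for a linearly
    analysed 1-4 calving score.
    """
    cfg = SimulationConfig(
        breed_labels=list(CALVING_BREED_WEIGHTS),
        founder_haplotype_pools=default_founder_pools(),
        n_herds=40,
        variance_components={"cg": 0.02, "direct": 0.04, "maternal": 0.02,
                             "pe": 0.01, "residual": 0.30},
        fixed_effects={
            "intercept": 1.10,
            "sex": {"M": 0.15, "F": 0.0},
            "parity": {1: 0.25, 2: 0.05},
            "covariates": {
                "het_a": -0.10, "het_d": -0.05, "rec_a": 0.05, "rec_d": 0.02,
                "calf_fr_BB": 0.15, "calf_fr_CH": 0.10, "calf_fr_LM": 0.08,
                "calf_fr_HE": 0.02, "calf_fr_HO": -0.05, "calf_fr_SI": 0.05,
                "calf_fr_FR": -0.02,
                "dam_fr_BB": 0.08, "dam_fr_CH": 0.05, "dam_fr_LM": 0.04,
                "dam_fr_HO": -0.03,
            },
        },
        genotype_effects={"nt821": {"calf": {1: 0.13, 2: 0.37},
                                    "dam": {1: 0.05, 2: 1.30}}},
        interaction_effects={("nt821", 2, 2): 0.91} if interaction else {},
        seed=seed,
    )
    return cfg


def carcass_recovery_config(seed: int, variant: str = "Q204X") -> SimulationConfig:
    """True parameters of the carcass-weight recovery study for one focal
    variant (Q204X +23.2 kg or nt821 +15.56 kg for the homozygote, with
    plausible heterozygote effects)."""
    effects = {"Q204X": {"calf": {1: 10.0, 2: 23.2}},
               "nt821": {"calf": {1: 7.0, 2: 15.56}}}
    return SimulationConfig(
        breed_labels=list(CARCASS_BREED_WEIGHTS),
        founder_haplotype_pools=default_founder_pools(),
        n_herds=40,
        variance_components={"cg": 400.0, "direct": 900.0, "maternal": 0.0,
                             "pe": 0.0, "residual": 1600.0},
        fixed_effects={
            "intercept": 320.0,
            "sex_class": {"steer": 0.0, "heifer": -25.0, "young_bull": 10.0},
            "age_slope": 2.5,
            "parity": {1: -8.0},
            "cg_sd": 20.0,
            "covariates": {
                "het_a": 4.0, "rec_a": -2.0,
                "fr_CH": 25.0, "fr_LM": 20.0, "fr_BB": 30.0, "fr_HE": -5.0,
                "fr_HO": -30.0, "fr_SI": 15.0,
            },
        },
        genotype_effects={variant: effects[variant]},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _draw_breeds(rng, weights: dict, n: int) -> list:
    breeds = list(weights)
    p = np.array([weights[b] for b in breeds], dtype=float)
    p = p / p.sum()
    return [breeds[i] for i in rng.choice(len(breeds), size=n, p=p)]


def _breed_composition(ped: Pedigree, founder_breeds: pd.Series,
                       breeds: list) -> pd.DataFrame:
    """Founders are purebred; every descendant is the parental average."""
    comp = np.zeros((len(ped), len(breeds)))
    bidx = {b: j for j, b in enumerate(breeds)}
    for i in range(len(ped)):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            comp[i, bidx[founder_breeds[ped.ids[i]]]] = 1.0
        else:
            comp[i] = 0.5 * comp[s] + 0.5 * comp[d]
    return pd.DataFrame(comp, index=ped.ids, columns=breeds)


def _het_rec(comp: pd.DataFrame, sires: pd.Series, dams: pd.Series):
    sc = comp.reindex(sires).to_numpy()
    dc = comp.reindex(dams).to_numpy()
    het = 1.0 - np.sum(sc * dc, axis=1)
    rec = 1.0 - 0.5 * (np.sum(sc ** 2, axis=1) + np.sum(dc ** 2, axis=1))
    return het, rec


def _pick_sire(rng, dam_breed, herd_sires, sire_breeds, ai_sires, ai_breeds,
               p_ai=0.3, p_same_breed=0.5):
    """Service sire choice: AI with probability p_ai, else the herd team;
    with probability p_same_breed prefer a sire matching the dam's breed."""
    pool, pool_b = (ai_sires, ai_breeds) if rng.random() < p_ai else (herd_sires, sire_breeds)
    if rng.random() < p_same_breed:
        match = [s for s, b in zip(pool, pool_b) if b == dam_breed]
        if match:
            return match[int(rng.integers(len(match)))]
    return pool[int(rng.integers(len(pool)))]


# ---------------------------------------------------------------------------
# calving design
# ---------------------------------------------------------------------------

@dataclass
class CalvingDesign:
    pedigree: Pedigree
    founder_breeds: pd.Series
    breed_composition: pd.DataFrame
    records: pd.DataFrame          # edited records with cg_id and covariates
    parity_medians: dict
    breeds: list
    spec: ModelSpec
    spec_interaction: ModelSpec
    n_groups: int


def build_calving_design(config: SimulationConfig,
                         dams_per_herd: int = 75,
                         g0_dams_per_herd: int = 25,
                         g0_sires_per_herd: int = 3,
                         service_sires_per_herd: int = 5,
                         n_ai_sires: int = 10,
                         first_year: int = 2015) -> CalvingDesign:
    rng = rng_for(config.seed, "calving-design")
    weights = {b: CALVING_BREED_WEIGHTS.get(b, 0.0) for b in config.breed_labels}
    H = config.n_herds

    rows, fbreeds = [], {}

    def founder(aid, sex, breed, year=2008):
        rows.append({"animal": aid, "sire": None, "dam": None,
                     "birth_date": pd.Timestamp(f"{year}-03-01"),
                     "sex": sex, "breed": breed})
        fbreeds[aid] = breed

    ai_sires = [f"AI{k:03d}" for k in range(n_ai_sires)]
    ai_breeds = _draw_breeds(rng, weights, n_ai_sires)
    for a, b in zip(ai_sires, ai_breeds):
        founder(a, "M", b)

    # pre-founder layer: purebred great-granddams and ancestral sires, so
    # foundation dams are themselves crossbred and the heterosis /
    # recombination covariates span their full range
    anc_sires = [f"AS{k:02d}" for k in range(6)]
    anc_breeds = _draw_breeds(rng, weights, len(anc_sires))
    for a, b in zip(anc_sires, anc_breeds):
        founder(a, "M", b, year=2004)

    herd_info = {}
    g0_parents: dict = {}
    for h in range(H):
        pre = [f"H{h:02d}P{k:02d}" for k in range(10)]
        for a, b in zip(pre, _draw_breeds(rng, weights, len(pre))):
            founder(a, "F", b, year=2004)
        g0d = [f"H{h:02d}D{k:03d}" for k in range(g0_dams_per_herd)]
        for a in g0d:
            s = anc_sires[int(rng.integers(len(anc_sires)))]
            d = pre[int(rng.integers(len(pre)))]
            rows.append({"animal": a, "sire": s, "dam": d,
                         "birth_date": pd.Timestamp("2008-03-01"),
                         "sex": "F", "breed": None})
            g0_parents[a] = (s, d)
        g0s = [f"H{h:02d}S{k}" for k in range(g0_sires_per_herd)]
        sb = [f"H{h:02d}B{k}" for k in range(service_sires_per_herd)]
        for a, b in zip(g0s, _draw_breeds(rng, weights, len(g0s))):
            founder(a, "M", b)
        for a, b in zip(sb, _draw_breeds(rng, weights, len(sb))):
            founder(a, "M", b, year=2012)
        # one crossbred (F1) bull per team: with exclusively purebred sires
        # the recombination covariates would be exact linear combinations of
        # the heterosis covariates
        for tag, team in (("SX", g0s), ("BX", sb)):
            a = f"H{h:02d}{tag}"
            rows.append({"animal": a, "sire": anc_sires[int(rng.integers(len(anc_sires)))],
                         "dam": pre[int(rng.integers(len(pre)))],
                         "birth_date": pd.Timestamp("2008-03-01"),
                         "sex": "M", "breed": None})
            g0_parents[a] = (rows[-1]["sire"], rows[-1]["dam"])
            team.append(a)
        herd_info[h] = (g0d, g0s, sb)

    # breed hints steer assortative mating for crossbred animals
    hint = dict(fbreeds)
    for a, (s, d) in g0_parents.items():
        hint[a] = hint[d] if rng.random() < 0.5 else hint[s]

    # replacement dams (G1)
    g1 = {}
    for h in range(H):
        g0d, g0s, _ = herd_info[h]
        dams = []
        for k in range(dams_per_herd):
            aid = f"H{h:02d}W{k:03d}"
            mother = g0d[int(rng.integers(len(g0d)))]
            father = _pick_sire(rng, hint[mother], g0s,
                                [hint[s] for s in g0s], ai_sires, ai_breeds)
            rows.append({"animal": aid, "sire": father, "dam": mother,
                         "birth_date": pd.Timestamp("2012-02-15"),
                         "sex": "F", "breed": None})
            hint[aid] = hint[mother] if rng.random() < 0.5 else hint[father]
            dams.append(aid)
        g1[h] = dams

    # calvings (G2 calves)
    season_day = {0: 45, 1: 165, 2: 285}
    recs = []
    calf_id = 0
    for h in range(H):
        _, _, sb = herd_info[h]
        sb_breeds = [hint[s] for s in sb]
        for dam in g1[h]:
            n_par = int(rng.integers(2, 6))
            fpa = float(rng.uniform(680, 840))
            y0 = first_year + int(rng.integers(0, 2))
            season = int(rng.integers(0, 3))
            for p in range(1, n_par + 1):
                calf_id += 1
                calf = f"C{calf_id:06d}"
                sire = _pick_sire(rng, None, sb, sb_breeds, ai_sires, ai_breeds,
                                  p_same_breed=0.0)
                year = y0 + (p - 1)
                day = season_day[season] + int(rng.integers(0, 13))
                date = pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=day - 1)
                age = fpa + 365.0 * (p - 1) + float(rng.normal(0, 20))
                rows.append({"animal": calf, "sire": sire, "dam": dam,
                             "birth_date": date, "sex": "M" if rng.random() < 0.5 else "F",
                             "breed": None})
                recs.append({"calf": calf, "dam": dam, "sire": sire, "herd": h,
                             "date": date, "parity": p, "age_days": age,
                             "cg_true": f"{h}:{year}:{season}",
                             "sex": rows[-1]["sex"],
                             "twin": rng.random() < 0.01,
                             "embryo_transfer": rng.random() < 0.005,
                             "breed_society": rng.random() < 0.01,
                             "genotyped_pair": True})

    ped_frame = pd.DataFrame(rows)
    ped = Pedigree.from_frame(ped_frame)
    founder_breeds = pd.Series(fbreeds)
    breeds = list(config.breed_labels)
    comp = _breed_composition(ped, founder_breeds, breeds)

    records = pd.DataFrame(recs)
    # structural edit pass; a placeholder continuous score exercises the
    # variability rule without ever triggering it
    records["score"] = rng.standard_normal(len(records))
    edited, audits = edit_calving_records(records)
    cg, groups = assign_calving_contemporary_groups(edited)
    edited = edited.assign(cg_id=cg).dropna(subset=["cg_id"]).drop(columns="score")

    med = edited.groupby("parity")["age_days"].median().to_dict()
    edited["parity_age"] = [
        parity_age_class(int(p), a, med)
        for p, a in zip(edited["parity"], edited["age_days"])]

    sire_of = dict(zip(ped_frame["animal"], ped_frame["sire"]))
    dam_of = dict(zip(ped_frame["animal"], ped_frame["dam"]))
    het_a, rec_a = _het_rec(comp, edited["sire"], edited["dam"])
    dam_sires = edited["dam"].map(sire_of)
    dam_dams = edited["dam"].map(dam_of)
    het_d, rec_d = _het_rec(comp, dam_sires, dam_dams)
    edited["het_a"], edited["rec_a"] = het_a, rec_a
    edited["het_d"], edited["rec_d"] = het_d, rec_d
    ref_breed = breeds[0]
    for b in breeds:
        if b == ref_breed:
            continue
        edited[f"calf_fr_{b}"] = comp[b].reindex(edited["calf"]).to_numpy()
        edited[f"dam_fr_{b}"] = comp[b].reindex(edited["dam"]).to_numpy()
    # keep reference-breed fractions available for phenotype simulation
    edited[f"calf_fr_{ref_breed}"] = comp[ref_breed].reindex(edited["calf"]).to_numpy()
    edited[f"dam_fr_{ref_breed}"] = comp[ref_breed].reindex(edited["dam"]).to_numpy()
    edited = edited.reset_index(drop=True)

    fr_terms = [FixedTerm(f"calf_fr_{b}", "covariate") for b in breeds if b != ref_breed]
    fr_terms += [FixedTerm(f"dam_fr_{b}", "covariate") for b in breeds if b != ref_breed]
    fixed = ([FixedTerm("sex", "class"),
              FixedTerm("het_a", "covariate"), FixedTerm("het_d", "covariate"),
              FixedTerm("rec_a", "covariate"), FixedTerm("rec_d", "covariate"),
              FixedTerm("parity_age", "class")] + fr_terms +
             [FixedTerm("calf_geno", "class", reference="0"),
              FixedTerm("dam_geno", "class", reference="0")])
    random = [RandomTerm("cg", "cg_id", "iid"),
              RandomTerm("animal", "calf", "pedigree"),
              RandomTerm("maternal", "dam", "pedigree"),
              RandomTerm("pe", "dam", "iid")]
    spec = ModelSpec("score", fixed, random)
    # deviation-coded interaction: cells with either genotype at zero copies
    # collapse into the reference, so each remaining dummy is directly the
    # deviation of that dam-calf combination from additivity
    spec_int = ModelSpec(
        "score",
        fixed + [FixedTerm("dam_calf_geno", "class", reference="0",
                           levels=("2|2", "2|1", "1|2", "1|1"))],
        random)
    return CalvingDesign(ped, founder_breeds, comp, edited, med, breeds,
                         spec, spec_int, n_groups=len(groups))


def simulate_calving_replicate(design: CalvingDesign, config: SimulationConfig,
                               rng: np.random.Generator,
                               focal: str = "nt821") -> tuple[pd.DataFrame, object]:
    """One replicate: redraw genotypes and phenotypes on the fixed design.

    Returns the model-ready data frame (score, genotype class columns,
    covariates, cg_id) and the phased haplotypes.
    """
    haps = simulate_genotypes(design.pedigree, design.founder_breeds,
                              config.founder_haplotype_pools, rng)
    cov_eff = config.fixed_effects.get("covariates", {})
    out = simulate_calving_phenotypes(design.pedigree, haps, design.records,
                                      config, rng, covariate_effects=cov_eff)
    gc = genotype_counts(haps, focal)
    out["calf_geno"] = gc.reindex(out["calf"]).astype(int).astype(str).to_numpy()
    out["dam_geno"] = gc.reindex(out["dam"]).astype(int).astype(str).to_numpy()
    zero = (out["calf_geno"] == "0") | (out["dam_geno"] == "0")
    out["dam_calf_geno"] = np.where(zero, "0",
                                    out["dam_geno"] + "|" + out["calf_geno"])
    return out, haps


# ---------------------------------------------------------------------------
# carcass design
# ---------------------------------------------------------------------------

@dataclass
class CarcassDesign:
    pedigree: Pedigree
    founder_breeds: pd.Series
    breed_composition: pd.DataFrame
    records: pd.DataFrame
    breeds: list
    spec: ModelSpec
    sires: list
    n_groups: int


def build_carcass_design(config: SimulationConfig,
                         dams_per_herd: int = 70,
                         offspring_per_dam: tuple = (3, 5),
                         service_sires_per_herd: int = 5,
                         n_ai_sires: int = 10,
                         first_year: int = 2016) -> CarcassDesign:
    rng = rng_for(config.seed, "carcass-design")
    weights = {b: CARCASS_BREED_WEIGHTS.get(b, 0.0) for b in config.breed_labels}
    H = config.n_herds
    rows, fbreeds = [], {}

    def founder(aid, sex, breed):
        rows.append({"animal": aid, "sire": None, "dam": None,
                     "birth_date": pd.Timestamp("2012-03-01"),
                     "sex": sex, "breed": breed})
        fbreeds[aid] = breed

    ai = [f"AI{k:03d}" for k in range(n_ai_sires)]
    ai_b = _draw_breeds(rng, weights, n_ai_sires)
    for a, b in zip(ai, ai_b):
        founder(a, "M", b)
    anc = [f"AS{k:02d}" for k in range(6)]
    for a, b in zip(anc, _draw_breeds(rng, weights, len(anc))):
        founder(a, "M", b)
    all_sires = list(ai)
    recs = []
    aid_n = 0
    sex_windows = {"steer": (24, 32), "heifer": (20, 30), "young_bull": (14, 22)}
    hint = dict(fbreeds)
    for h in range(H):
        # purebred granddams, crossbred production dams
        pre = [f"H{h:02d}P{k:02d}" for k in range(8)]
        for a, b in zip(pre, _draw_breeds(rng, weights, len(pre))):
            founder(a, "F", b)
        dams = [f"H{h:02d}D{k:03d}" for k in range(dams_per_herd)]
        for a in dams:
            s = anc[int(rng.integers(len(anc)))]
            d = pre[int(rng.integers(len(pre)))]
            rows.append({"animal": a, "sire": s, "dam": d,
                         "birth_date": pd.Timestamp("2013-03-01"),
                         "sex": "F", "breed": None})
            hint[a] = fbreeds[d] if rng.random() < 0.5 else fbreeds[s]
        sb = [f"H{h:02d}B{k}" for k in range(service_sires_per_herd)]
        for a, b in zip(sb, _draw_breeds(rng, weights, len(sb))):
            founder(a, "M", b)
        all_sires += sb
        sb_b = [fbreeds[s] for s in sb]
        for dam in dams:
            n_off = int(rng.integers(*offspring_per_dam))
            for k in range(n_off):
                aid_n += 1
                animal = f"X{aid_n:06d}"
                sire = _pick_sire(rng, hint[dam], sb, sb_b, ai, ai_b,
                                  p_ai=0.3, p_same_breed=0.6)
                sex = rng.choice(["steer", "heifer", "young_bull"], p=[0.4, 0.4, 0.2])
                year = first_year + int(rng.integers(0, 2))
                batch = int(rng.integers(0, 2))
                s_day = 60 + 180 * batch + int(rng.integers(0, 21))
                sdate = pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=s_day)
                lo, hi = sex_windows[sex]
                age_mo = int(rng.integers(lo, hi + 1))
                if rng.random() < 0.01:  # occasional out-of-window slaughter
                    age_mo = hi + 2
                rows.append({"animal": animal, "sire": sire, "dam": dam,
                             "birth_date": sdate - pd.Timedelta(days=int(age_mo * 30.44)),
                             "sex": "M" if sex != "heifer" else "F", "breed": None})
                recs.append({"animal": animal, "sire": sire, "dam": dam, "herd": h,
                             "slaughter_date": sdate, "sex_class": sex,
                             "age_months": age_mo,
                             "cg_true": f"{h}:{year}:{sex}:{batch}",
                             "dam_parity": k + 1,
                             "embryo_transfer": rng.random() < 0.005,
                             "n_lifetime_herds": 1 + (rng.random() < 0.1),
                             "days_since_herd_move": (
                                 float(rng.integers(0, 300)) if rng.random() < 0.03 else np.nan),
                             "breed_society": rng.random() < 0.01,
                             "weight": 350.0})  # placeholder inside the edit bounds

    ped_frame = pd.DataFrame(rows)
    ped = Pedigree.from_frame(ped_frame)
    founder_breeds = pd.Series(fbreeds)
    breeds = list(config.breed_labels)
    comp = _breed_composition(ped, founder_breeds, breeds)

    records = pd.DataFrame(recs)
    edited, audits = edit_carcass_records(records)
    genotyped = pd.Series(True, index=edited.index)
    cg, groups = assign_carcass_contemporary_groups(edited, genotyped)
    edited = edited.assign(cg_id=cg).dropna(subset=["cg_id"]).drop(columns="weight")
    edited["age_sex"] = [age_sex_class(a, s) for a, s in
                         zip(edited["age_months"], edited["sex_class"])]
    het_a, rec_a = _het_rec(comp, edited["sire"], edited["dam"])
    edited["het_a"], edited["rec_a"] = het_a, rec_a
    ref_breed = breeds[0]
    for b in breeds:
        edited[f"fr_{b}"] = comp[b].reindex(edited["animal"]).to_numpy()
    edited = edited.reset_index(drop=True)

    fixed = ([FixedTerm("cg_id", "class"),
              FixedTerm("age_sex", "class"),
              FixedTerm("dam_parity", "class"),
              FixedTerm("het_a", "covariate"), FixedTerm("rec_a", "covariate")] +
             [FixedTerm(f"fr_{b}", "covariate") for b in breeds if b != ref_breed] +
             [FixedTerm("calf_geno", "class", reference="0")])
    spec = ModelSpec("weight", fixed, [RandomTerm("animal", "animal", "pedigree")])
    return CarcassDesign(ped, founder_breeds, comp, edited, breeds, spec,
                         sires=all_sires, n_groups=len(groups))


def simulate_carcass_replicate(design: CarcassDesign, config: SimulationConfig,
                               rng: np.random.Generator,
                               focal: str = "Q204X",
                               carrier_sires: bool = True) -> tuple[pd.DataFrame, object]:
    haps = simulate_genotypes(
        design.pedigree, design.founder_breeds, config.founder_haplotype_pools,
        rng, carrier_founders=(design.sires, focal) if carrier_sires else None)
    cov_eff = config.fixed_effects.get("covariates", {})
    out = simulate_carcass_phenotypes(design.pedigree, haps, design.records,
                                      config, rng, covariate_effects=cov_eff)
    gc = genotype_counts(haps, focal)
    out["calf_geno"] = gc.reindex(out["animal"]).astype(int).astype(str).to_numpy()
    return out, haps


# ---------------------------------------------------------------------------
# null-calibration design (type-I error of the genotype F-test)
# ---------------------------------------------------------------------------

@dataclass
class NullDesign:
    design: CarcassDesign
    config: SimulationConfig
    haps: object
    data: pd.DataFrame
    model: MixedModel
    term: str


def build_null_design(seed: int, n_herds: int = 20,
                      animals_per_herd: int = 100) -> NullDesign:
    """Small animal-model design with a genotype class term whose true
    effect is zero.  The design (incl. the genotype draw) is fixed; null
    replicates redraw the phenotype only, which is exactly the conditional
    sampling model under which the F-test claims its size."""
    cfg = carcass_recovery_config(seed, "Q204X")
    cfg = SimulationConfig(**{**cfg.__dict__, "n_herds": n_herds,
                              "genotype_effects": {}, "seed": seed})
    design = build_carcass_design(cfg, dams_per_herd=max(10, animals_per_herd // 4),
                                  offspring_per_dam=(3, 6),
                                  service_sires_per_herd=3, n_ai_sires=5)
    rng = rng_for(seed, "null-genotypes")
    data, haps = simulate_carcass_replicate(design, cfg, rng, focal="nt374_51",
                                            carrier_sires=False)
    model = MixedModel(design.spec, data, pedigree=design.pedigree)
    return NullDesign(design=design, config=cfg, haps=haps, data=data,
                      model=model, term="calf_geno")


def simulate_null_response(nd: NullDesign, rng: np.random.Generator) -> np.ndarray:
    """Fresh phenotype draw with zero genotype effect on the null design."""
    cov_eff = nd.config.fixed_effects.get("covariates", {})
    out = simulate_carcass_phenotypes(nd.design.pedigree, nd.haps,
                                      nd.design.records, nd.config, rng,
                                      covariate_effects=cov_eff)
    return out["weight"].to_numpy()
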