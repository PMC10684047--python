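"""Synthetic-data generator: Mendelian transmission, genetic covariance,
phenotype construction and determinism."""

import numpy as np
import pandas as pd
import pytest

from mstnassoc.pedigree import Pedigree, build_A
from mstnassoc.simulate import (SimulationConfig, discretize_scores,
                                genotype_counts, rng_for,
                                sample_breeding_values,
                                simulate_calving_phenotypes,
                                simulate_genotypes, simulate_pedigree)
from mstnassoc.variants import SEGREGATING_VARIANTS


def config(**kw):
    base = dict(n_founders=10, n_generations=2, breed_labels=["AA", "BB"],
                founder_haplotype_pools={
                    "AA": [("hap01", 1.0)],
                    "BB": [("hap04", 0.6), ("hap01", 0.4)]},
                seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            SimulationConfig(seed=None)

    def test_pool_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            config(founder_haplotype_pools={"AA": [("hap01", 0.9)]})

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            config(variance_components={"cg": -0.1, "residual": 1.0})

    def test_yaml_round_trip(self, tmp_path):
        cfg = config(interaction_effects={("nt821", 2, 2): 0.91})
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = SimulationConfig.from_yaml(p)
        assert back.founder_haplotype_pools.keys() == cfg.founder_haplotype_pools.keys()
        assert back.interaction_effects == {("nt821", 2, 2): 0.91}


class TestSimulatePedigree:
    def test_two_founders_only_possible_mating(self):
        ped = simulate_pedigree(config(n_founders=2, n_generations=1))
        founders = ped[ped["sire"].isna()]
        offspring = ped[ped["sire"].notna()]
        assert len(founders) == 2
        assert (offspring["sire"] == founders.iloc[0]["animal"]).all()
        assert (offspring["dam"] == founders.iloc[1]["animal"]).all()

    def test_acyclic_by_construction(self):
        frame = simulate_pedigree(config(n_founders=30, n_generations=3))
        Pedigree.from_frame(frame)  # topological sort succeeds

    def test_deterministic_for_fixed_seed(self):
        c = config(n_founders=100, n_generations=3)
        assert simulate_pedigree(c).equals(simulate_pedigree(c))

    def test_single_founder_rejected(self):
        with pytest.raises(ValueError, match="two founders"):
            simulate_pedigree(config(n_founders=1))


@pytest.fixture
def small_population():
    cfg = config(n_founders=40, n_generations=2)
    frame = simulate_pedigree(cfg)
    ped = Pedigree.from_frame(frame)
    breeds = frame.set_index("animal")["breed"].dropna()
    return cfg, ped, breeds


class TestSimulateGenotypes:
    def test_wildtype_pool_gives_all_zero(self, small_population):
        cfg, ped, breeds = small_population
        pools = {"AA": [("hap01", 1.0)], "BB": [("hap01", 1.0)]}
        haps = simulate_genotypes(ped, breeds, pools, rng_for(1, "g"))
        assert (haps.genotype_table().to_numpy() == 0).all()

    def test_mendelian_certainty_cross(self):
        frame = pd.DataFrame({
            "animal": ["S", "D"] + [f"k{i}" for i in range(20)],
            "sire": [None, None] + ["S"] * 20,
            "dam": [None, None] + ["D"] * 20,
            "breed": ["MUT", "WT"] + [None] * 20})
        ped = Pedigree.from_frame(frame)
        pools = {"MUT": [("hap04", 1.0)], "WT": [("hap01", 1.0)]}
        breeds = frame.set_index("animal")["breed"].dropna()
        haps = simulate_genotypes(ped, breeds, pools, rng_for(2, "g"))
        copies = genotype_counts(haps, "nt821")
        assert (copies[[f"k{i}" for i in range(20)]] == 1).all()

    def test_transmission_conserves_parental_haplotypes(self, small_population):
        cfg, ped, breeds = small_population
        haps = simulate_genotypes(ped, breeds, cfg.founder_haplotype_pools,
                                  rng_for(3, "g"))
        for i in range(len(ped)):
            s, d = ped.sire[i], ped.dam[i]
            if s < 0:
                continue
            assert ((haps.paternal[i] == haps.paternal[s]).all()
                    or (haps.paternal[i] == haps.maternal[s]).all())
            assert ((haps.maternal[i] == haps.paternal[d]).all()
                    or (haps.maternal[i] == haps.maternal[d]).all())

    def test_founder_frequency_binomial(self):
        n = 3000
        frame = pd.DataFrame({"animal": [f"f{i}" for i in range(n)],
                              "sire": None, "dam": None, "breed": "BB"})
        ped = Pedigree.from_frame(frame)
        breeds = frame.set_index("animal")["breed"]
        p = 0.6
        pools = {"BB": [("hap04", p), ("hap01", 1 - p)]}
        haps = simulate_genotypes(ped, breeds, pools, rng_for(4, "g"))
        freq = genotype_counts(haps, "nt821").sum() / (2 * n)
        assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / (2 * n))

    def test_genotype_table_consistent_with_haplotypes(self, small_population):
        cfg, ped, breeds = small_population
        haps = simulate_genotypes(ped, breeds, cfg.founder_haplotype_pools,
                                  rng_for(5, "g"))
        g = haps.genotype_table()
        assert (g.to_numpy() == haps.paternal + haps.maternal).all()

    def test_missing_pool_rejected(self, small_population):
        cfg, ped, breeds = small_population
        with pytest.raises(ValueError, match="no haplotype pool"):
            simulate_genotypes(ped, breeds, {"AA": [("hap01", 1.0)]},
                               rng_for(6, "g"))

    def test_carrier_founders_forced(self, small_population):
        cfg, ped, breeds = small_population
        founders = list(breeds.index)
        haps = simulate_genotypes(ped, breeds, cfg.founder_haplotype_pools,
                                  rng_for(7, "g"),
                                  carrier_founders=(founders, "nt821"))
        copies = genotype_counts(haps, "nt821")
        assert (copies[founders] >= 1).all()


class TestBreedingValues:
    def test_covariance_matches_A(self, small_population):
        _, ped, _ = small_population
        A = build_A(ped).values
        sigma2 = 2.5
        rng = np.random.default_rng(0)
        draws = np.array([sample_breeding_values(ped, sigma2, rng)
                          for _ in range(4000)])
        emp_var = draws.var(axis=0, ddof=0)
        assert np.allclose(emp_var, sigma2 * np.diag(A), rtol=0.12)
        # one off-diagonal check: parent-offspring covariance
        i = next(k for k in range(len(ped)) if ped.sire[k] >= 0)
        s = ped.sire[i]
        emp_cov = np.cov(draws[:, i], draws[:, s], ddof=0)[0, 1]
        assert emp_cov == pytest.approx(sigma2 * A[i, s], abs=0.2)


class TestCalvingPhenotypes:
    def _skeleton(self, ped, n=60):
        rng = np.random.default_rng(8)
        calves = [a for k, a in enumerate(ped.ids) if ped.sire[k] >= 0]
        calves = calves[:n]
        dams = [ped.ids[ped.dam[ped.indices_of([c])[0]]] for c in calves]
        return pd.DataFrame({
            "calf": calves, "dam": dams, "herd": 1,
            "date": pd.Timestamp("2018-03-01"), "parity": 2,
            "age_days": 1100.0, "sex": rng.choice(["M", "F"], len(calves)),
            "cg_true": "1:2018:0"})

    def test_degenerate_model_constant(self, small_population):
        cfg, ped, breeds = small_population
        haps = simulate_genotypes(ped, breeds, cfg.founder_haplotype_pools,
                                  rng_for(9, "g"))
        cfg0 = config(variance_components={"cg": 0, "direct": 0, "maternal": 0,
                                           "pe": 0, "residual": 0},
                      fixed_effects={"intercept": 1.5})
        out = simulate_calving_phenotypes(ped, haps, self._skeleton(ped), cfg0,
                                          rng_for(9, "p"))
        assert np.allclose(out["score"], 1.5)

    def test_pure_genotype_effect_exact_group_difference(self, small_population):
        cfg, ped, breeds = small_population
        haps = simulate_genotypes(ped, breeds, cfg.founder_haplotype_pools,
                                  rng_for(10, "g"))
        cfg1 = config(variance_components={"cg": 0, "direct": 0, "maternal": 0,
                                           "pe": 0, "residual": 0},
                      genotype_effects={"nt821": {"calf": {1: 0.13, 2: 0.37}}})
        out = simulate_calving_phenotypes(ped, haps, self._skeleton(ped), cfg1,
                                          rng_for(10, "p"))
        copies = genotype_counts(haps, "nt821").reindex(out["calf"]).to_numpy()
        if (copies == 2).any() and (copies == 0).any():
            diff = out.loc[copies == 2, "score"].mean() - \
                out.loc[copies == 0, "score"].mean()
            assert diff == pytest.approx(0.37)

    def test_interaction_deviation_added(self, small_population):
        cfg, ped, breeds = small_population
        haps = simulate_genotypes(ped, breeds, cfg.founder_haplotype_pools,
                                  rng_for(11, "g"))
        base = config(variance_components={"cg": 0, "direct": 0, "maternal": 0,
                                           "pe": 0, "residual": 0},
                      genotype_effects={"nt821": {"calf": {2: 0.37},
                                                  "dam": {2: 1.30}}})
        plus = config(variance_components=base.variance_components,
                      genotype_effects=base.genotype_effects,
                      interaction_effects={("nt821", 2, 2): 0.91})
        sk = self._skeleton(ped)
        y0 = simulate_calving_phenotypes(ped, haps, sk, base, rng_for(11, "p"))
        y1 = simulate_calving_phenotypes(ped, haps, sk, plus, rng_for(11, "p"))
        copies = genotype_counts(haps, "nt821")
        cc = copies.reindex(sk["calf"]).to_numpy()
        dc = copies.reindex(sk["dam"]).to_numpy()
        dev = (y1["score"] - y0["score"]).to_numpy()
        assert np.allclose(dev[(cc == 2) & (dc == 2)], 0.91)
        assert np.allclose(dev[~((cc == 2) & (dc == 2))], 0.0)

    def test_environment_only_variance(self, small_population):
        cfg, ped, breeds = small_population
        haps = simulate_genotypes(ped, breeds, cfg.founder_haplotype_pools,
                                  rng_for(12, "g"))
        vc = {"cg": 0.3, "direct": 0.0, "maternal": 0.0, "pe": 0.0,
              "residual": 0.7}
        sk = self._skeleton(ped)
        rng = np.random.default_rng(13)
        # many cg_true levels so the cg variance is visible
        sk = sk.assign(cg_true=[f"g{i % 30}" for i in range(len(sk))])
        ys = []
        for r in range(300):
            cfgv = config(variance_components=vc)
            out = simulate_calving_phenotypes(ped, haps, sk, cfgv,
                                              np.random.default_rng(rng.integers(2**31)))
            ys.append(out["score"].to_numpy())
        v = np.concatenate([y - y.mean() for y in ys]).var()
        assert v == pytest.approx(1.0, rel=0.1)


class TestDiscretize:
    def test_category_proportions(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 100_000)
        s = discretize_scores(y)
        props = np.bincount(s, minlength=5)[1:] / len(s)
        assert np.allclose(props, [0.909, 0.075, 0.013, 0.003], atol=0.002)
        assert set(np.unique(s)) <= {1, 2, 3, 4}


def test_full_replicate_deterministic():
    from mstnassoc.scenarios import (calving_recovery_config,
                                     build_calving_design,
                                     simulate_calving_replicate)
    cfg = calving_recovery_config(seed=3)
    d1 = build_calving_design(cfg, dams_per_herd=10, g0_dams_per_herd=5)
    d2 = build_calving_design(cfg, dams_per_herd=10, g0_dams_per_herd=5)
    r1, _ = simulate_calving_replicate(d1, cfg, rng_for(3, "x"))
    r2, _ = simulate_calving_replicate(d2, cfg, rng_for(3, "x"))
    pd.testing.assert_frame_equal(r1, r2)
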