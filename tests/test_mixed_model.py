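"""Mixed-model equations against a dense GLS oracle, closed-form REML,
and the estimability/inference machinery."""

import numpy as np
import pandas as pd
import pytest

from mstnassoc.mixed_model import (NE, ConvergenceError, FixedTerm,
                                   MixedModel, ModelSpec, RandomTerm)
from mstnassoc.pedigree import build_A

from conftest import random_pedigree


def make_data(n=60, seed=1, ped=None, n_groups=3):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame({
        "y": rng.standard_normal(n),
        "grp": rng.choice([f"g{i}" for i in range(n_groups)], n),
        "x": rng.standard_normal(n),
        "cls": rng.choice(["u", "v", "w"], n),
    })
    if ped is not None:
        nonfounders = [a for k, a in enumerate(ped.ids) if ped.sire[k] >= 0]
        data["animal"] = rng.choice(nonfounders, n)
    return data


def dense_gls(X, V, y):
    Vi = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vi @ X)
    return C @ (X.T @ Vi @ y), C


@pytest.fixture(scope="module")
def small_ped():
    return random_pedigree(n_founders=10, n_per_gen=20, n_gen=2, seed=2)


class TestGLSOracle:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_mme_solution_equals_dense_gls(self, small_ped, seed):
        """Instances well under 200 equations, solved both ways."""
        data = make_data(n=70, seed=seed, ped=small_ped)
        spec = ModelSpec("y", [FixedTerm("grp"), FixedTerm("x", "covariate")],
                         [RandomTerm("cls", "cls", "iid"),
                          RandomTerm("animal", "animal", "pedigree")])
        m = MixedModel(spec, data, pedigree=small_ped)
        comps = {"cls": 0.4, "animal": 0.9, "residual": 1.1}
        fit = m.fit(components=comps)
        A = build_A(small_ped).values
        idx = small_ped.indices_of(data["animal"])
        Zc = pd.get_dummies(data["cls"]).to_numpy(float)
        V = 1.1 * np.eye(len(data)) + 0.4 * Zc @ Zc.T \
            + 0.9 * A[np.ix_(idx, idx)]
        beta, cov = dense_gls(m.design.X, V, data["y"].to_numpy())
        assert np.abs(fit.beta - beta).max() < 1e-8
        assert np.abs(fit.cov_fixed - cov).max() < 1e-8

    def test_assemble_mme_solves_to_gls(self, small_ped):
        data = make_data(n=50, seed=4, ped=small_ped)
        spec = ModelSpec("y", [FixedTerm("x", "covariate")],
                         [RandomTerm("animal", "animal", "pedigree")])
        m = MixedModel(spec, data, pedigree=small_ped)
        C, rhs = m.assemble_mme({"animal": 0.7}, residual=1.3)
        sol = np.linalg.solve(C.toarray(), rhs)
        A = build_A(small_ped).values
        idx = small_ped.indices_of(data["animal"])
        V = 1.3 * np.eye(len(data)) + 0.7 * A[np.ix_(idx, idx)]
        beta, _ = dense_gls(m.design.X, V, data["y"].to_numpy())
        assert np.abs(sol[:m.p] - beta).max() < 1e-8

    def test_nonpositive_component_rejected(self, small_ped):
        data = make_data(n=30, seed=5, ped=small_ped)
        spec = ModelSpec("y", [], [RandomTerm("animal", "animal", "pedigree")])
        m = MixedModel(spec, data, pedigree=small_ped)
        with pytest.raises(ValueError, match="strictly positive"):
            m.assemble_mme({"animal": 0.0}, residual=1.0)


class TestLimitingCases:
    def test_no_random_terms_is_ols(self):
        data = make_data(n=80, seed=6)
        spec = ModelSpec("y", [FixedTerm("grp"), FixedTerm("x", "covariate")], [])
        fit = MixedModel(spec, data).fit()
        X = np.column_stack([np.ones(80),
                             pd.get_dummies(data["grp"], drop_first=True).to_numpy(float),
                             data["x"]])
        beta = np.linalg.lstsq(X, data["y"], rcond=None)[0]
        assert np.abs(fit.beta - beta).max() < 1e-10

    def test_huge_variance_approaches_fixed_treatment(self):
        data = make_data(n=120, seed=7, n_groups=4)
        random_spec = ModelSpec("y", [FixedTerm("x", "covariate")],
                                [RandomTerm("grp", "grp", "iid")])
        m = MixedModel(random_spec, data)
        fit = m.fit(components={"grp": 1e8, "residual": 1.0})
        fixed_spec = ModelSpec("y", [FixedTerm("grp"), FixedTerm("x", "covariate")], [])
        ols = MixedModel(fixed_spec, data).fit()
        x_r = fit.coefficient("x")[0]
        x_f = ols.coefficient("x")[0]
        assert x_r == pytest.approx(x_f, abs=1e-5)


class TestREML:
    def test_balanced_one_way_matches_anova(self):
        rng = np.random.default_rng(8)
        g, r = 40, 8
        lab = np.repeat(np.arange(g), r)
        y = 3.0 + rng.normal(0, np.sqrt(1.5), g)[lab] + rng.normal(0, 1.0, g * r)
        data = pd.DataFrame({"y": y, "grp": [f"g{i}" for i in lab]})
        vc = MixedModel(ModelSpec("y", [], [RandomTerm("grp", "grp", "iid")]),
                        data).reml()
        df = pd.DataFrame({"y": y, "g": lab})
        msb = df.groupby("g")["y"].mean().var(ddof=1) * r
        msw = df.groupby("g")["y"].var(ddof=1).mean()
        assert vc.components["grp"] == pytest.approx((msb - msw) / r, rel=1e-3)
        assert vc.residual == pytest.approx(msw, rel=1e-3)

    def test_scale_equivariance(self, small_ped):
        data = make_data(n=150, seed=9, ped=small_ped)
        spec = ModelSpec("y", [FixedTerm("x", "covariate")],
                         [RandomTerm("grp", "grp", "iid"),
                          RandomTerm("animal", "animal", "pedigree")])
        m = MixedModel(spec, data, pedigree=small_ped)
        vc1 = m.reml()
        data2 = data.assign(y=3.0 * data["y"])
        vc2 = MixedModel(spec, data2, pedigree=small_ped).reml()
        for k in vc1.components:
            assert vc2.components[k] == pytest.approx(9.0 * vc1.components[k],
                                                      rel=0.02, abs=1e-4)
        assert vc2.residual == pytest.approx(9.0 * vc1.residual, rel=0.01)

    def test_zero_signal_drives_component_to_boundary(self):
        rng = np.random.default_rng(10)
        data = pd.DataFrame({"y": rng.standard_normal(400),
                             "grp": rng.choice([f"g{i}" for i in range(5)], 400)})
        vc = MixedModel(ModelSpec("y", [], [RandomTerm("grp", "grp", "iid")]),
                        data).reml()
        assert vc.components["grp"] < 0.05 * vc.residual

    def test_component_recovery_on_correctly_specified_design(self):
        """Mean REML estimates across replicates track the generating
        variances on a moderate hierarchical design."""
        from mstnassoc.scenarios import (build_calving_design,
                                         calving_recovery_config)
        from mstnassoc.simulate import rng_for, sample_breeding_values
        cfg = calving_recovery_config(seed=21)
        import dataclasses
        cfg = dataclasses.replace(cfg, n_herds=12)
        design = build_calving_design(cfg, dams_per_herd=40)
        data = design.records.assign(calf_geno="0", dam_geno="0", score=0.0)
        model = MixedModel(design.spec, data, pedigree=design.pedigree)
        truth = cfg.variance_components
        ped = design.pedigree
        ci = ped.indices_of(data["calf"])
        di = ped.indices_of(data["dam"])
        ests = []
        warm = None
        for r in range(8):
            rng = rng_for(21, f"vc-rep-{r}")
            # simulate straight from the fitted model's own design: cg on the
            # assigned groups, so the model is exactly correctly specified
            cg_lv = sorted(data["cg_id"].unique())
            cg = dict(zip(cg_lv, rng.normal(0, np.sqrt(truth["cg"]), len(cg_lv))))
            dams = sorted(data["dam"].unique())
            pe = dict(zip(dams, rng.normal(0, np.sqrt(truth["pe"]), len(dams))))
            y = (data["cg_id"].map(cg).to_numpy()
                 + sample_breeding_values(ped, truth["direct"], rng)[ci]
                 + sample_breeding_values(ped, truth["maternal"], rng)[di]
                 + data["dam"].map(pe).to_numpy()
                 + rng.normal(0, np.sqrt(truth["residual"]), len(data)))
            vc = model.reml(start=warm, y=y)
            warm = {**vc.components, "residual": vc.residual}
            ests.append({**vc.components, "residual": vc.residual})
        means = pd.DataFrame(ests).mean()
        lookup = {"cg": "cg", "animal": "direct", "maternal": "maternal",
                  "pe": "pe", "residual": "residual"}
        for term, key in lookup.items():
            mc_se = pd.DataFrame(ests)[term].std(ddof=1) / np.sqrt(len(ests))
            assert abs(means[term] - truth[key]) < max(3 * mc_se, 0.15 * truth[key]), term

    def test_nonconvergence_raises_with_trace(self, small_ped):
        data = make_data(n=60, seed=11, ped=small_ped)
        spec = ModelSpec("y", [], [RandomTerm("grp", "grp", "iid"),
                                   RandomTerm("animal", "animal", "pedigree")])
        m = MixedModel(spec, data, pedigree=small_ped)
        with pytest.raises(ConvergenceError) as exc:
            m.reml(max_evals=5)
        assert len(exc.value.trace) > 0


class TestEstimability:
    def test_empty_and_dependent_columns_flagged(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame({
            "y": rng.standard_normal(50),
            "a": rng.choice(["p", "q"], 50),
        })
        data["b"] = data["a"]  # perfectly aliased class
        spec = ModelSpec("y", [FixedTerm("a"), FixedTerm("b")], [])
        fit = MixedModel(spec, data).fit()
        assert ("b", "q") in fit.ne_levels
        with pytest.raises(KeyError, match="non-estimable"):
            fit.coefficient("b", "q")
        frame = fit.coefficients_frame()
        assert (frame.loc[frame["term"] == "b", "status"] == NE).all()

    def test_reference_relabelling_shifts_estimates(self):
        rng = np.random.default_rng(13)
        data = pd.DataFrame({"y": rng.standard_normal(90),
                             "cls": rng.choice(["u", "v", "w"], 90)})
        f1 = MixedModel(ModelSpec("y", [FixedTerm("cls", reference="u")], []),
                        data).fit()
        f2 = MixedModel(ModelSpec("y", [FixedTerm("cls", reference="v")], []),
                        data).fit()
        # cell means are invariant to the reference level
        mu1 = {lv: f1.coefficient("cls", lv)[0] for lv in ("u", "v", "w")}
        mu2 = {lv: f2.coefficient("cls", lv)[0] for lv in ("u", "v", "w")}
        base1 = f1.beta[0]
        base2 = f2.beta[0]
        for lv in ("u", "v", "w"):
            assert base1 + mu1[lv] == pytest.approx(base2 + mu2[lv], abs=1e-9)


class TestInference:
    def test_single_df_f_equals_squared_t(self, small_ped):
        data = make_data(n=100, seed=14, ped=small_ped)
        spec = ModelSpec("y", [FixedTerm("x", "covariate")],
                         [RandomTerm("animal", "animal", "pedigree")])
        fit = MixedModel(spec, data, pedigree=small_ped).fit(
            components={"animal": 0.5, "residual": 1.0})
        est, se = fit.coefficient("x")
        F, df1, df2, p = fit.wald_f_test("x")
        assert df1 == 1
        assert F == pytest.approx((est / se) ** 2, abs=1e-10)

    def test_unit_contrast_reproduces_coefficient(self, small_ped):
        data = make_data(n=100, seed=15, ped=small_ped)
        spec = ModelSpec("y", [FixedTerm("grp")],
                         [RandomTerm("animal", "animal", "pedigree")])
        fit = MixedModel(spec, data, pedigree=small_ped).fit(
            components={"animal": 0.5, "residual": 1.0})
        lv = sorted(data["grp"].unique())[1]
        est, se = fit.coefficient("grp", lv)
        cest, cse = fit.contrast([("grp", lv, 1.0)])
        assert (cest, cse) == (pytest.approx(est), pytest.approx(se))

    def test_zero_contrast(self, small_ped):
        data = make_data(n=60, seed=16, ped=small_ped)
        spec = ModelSpec("y", [FixedTerm("grp")],
                         [RandomTerm("animal", "animal", "pedigree")])
        fit = MixedModel(spec, data, pedigree=small_ped).fit(
            components={"animal": 0.5, "residual": 1.0})
        assert fit.contrast([]) == (0.0, 0.0)

    def test_null_f_test_uniform_p(self):
        """Type-I error of the class F-test at nominal level on iid data."""
        rng = np.random.default_rng(17)
        n, reps = 150, 400
        grp = rng.choice(["a", "b", "c"], n)
        cls = rng.choice(["u", "v"], n)
        rejections = 0
        data = pd.DataFrame({"grp": grp, "cls": cls, "y": np.zeros(n)})
        spec = ModelSpec("y", [FixedTerm("cls")], [RandomTerm("grp", "grp", "iid")])
        m = MixedModel(spec, data)
        for _ in range(reps):
            y = rng.standard_normal(n)
            vc = m.reml(y=y)
            fit = m.fit(components=vc, y=y)
            if fit.wald_f_test("cls")[3] < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 2.5 * np.sqrt(0.05 * 0.95 / reps)
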