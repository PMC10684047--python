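"""Replicate simulation studies: parameter recovery and error calibration.

These drivers are shared by the analysis scripts, the acceptance checks and
the test suite.  Each study builds one design (pedigree, herd structure,
contemporary groups) and redraws genotypes, genetic effects and noise per
replicate; REML fits are warm-started from the previous replicate's
estimates, which speeds convergence without affecting the optimum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixed_model import ConvergenceError, MixedModel
from .scenarios import (build_calving_design, build_carcass_design,
                        build_null_design, calving_recovery_config,
                        carcass_recovery_config, rng_for,
                        simulate_calving_replicate, simulate_carcass_replicate,
                        simulate_null_response)


def _reml_robust(model, warm=None, y=None, max_evals=400):
    """REML with one cold-start retry at a larger evaluation budget; a
    stalled warm start on one replicate must not abort a replicated study."""
    try:
        return model.reml(start=warm, y=y, max_evals=max_evals)
    except ConvergenceError:
        return model.reml(y=y, max_evals=4 * max_evals)


def run_calving_recovery(seed: int, n_replicates: int = 20,
                         interaction: bool = False,
                         design: object | None = None,
                         max_evals: int = 400) -> dict:
    """Recover the calf and dam nt821 class effects (and optionally the
    homozygous dam x homozygous calf deviation) from replicated calving
    datasets simulated at the published effects as truth."""
    cfg = calving_recovery_config(seed, interaction=interaction)
    if design is None:
        design = build_calving_design(cfg)
    spec = design.spec_interaction if interaction else design.spec
    truth = {"calf_het": 0.13, "calf_hom": 0.37, "dam_het": 0.05,
             "dam_hom": 1.30}
    if interaction:
        truth["interaction_dev"] = 0.91
    rows = []
    warm = None
    for r in range(n_replicates):
        rng = rng_for(seed, f"calving-rep-{'i' if interaction else 'b'}-{r}")
        data, _ = simulate_calving_replicate(design, cfg, rng)
        model = MixedModel(spec, data, pedigree=design.pedigree)
        vc = _reml_robust(model, warm, max_evals=max_evals)
        warm = {**vc.components, "residual": vc.residual}
        fit = model.fit(components=vc)
        row = {
            "replicate": r,
            "calf_het": fit.coefficient("calf_geno", "1")[0],
            "calf_hom": fit.coefficient("calf_geno", "2")[0],
            "dam_het": fit.coefficient("dam_geno", "1")[0],
            "dam_hom": fit.coefficient("dam_geno", "2")[0],
            "n_records": len(data),
            "n_calf_hom": int((data["calf_geno"] == "2").sum()),
            "n_dam_hom": int((data["dam_geno"] == "2").sum()),
        }
        for k, v in vc.components.items():
            row[f"vc_{k}"] = v
        row["vc_residual"] = vc.residual
        if interaction:
            est, se = fit.coefficient("dam_calf_geno", "2|2")
            row["interaction_dev"] = est
            row["interaction_se"] = se
        rows.append(row)
    return {"replicates": pd.DataFrame(rows), "truth": truth,
            "config": cfg, "design": design}


def run_carcass_recovery(seed: int, variant: str = "Q204X",
                         n_replicates: int = 20,
                         design: object | None = None) -> dict:
    """Recover the homozygous carcass-weight effect of one focal variant
    (carrier-sire progeny design) from replicated carcass datasets."""
    cfg = carcass_recovery_config(seed, variant)
    if design is None:
        design = build_carcass_design(cfg)
    truth = {"hom": cfg.genotype_effects[variant]["calf"][2],
             "het": cfg.genotype_effects[variant]["calf"][1]}
    rows, warm = [], None
    for r in range(n_replicates):
        rng = rng_for(seed, f"carcass-rep-{variant}-{r}")
        data, _ = simulate_carcass_replicate(design, cfg, rng, focal=variant)
        model = MixedModel(design.spec, data, pedigree=design.pedigree)
        vc = _reml_robust(model, warm)
        warm = {**vc.components, "residual": vc.residual}
        fit = model.fit(components=vc)
        rows.append({
            "replicate": r,
            "het": fit.coefficient("calf_geno", "1")[0],
            "hom": fit.coefficient("calf_geno", "2")[0],
            "n_records": len(data),
            "n_hom": int((data["calf_geno"] == "2").sum()),
            "vc_direct": vc.components["animal"],
            "vc_residual": vc.residual,
        })
    return {"replicates": pd.DataFrame(rows), "truth": truth,
            "config": cfg, "design": design}


def run_null_calibration(seed: int, n_replicates: int = 1000,
                         alpha: float = 0.05) -> dict:
    """Size of the per-variant Wald F-test under the null.

    One small animal-model design with a genotype term of zero true effect;
    each replicate redraws the phenotype, re-estimates the variance
    components by REML and records the genotype-term p-value.
    """
    nd = build_null_design(seed)
    pvals = np.empty(n_replicates)
    warm = None
    for r in range(n_replicates):
        rng = rng_for(seed, f"null-rep-{r}")
        y = simulate_null_response(nd, rng)
        vc = _reml_robust(nd.model, warm, y=y)
        warm = {**vc.components, "residual": vc.residual}
        fit = nd.model.fit(components=vc, y=y)
        pvals[r] = fit.wald_f_test(nd.term)[3]
    rate = float(np.mean(pvals < alpha))
    half = 2.0 * np.sqrt(alpha * (1 - alpha) / n_replicates)
    return {"pvalues": pvals, "rejection_rate": rate, "alpha": alpha,
            "binomial_2se": half, "n_replicates": n_replicates}


def recovery_summary(study: dict, keys: list[str]) -> pd.DataFrame:
    """Mean estimate, Monte-Carlo SE of the mean, and truth per effect."""
    reps = study["replicates"]
    rows = []
    for k in keys:
        est = reps[k].to_numpy(dtype=float)
        rows.append({
            "effect": k,
            "truth": study["truth"][k],
            "mean": float(est.mean()),
            "mc_se": float(est.std(ddof=1) / np.sqrt(len(est))),
            "n_replicates": len(est),
        })
    return pd.DataFrame(rows)
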