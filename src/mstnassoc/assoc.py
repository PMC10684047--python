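"""Association analysis plans over the mixed models.

The analysis sequence mirrors the study design: each variant (or haplotype)
is first tested singly, with the calf and dam genotype classes fitted
concurrently for calving difficulty (the carcass models carry only the
animal's own genotype).  Units whose calf or dam term is significant at
alpha go forward to (a) an interaction follow-up adding the concatenated
dam-calf genotype class, whose coefficients are directly the deviations
from additivity, and (b) one multi-locus model containing all qualifying
units concurrently.  No multiple-testing correction is applied across
units, matching the original analysis plan (a Bonferroni option exists but
is off by default).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import PhasedHaplotypes
from .mixed_model import NE, FixedTerm, MixedModel, ModelFit, ModelSpec
from .simulate import genotype_counts


@dataclass
class AnalysisPlan:
    phenotype: str               # calving | carcass-weight | carcass-conformation | carcass-fat
    unit_kind: str = "variant"   # variant | haplotype
    alpha: float = 0.05
    bonferroni: bool = False
    n_units: int = 1

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_units if self.bonferroni else self.alpha


@dataclass
class UnitResult:
    unit: str
    status: str                  # ok | not-segregating
    fit: ModelFit | None = None
    tests: dict = field(default_factory=dict)   # role -> (F, df1, df2, p)

    def significant(self, alpha: float) -> bool:
        return any(isinstance(t[3], float) and t[3] < alpha
                   for t in self.tests.values())


def haplotype_copies(haps: PhasedHaplotypes, hap_indicator) -> pd.Series:
    """Copies (0/1/2) of one haplotype carried per animal."""
    target = np.asarray(hap_indicator, dtype=np.int8)
    p = (haps.paternal == target).all(axis=1).astype(int)
    m = (haps.maternal == target).all(axis=1).astype(int)
    return pd.Series(p + m, index=haps.animals)


def attach_unit_classes(data: pd.DataFrame, haps: PhasedHaplotypes, unit,
                        calf_col: str = "calf", dam_col: str | None = "dam",
                        suffix: str = "") -> pd.DataFrame:
    """Add genotype/haplotype-copy class columns for one analysis unit."""
    if isinstance(unit, str):
        copies = genotype_counts(haps, unit)
    else:
        copies = haplotype_copies(haps, unit)
    out = data.copy()
    out[f"calf_geno{suffix}"] = copies.reindex(
        data[calf_col]).astype(int).astype(str).to_numpy()
    if dam_col is not None:
        out[f"dam_geno{suffix}"] = copies.reindex(
            data[dam_col]).astype(int).astype(str).to_numpy()
    return out


def run_single_locus(spec: ModelSpec, data: pd.DataFrame, pedigree, unit: str,
                     reml_start=None, **fit_kw) -> UnitResult:
    """Single-unit fit with the calf (and, for calving, dam) class effects
    included concurrently.  Monomorphic units are skipped with a status."""
    if data["calf_geno"].nunique() < 2:
        return UnitResult(unit=unit, status="not-segregating")
    model = MixedModel(spec, data, pedigree=pedigree)
    fit = model.fit(start=reml_start, **fit_kw) if reml_start else model.fit(**fit_kw)
    tests = {}
    for role in ("calf_geno", "dam_geno"):
        if any(t.name == role for t in spec.fixed):
            tests[role] = fit.wald_f_test(role)
    return UnitResult(unit=unit, status="ok", fit=fit, tests=tests)


def interaction_spec(spec: ModelSpec) -> ModelSpec:
    """The single-locus model plus the concatenated dam-calf class.

    Deviation coding: combinations in which either animal carries zero
    copies collapse into the reference level, so every remaining dummy is
    directly the deviation of that dam-progeny combination from the sum of
    the marginal genotype effects."""
    extra = FixedTerm("dam_calf_geno", "class", reference="0",
                      levels=("2|2", "2|1", "1|2", "1|1"))
    return ModelSpec(spec.response, list(spec.fixed) + [extra], list(spec.random))


def add_interaction_column(data: pd.DataFrame) -> pd.DataFrame:
    out = data.copy()
    zero = (out["calf_geno"] == "0") | (out["dam_geno"] == "0")
    out["dam_calf_geno"] = np.where(zero, "0",
                                    out["dam_geno"] + "|" + out["calf_geno"])
    return out


def run_interaction(spec: ModelSpec, data: pd.DataFrame, pedigree, unit: str,
                    **fit_kw) -> tuple[UnitResult, pd.DataFrame]:
    """Interaction follow-up: refit with the concatenated dam-calf class.

    With calf, dam and joint classes all referenced at zero copies, each
    joint-class coefficient is exactly the deviation of that dam-progeny
    combination from the sum of the marginal genotype effects.  Returns the
    fit and a dam x calf matrix of (deviation, SE) with NE for unobserved
    combinations.
    """
    ispec = interaction_spec(spec)
    if "dam_calf_geno" not in data.columns:
        data = add_interaction_column(data)
    model = MixedModel(ispec, data, pedigree=pedigree)
    fit = model.fit(**fit_kw)
    res = UnitResult(unit=unit, status="ok", fit=fit,
                     tests={"dam_calf_geno": fit.wald_f_test("dam_calf_geno")})
    cells = {}
    observed = set(data["dam_geno"] + "|" + data["calf_geno"])
    for dcop in ("0", "1", "2"):
        row = {}
        for ccop in ("0", "1", "2"):
            lev = f"{dcop}|{ccop}"
            if lev not in observed:
                row[ccop] = NE
            elif dcop == "0" or ccop == "0":
                row[ccop] = (0.0, 0.0)
            else:
                try:
                    row[ccop] = fit.coefficient("dam_calf_geno", lev)
                except KeyError:
                    row[ccop] = NE
        cells[dcop] = row
    matrix = pd.DataFrame(cells).T
    matrix.index.name = "dam_copies"
    matrix.columns.name = "calf_copies"
    return res, matrix


def multi_locus_spec(spec: ModelSpec, units: list[str]) -> ModelSpec:
    """One model containing every qualifying unit's class terms
    concurrently (both calf and dam roles wherever the base model has
    them).  Terms enter in the listed unit order; aliased columns of
    later-listed units are dropped as NE by the rank detection."""
    fixed = [t for t in spec.fixed if t.name not in ("calf_geno", "dam_geno")]
    has_dam = any(t.name == "dam_geno" for t in spec.fixed)
    for u in units:
        fixed.append(FixedTerm(f"calf_geno_{u}", "class", reference="0"))
        if has_dam:
            fixed.append(FixedTerm(f"dam_geno_{u}", "class", reference="0"))
    return ModelSpec(spec.response, fixed, list(spec.random))


def run_multi_locus(spec: ModelSpec, data: pd.DataFrame, pedigree,
                    units: list[str], **fit_kw) -> dict[str, UnitResult]:
    """Concurrent fit of all significant units; per-unit conditional
    effects and F-tests.  Requires columns calf_geno_<unit> (and
    dam_geno_<unit> for calving) on ``data``."""
    if not units:
        raise ValueError("multi-locus model needs at least one unit")
    mspec = multi_locus_spec(spec, units)
    model = MixedModel(mspec, data, pedigree=pedigree)
    fit = model.fit(**fit_kw)
    out = {}
    for u in units:
        tests = {}
        for role in ("calf_geno", "dam_geno"):
            name = f"{role}_{u}"
            if any(t.name == name for t in mspec.fixed):
                tests[role] = fit.wald_f_test(name)
        out[u] = UnitResult(unit=u, status="ok", fit=fit, tests=tests)
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _fmt(x):
    if isinstance(x, str):
        return x
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return NE
    return f"{x:.6g}"


def report(results: dict[str, UnitResult], out_dir, alpha: float = 0.05,
           metadata: dict | None = None,
           matrices: dict[str, pd.DataFrame] | None = None) -> Path:
    """Publication-shaped TSV tables plus a run manifest.

    One effects table (unit, role, copies, estimate, SE, p, status; NE
    printed literally), optional interaction matrices, and a manifest with
    the metadata and a config hash so reruns are byte-identical and
    verifiable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for unit, res in sorted(results.items()):
        if res.status != "ok":
            rows.append({"unit": unit, "role": "-", "copies": "-",
                         "estimate": NE, "se": NE, "p_term": NE,
                         "status": res.status})
            continue
        for role, test in res.tests.items():
            term = role if (role in [t.name for t in res.fit.model.spec.fixed]) \
                else f"{role}_{unit}"
            for copies in ("1", "2"):
                try:
                    est, se = res.fit.coefficient(term, copies)
                    rows.append({"unit": unit, "role": role, "copies": copies,
                                 "estimate": _fmt(est), "se": _fmt(se),
                                 "p_term": _fmt(test[3]), "status": "ok"})
                except KeyError:
                    rows.append({"unit": unit, "role": role, "copies": copies,
                                 "estimate": NE, "se": NE,
                                 "p_term": _fmt(test[3]), "status": NE})
    table = pd.DataFrame(rows)
    sig = [u for u, r in results.items() if r.status == "ok" and r.significant(alpha)]
    eff_path = out_dir / "effects.tsv"
    if table.empty or not any(r.status == "ok" for r in results.values()):
        eff_path.write_text(f"no associations at alpha={alpha}\n")
    else:
        table.to_csv(eff_path, sep="\t", index=False)
        if not sig:
            (out_dir / "significant.tsv").write_text(
                f"no associations at alpha={alpha}\n")
        else:
            pd.Series(sig, name="unit").to_csv(
                out_dir / "significant.tsv", sep="\t", index=False)
    for name, mat in (matrices or {}).items():
        mat.map(lambda c: NE if c == NE else f"{c[0]:.4g}({c[1]:.4g})") \
            .to_csv(out_dir / f"interaction_{name}.tsv", sep="\t")
    meta = dict(metadata or {})
    meta["alpha"] = alpha
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()).hexdigest()[:16]
    (out_dir / "manifest.json").write_text(json.dumps(meta, indent=2, default=str,
                                                      sort_keys=True) + "\n")
    return eff_path
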