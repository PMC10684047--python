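"""Linear mixed models via Henderson's mixed-model equations.

Supports the two model families used in the association analyses:

* calving difficulty: fixed nuisance effects plus calf and dam genotype
  class effects, with random contemporary group (iid), direct additive
  genetic and maternal genetic effects (pedigree covariance, zero
  direct-maternal covariance) and a permanent environmental effect of the
  dam (iid);
* carcass traits: fixed contemporary group and nuisance effects plus the
  animal's genotype class, with a single pedigree-structured direct genetic
  effect.

Variance components are estimated by REML.  The restricted log-likelihood
is evaluated exactly from a sparse LDL' factorisation of the full MME
coefficient matrix (log |C| from the pivots, the residual variance profiled
out analytically) and maximised over log variance ratios with derivative-
free optimisation (Brent for one component, Nelder-Mead otherwise).  This
gives the same optimum as scoring-type REML iterations while needing only
factorisations, never traces of inverses.

Fixed-effect estimability: class levels whose design column is empty or
linearly dependent on earlier columns are flagged NE (non-estimable) and
carry no estimate; estimation proceeds on the remaining full-rank design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats

from .pedigree import Pedigree, build_A_inverse, log_det_A
from .sparsechol import SymbolicLDL

NE = "NE"
_GAMMA_LOG_BOUND = 11.5  # |log gamma| bound, ratios ~1e-5 .. 1e5


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class FixedTerm:
    name: str
    kind: str = "class"  # class | covariate | interaction
    columns: tuple = ()
    reference: object = None
    levels: tuple | None = None  # explicit level (= column) order; earlier
    #                              levels win when aliasing forces NE drops

    def __post_init__(self):
        if not self.columns:
            self.columns = (self.name,)
        if self.kind not in ("class", "covariate", "interaction"):
            raise ValueError(f"unknown fixed-term kind {self.kind!r}")


@dataclass
class RandomTerm:
    name: str
    level_column: str
    covariance: str = "iid"  # iid | pedigree

    def __post_init__(self):
        if self.covariance not in ("iid", "pedigree"):
            raise ValueError(f"unknown covariance {self.covariance!r}")


@dataclass
class ModelSpec:
    response: str
    fixed: list[FixedTerm]
    random: list[RandomTerm] = field(default_factory=list)

    def __post_init__(self):
        names = [t.name for t in self.fixed] + [t.name for t in self.random]
        if len(set(names)) != len(names):
            raise ValueError("duplicate term names in model specification")


@dataclass
class VarianceComponents:
    components: dict[str, float]
    residual: float
    converged: bool
    loglik: float
    n_evaluations: int
    boundary: set = field(default_factory=set)
    trace: list = field(default_factory=list)


def _interaction_labels(data: pd.DataFrame, columns) -> pd.Series:
    lab = data[columns[0]].astype(str)
    for c in columns[1:]:
        lab = lab + "|" + data[c].astype(str)
    return lab


class _Design:
    """Fixed design matrix with labels, reference levels and ordered-pivot
    rank detection (earlier columns win; dependent/empty columns -> NE)."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, rank_tol: float = 1e-9):
        cols: list[np.ndarray] = [np.ones(len(data))]
        labels: list[tuple[str, object]] = [("(Intercept)", None)]
        self.references: dict[str, object] = {}
        for t in spec.fixed:
            if t.kind == "covariate":
                v = data[t.columns[0]].to_numpy(dtype=float)
                if np.isnan(v).any():
                    raise ValueError(f"covariate {t.name!r} has missing values")
                cols.append(v)
                labels.append((t.name, None))
                continue
            lab = (_interaction_labels(data, t.columns) if t.kind == "interaction"
                   else data[t.columns[0]].astype(str))
            observed = sorted(lab.unique())
            if t.levels is not None:
                levels = [str(l) for l in t.levels if str(l) in observed]
                levels += [l for l in observed if l not in levels]
            else:
                levels = observed
            ref = str(t.reference) if t.reference is not None else levels[0]
            if ref not in levels:
                ref = levels[0]
            self.references[t.name] = ref
            for lv in levels:
                if lv == ref:
                    continue
                cols.append((lab == lv).to_numpy(dtype=float))
                labels.append((t.name, lv))
        X = np.column_stack(cols)
        self.labels = labels
        G = X.T @ X
        keep, ne = _ordered_rank_detection(G, rank_tol)
        self.ne_columns = [labels[j] for j in ne]
        self.kept = keep
        self.X = X[:, keep]
        self.kept_labels = [labels[j] for j in keep]
        self.rank = len(keep)


def _ordered_rank_detection(G: np.ndarray, tol: float) -> tuple[list[int], list[int]]:
    """Cholesky in listed column order; pivots below tol * original diagonal
    mark the column as dependent on its predecessors (NE)."""
    p = G.shape[0]
    R = G.astype(float).copy()
    base = np.diag(G).copy()
    keep, ne = [], []
    for j in range(p):
        d = R[j, j]
        if base[j] <= 0 or d <= tol * max(base[j], 1.0):
            ne.append(j)
            R[j, :] = 0.0
            R[:, j] = 0.0
            continue
        keep.append(j)
        if j + 1 < p:
            v = R[j + 1:, j]
            R[j + 1:, j + 1:] -= np.outer(v, v) / d
    return keep, ne


class MixedModel:
    """Assembled mixed-model equations for one model spec on one dataset.

    Heavy structural work (design build, sparsity pattern, fill-reducing
    ordering, symbolic factorisation) happens once in the constructor;
    ``reml()`` and ``fit()`` reuse it.  For repeated fits on new responses
    over the same structure (simulation replicates), pass a new ``y`` to
    ``fit``/``reml`` directly.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame,
                 pedigree: Pedigree | None = None, rank_tol: float = 1e-9):
        self.spec = spec
        self.n = len(data)
        y = data[spec.response].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("response contains missing values")
        self.y = y
        self.design = _Design(spec, data, rank_tol)
        self.p = self.design.rank
        if self.p >= self.n:
            raise ValueError("more fixed-effect columns than records")

        self.random_levels: dict[str, list] = {}
        Zs = []
        self._logdet_struct = 0.0
        self._precisions = []
        self._ainv_cache = None
        for t in spec.random:
            codes_col = data[t.level_column]
            if t.covariance == "pedigree":
                if pedigree is None:
                    raise ValueError(f"term {t.name!r} needs a pedigree")
                levels = list(pedigree.ids)
                codes = pedigree.indices_of(codes_col)
                if self._ainv_cache is None:
                    self._ainv_cache = (build_A_inverse(pedigree), log_det_A(pedigree))
                P, lds = self._ainv_cache
            else:
                levels = sorted(map(str, codes_col.unique()))
                lut = {l: i for i, l in enumerate(levels)}
                codes = np.array([lut[str(v)] for v in codes_col], dtype=np.int64)
                P, lds = sp.identity(len(levels), format="csc"), 0.0
            q = len(levels)
            Z = sp.csc_matrix((np.ones(self.n), (np.arange(self.n), codes)),
                              shape=(self.n, q))
            Zs.append(Z)
            self.random_levels[t.name] = levels
            self._precisions.append((t.name, P, q, lds))

        W = sp.hstack([sp.csc_matrix(self.design.X)] + Zs).tocsc() if Zs else \
            sp.csc_matrix(self.design.X)
        self.W = W
        self.n_eq = W.shape[1]
        self._WtW = (W.T @ W).tocsc()
        self.Wty = W.T @ y
        self.yty = float(y @ y)

        if self.spec.random:
            self._build_symbolic()

    # -- structural ---------------------------------------------------------
    def _build_symbolic(self):
        offsets = [self.p]
        for _, _, q, _ in self._precisions:
            offsets.append(offsets[-1] + q)
        self._offsets = offsets
        # pattern matrices carry all-ones data: exact numeric cancellations
        # (possible in A-inverse entries) must not prune structural slots
        pat = sp.csc_matrix(
            (np.ones_like(self._WtW.data), self._WtW.indices, self._WtW.indptr),
            shape=self._WtW.shape)
        parts = []
        for k, (_, P, q, _) in enumerate(self._precisions):
            Pc = P.tocoo()
            parts.append((Pc.row + offsets[k], Pc.col + offsets[k], Pc.data))
        blocks = sp.coo_matrix(
            (np.ones(sum(len(p[2]) for p in parts)),
             (np.concatenate([p[0] for p in parts]),
              np.concatenate([p[1] for p in parts]))),
            shape=pat.shape).tocsc()
        self.symbolic = SymbolicLDL((pat + blocks).tocsc())

        wc = self._WtW.tocoo()
        m = wc.row <= wc.col
        slots_w = self.symbolic.coo_slots(wc.row[m], wc.col[m])
        vals_w = wc.data[m]
        self._seg_slots = [slots_w]
        self._seg_vals = [vals_w]
        for k, (_, P, q, _) in enumerate(self._precisions):
            Pc = P.tocoo()
            mm = Pc.row <= Pc.col
            self._seg_slots.append(
                self.symbolic.coo_slots(Pc.row[mm] + self._offsets[k],
                                        Pc.col[mm] + self._offsets[k]))
            self._seg_vals.append(Pc.data[mm])
        self._all_slots = np.concatenate(self._seg_slots)
        self._seg_sizes = [len(v) for v in self._seg_vals]
        self._all_vals = np.concatenate(self._seg_vals)

    def _upper_data(self, gamma: np.ndarray) -> np.ndarray:
        w = self._all_vals.copy()
        pos = self._seg_sizes[0]
        for k, g in enumerate(gamma):
            w[pos:pos + self._seg_sizes[k + 1]] /= g
            pos += self._seg_sizes[k + 1]
        return np.bincount(self._all_slots, weights=w,
                           minlength=self.symbolic.upper_nnz)

    def assemble_mme(self, components: dict[str, float], residual: float):
        """Coefficient matrix and right-hand side of the MME at the given
        variance components (sparse CSC; deterministic column order:
        fixed effects, then each random term's levels in order)."""
        for name, v in components.items():
            if v <= 0:
                raise ValueError(f"component {name!r} must be strictly positive")
        C = (self._WtW / residual).tolil()
        for k, (name, P, q, _) in enumerate(self._precisions):
            o = self._offsets[k]
            C[o:o + q, o:o + q] = C[o:o + q, o:o + q] + P / components[name]
        return C.tocsc(), self.Wty / residual

    # -- REML ---------------------------------------------------------------
    def _neg2_restricted_ll(self, log_gamma: np.ndarray, y_stats=None) -> float:
        # boundary components: evaluate at the clipped ratio with a smooth
        # quadratic pull-back, so the optimiser settles on the bound instead
        # of bouncing off a penalty cliff
        clipped = np.clip(log_gamma, -_GAMMA_LOG_BOUND, _GAMMA_LOG_BOUND)
        penalty = 1e3 * float(np.sum((log_gamma - clipped) ** 2))
        gamma = np.exp(clipped)
        Wty, yty = y_stats if y_stats is not None else (self.Wty, self.yty)
        try:
            fac = self.symbolic.factor_from_upper(self._upper_data(gamma))
        except np.linalg.LinAlgError:
            return 1e30
        sol = fac.solve(Wty)
        s = yty - float(Wty @ sol)
        if s <= 0:
            return 1e30
        df = self.n - self.p
        out = df * (np.log(s / df) + 1.0) + fac.logdet + penalty
        for k, (_, _, q, lds) in enumerate(self._precisions):
            out += q * clipped[k] + lds
        return float(out)

    def reml(self, start: dict[str, float] | None = None, max_evals: int = 400,
             tol: float = 1e-6, y: np.ndarray | None = None) -> VarianceComponents:
        """Estimate variance components by restricted maximum likelihood.

        ``start`` maps term names (and optionally "residual") to starting
        variances; the default splits 30% of the phenotypic variance evenly
        over the random terms.
        """
        if not self.spec.random:
            raise ValueError("model has no random terms")
        y_stats = None
        yv = self.y
        if y is not None:
            yv = np.asarray(y, dtype=float)
            y_stats = (self.W.T @ yv, float(yv @ yv))
        vary = float(np.var(yv))
        k = len(self._precisions)
        if start:
            res0 = start.get("residual", 0.7 * vary)
            x0 = np.log([max(start.get(nm, 0.3 * vary / k), 1e-6) / res0
                         for nm, _, _, _ in self._precisions])
        else:
            x0 = np.full(k, np.log(0.3 / (0.7 * k)))
        trace: list = []

        def obj(th):
            v = self._neg2_restricted_ll(th, y_stats)
            trace.append((list(th), v))
            return v

        if k == 1:
            r = optimize.minimize_scalar(
                lambda t: obj(np.array([t])), bounds=(-_GAMMA_LOG_BOUND, _GAMMA_LOG_BOUND),
                method="bounded", options={"xatol": 1e-4, "maxiter": max_evals})
            theta = np.array([r.x])
            n_ev, ok = r.nfev, bool(r.success)
        else:
            # Nelder-Mead with restarts: a fresh simplex at the incumbent
            # best point recovers from simplex collapse along flat
            # (boundary) directions
            x_cur, n_ev, ok = x0, 0, False
            for _ in range(3):
                r = optimize.minimize(
                    obj, x_cur, method="Nelder-Mead",
                    options={"fatol": tol, "xatol": 1e-3, "maxfev": max_evals,
                             "adaptive": True})
                n_ev += r.nfev
                theta, ok = r.x, bool(r.success)
                if ok:
                    break
                x_cur = r.x
        if not ok:
            # convergence is judged on the restricted log-likelihood: when a
            # ratio sits on its boundary the simplex can drift along a flat
            # axis without shrinking, while the likelihood is long converged
            vals = np.array([v for _, v in trace])
            best = np.minimum.accumulate(vals)
            window = int(0.7 * len(best))
            if len(best) > 30 and best[window] - best[-1] < tol:
                ok = True
                theta = np.clip(np.asarray(trace[int(np.argmin(vals))][0]),
                                -_GAMMA_LOG_BOUND, _GAMMA_LOG_BOUND)
        if not ok:
            raise ConvergenceError(
                f"REML did not converge within {max_evals} evaluations", trace)
        gamma = np.exp(theta)
        Wty, yty = y_stats if y_stats is not None else (self.Wty, self.yty)
        fac = self.symbolic.factor_from_upper(self._upper_data(gamma))
        sol = fac.solve(Wty)
        s = yty - float(Wty @ sol)
        sigma2e = s / (self.n - self.p)
        comps = {nm: float(g * sigma2e) for (nm, _, _, _), g in
                 zip(self._precisions, gamma)}
        boundary = {nm for (nm, _, _, _), th in zip(self._precisions, theta)
                    if abs(th) > _GAMMA_LOG_BOUND - 1.0}
        return VarianceComponents(
            components=comps, residual=float(sigma2e), converged=ok,
            loglik=-0.5 * float(obj(theta)), n_evaluations=n_ev,
            boundary=boundary, trace=trace)

    # -- solving ------------------------------------------------------------
    def fit(self, components: VarianceComponents | dict | None = None,
            y: np.ndarray | None = None, **reml_kw) -> "ModelFit":
        """BLUE/BLUP solutions, covariances and test machinery.

        Without ``components`` REML is run first.  ``y`` substitutes a new
        response on the same design (simulation replicates).
        """
        yv = self.y if y is None else np.asarray(y, dtype=float)
        if not self.spec.random:
            return self._fit_ols(yv)
        if components is None:
            components = self.reml(y=None if y is None else yv, **reml_kw)
        if isinstance(components, dict):
            comps = dict(components)
            resid = comps.pop("residual")
            components = VarianceComponents(
                components=comps, residual=float(resid), converged=True,
                loglik=np.nan, n_evaluations=0)
        gamma = np.array([components.components[nm] / components.residual
                          for nm, _, _, _ in self._precisions])
        fac = self.symbolic.factor_from_upper(self._upper_data(gamma))
        Wty = self.Wty if y is None else self.W.T @ yv
        sol = fac.solve(Wty)
        B = np.zeros((self.n_eq, self.p))
        B[:self.p, :] = np.eye(self.p)
        cov_fixed = fac.solve(B)[:self.p, :] * components.residual
        return ModelFit(self, components, sol, cov_fixed)

    def _fit_ols(self, yv: np.ndarray) -> "ModelFit":
        X = self.design.X
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ yv)
        rss = float(yv @ yv - beta @ (X.T @ yv))
        sigma2 = rss / (self.n - self.p)
        comps = VarianceComponents(components={}, residual=sigma2, converged=True,
                                   loglik=np.nan, n_evaluations=0)
        return ModelFit(self, comps, beta, np.linalg.inv(XtX) * sigma2)


class ModelFit:
    """Solutions of one fitted mixed model."""

    def __init__(self, model: MixedModel, varcomp: VarianceComponents,
                 solution: np.ndarray, cov_fixed: np.ndarray):
        self.model = model
        self.varcomp = varcomp
        self._sol = solution
        self.cov_fixed = cov_fixed
        self.beta = solution[:model.p]
        self._colmap = {lab: j for j, lab in enumerate(model.design.kept_labels)}
        self.ne_levels = set(model.design.ne_columns)

    # -- accessors ----------------------------------------------------------
    def coefficient(self, term: str, level=None) -> tuple[float, float]:
        """(estimate, SE) of one fixed-effect column; reference levels are 0
        by construction; NE levels raise KeyError."""
        key = (term, None if level is None else str(level))
        if key in self.ne_levels:
            raise KeyError(f"{term}={level} is non-estimable (NE)")
        ref = self.model.design.references.get(term)
        if level is not None and str(level) == ref:
            return 0.0, 0.0
        j = self._colmap[key]
        return float(self.beta[j]), float(np.sqrt(self.cov_fixed[j, j]))

    def coefficients_frame(self) -> pd.DataFrame:
        rows = []
        for (term, level), j in self._colmap.items():
            rows.append({"term": term, "level": level,
                         "estimate": float(self.beta[j]),
                         "se": float(np.sqrt(self.cov_fixed[j, j])),
                         "status": "estimated"})
        for term, level in self.ne_levels:
            rows.append({"term": term, "level": level, "estimate": np.nan,
                         "se": np.nan, "status": NE})
        return pd.DataFrame(rows)

    def blup(self, term: str) -> pd.Series:
        names = [t.name for t in self.model.spec.random]
        k = names.index(term)
        o = self.model._offsets[k]
        q = len(self.model.random_levels[term])
        return pd.Series(self._sol[o:o + q], index=self.model.random_levels[term])

    # -- inference ----------------------------------------------------------
    def wald_f_test(self, term: str):
        """Wald F on the term's estimable non-reference columns.

        Denominator df by a containment-style residual approximation,
        n - rank(X).  Returns (F, df_num, df_den, p); all-NE terms return
        an NE status tuple.
        """
        js = [j for (t, lv), j in self._colmap.items() if t == term]
        if not js:
            return (NE, 0, 0, NE)
        b = self.beta[js]
        V = self.cov_fixed[np.ix_(js, js)]
        m = len(js)
        F = float(b @ np.linalg.solve(V, b)) / m
        df2 = self.model.n - self.model.p
        pval = float(stats.f.sf(F, m, df2))
        return (F, m, df2, pval)

    def contrast(self, coefficients: list[tuple]) -> tuple:
        """Linear contrast c'beta with SE from the MME inverse.

        ``coefficients`` is a list of (term, level, weight); reference
        levels contribute 0.  Touching an NE level returns (NE, NE).
        """
        c = np.zeros(self.model.p)
        for term, level, w in coefficients:
            key = (term, None if level is None else str(level))
            if key in self.ne_levels:
                return (NE, NE)
            ref = self.model.design.references.get(term)
            if level is not None and str(level) == ref:
                continue
            c[self._colmap[key]] += w
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov_fixed @ c))
        return (est, se)
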