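"""Longitudinal and categorical statistics for cohort tables.

Model surface mirrors the study's analysis plan:

* Poisson generalized mixed model (Laplace approximation) for sprout
  counts over time, reported as a count-scale slope (sprouts/dpt);
* linear mixed model (LMM) for session-mean sprout length (um/dpt);
* mixed linear regression with a treatment-by-time interaction (MLMR)
  for the perfusion metrics, with an omnibus Wald F on the interaction
  and Holm-Bonferroni-corrected pairwise post-hoc contrasts;
* through-origin mixed regression of perfused on total sprout counts
  (slope = perfused fraction);
* Wilcoxon signed-rank, Fisher's exact and Mann-Whitney U tests.

Random-effects structure is an intercept per animal throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

__all__ = ["ModelFit", "TestResult", "holm", "fit_poisson_glmm", "fit_lmm",
           "fit_mlmr_interaction", "fit_perfused_ratio",
           "wilcoxon_signed_rank", "fisher_exact_2x2", "mann_whitney_u"]


class DegenerateFitError(ValueError):
    pass


@dataclass
class ModelFit:
    model_kind: str
    formula_text: str
    slopes: dict[str, tuple[float, float, float]]  # name -> (est, se, p)
    omnibus_f: float | None = None
    omnibus_df: tuple[int, int] | None = None
    omnibus_p: float | None = None
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def slope(self, name: str = "dpt") -> float:
        return self.slopes[name][0]

    def slope_se(self, name: str = "dpt") -> float:
        return self.slopes[name][1]

    def to_jsonable(self) -> dict:
        d = {
            "model_kind": self.model_kind,
            "formula": self.formula_text,
            "slopes": {k: {"estimate": v[0], "se": v[1], "p": v[2]}
                       for k, v in self.slopes.items()},
        }
        if self.omnibus_f is not None:
            d["omnibus"] = {"F": self.omnibus_f, "df": list(self.omnibus_df),
                            "p": self.omnibus_p}
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    flag: str | None = None


def holm(pvalues) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values.

    Monotone, deterministic: adj_(i) = min(1, max_{j<=i} (m-j+1) p_(j))
    over the ascending order statistics.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _zp(est: float, se: float) -> float:
    if se <= 0 or not np.isfinite(se):
        return float("nan")
    return float(2.0 * sps.norm.sf(abs(est / se)))


def fit_poisson_glmm(
    counts: pd.DataFrame,
    response: str = "count",
    time: str = "dpt",
    animal: str = "animal_id",
) -> ModelFit:
    """Poisson mixed model of counts over time, Laplace approximation.

    The model uses the canonical log link with a random intercept per
    animal; because the study reports the slope on the count scale
    (sprouts per day), the log-scale fit is converted to the mean count
    increment per day over the observed time range:
    ``(mu(t_max) - mu(t_min)) / (t_max - t_min)`` with ``mu(t) =
    exp(a + b t)``, and its standard error follows from the delta
    method on (a, b).
    """
    df = counts[[animal, time, response]].dropna().copy()
    if (df[response] == 0).all():
        raise DegenerateFitError("all counts are zero; Poisson fit degenerate")
    if df.groupby(animal)[time].nunique().min() < 2:
        raise DegenerateFitError("need >= 2 sessions per animal")
    formula = f"{response} ~ {time}"
    model = PoissonBayesMixedGLM.from_formula(
        formula, {"animal": f"0 + C({animal})"}, df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Laplace convergence chatter
        result = model.fit_map()
    a, b = (float(x) for x in result.fe_mean[:2])
    cov = result.cov_params
    if callable(cov):
        cov = cov()
    cov = np.asarray(cov)[:2, :2]
    t0, t1 = float(df[time].min()), float(df[time].max())
    mu0, mu1 = np.exp(a + b * t0), np.exp(a + b * t1)
    span = t1 - t0
    slope = (mu1 - mu0) / span
    grad = np.array([(mu1 - mu0) / span, (t1 * mu1 - t0 * mu0) / span])
    se = float(np.sqrt(grad @ cov @ grad))
    b_se = float(np.sqrt(cov[1, 1]))
    return ModelFit(
        model_kind="poisson_glmm",
        formula_text=formula + f" + (1 | {animal})  [log link, Laplace]",
        slopes={"count_per_dpt": (float(slope), se, _zp(b, b_se)),
                "log_dpt": (b, b_se, _zp(b, b_se))},
        extra={"intercept": a, "t_range": (t0, t1)},
    )


def fit_lmm(
    lengths: pd.DataFrame,
    response: str = "value",
    time: str = "dpt",
    animal: str = "animal_id",
) -> ModelFit:
    """Linear mixed model: response ~ time with a per-animal intercept."""
    df = lengths[[animal, time, response]].dropna().copy()
    if df[animal].nunique() < 3:
        raise DegenerateFitError(
            f"need >= 3 animals, got {df[animal].nunique()}")
    formula = f"{response} ~ {time}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.mixedlm(formula, df, groups=df[animal]).fit(reml=True)
    est = float(res.params[time])
    se = float(res.bse[time])
    if not np.isfinite(se):
        resid_fe = res.model.endog - res.model.exog @ np.asarray(res.fe_params)
        if float(np.var(resid_fe)) < 1e-12:
            se = 0.0  # perfect fit: zero residual variance
    return ModelFit(
        model_kind="lmm",
        formula_text=formula + f" + (1 | {animal})",
        slopes={time: (est, se, float(res.pvalues[time]))},
    )


def _group_term(col_names: list[str], group: str, interaction: bool) -> str | None:
    pat = f"[T.{group}]"
    for name in col_names:
        if pat in name and (":" in name) == interaction:
            return name
    return None


def fit_mlmr_interaction(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    time: str = "dpt",
    animal: str = "animal_id",
    reference: str = "control",
) -> ModelFit:
    """MLMR: value ~ group x time, random intercept per animal.

    Reports per-group time slopes, an omnibus Wald F over the
    interaction terms, and Holm-corrected pairwise post-hoc contrasts of
    group means at each observed session time.  Groups contributing
    fewer than two animals are dropped with a warning.  Censored rows
    must already be excluded by the caller.
    """
    df = data[[animal, group, time, value]].dropna().copy()
    sizes = df.groupby(group)[animal].nunique()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping groups with < 2 animals: {small}")
        df = df[~df[group].isin(small)]
    groups = sorted(df[group].unique(), key=lambda g: (g != reference, g))
    if reference not in groups:
        reference = groups[0]
    formula = f"{value} ~ C({group}, Treatment('{reference}')) * {time}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.mixedlm(formula, df, groups=df[animal]).fit(reml=False)
    names = list(res.fe_params.index)
    k = len(names)
    fe = np.asarray(res.fe_params, dtype=float)
    cov = np.asarray(res.cov_params())[:k, :k]

    def lincomb(vec):
        est = float(vec @ fe)
        se = float(np.sqrt(vec @ cov @ vec))
        return est, se

    slopes: dict[str, tuple[float, float, float]] = {}
    base_idx = names.index(time)
    for g in groups:
        vec = np.zeros(k)
        vec[base_idx] = 1.0
        if g != reference:
            term = _group_term(names, g, interaction=True)
            if term:
                vec[names.index(term)] = 1.0
        est, se = lincomb(vec)
        slopes[g] = (est, se, _zp(est, se))

    inter_idx = [i for i, n in enumerate(names) if ":" in n]
    omnibus_f = omnibus_p = None
    dfree = None
    if inter_idx:
        L = np.zeros((len(inter_idx), k))
        for r, i in enumerate(inter_idx):
            L[r, i] = 1.0
        lb = L @ fe
        lcl = L @ cov @ L.T
        chi2 = float(lb @ np.linalg.solve(lcl, lb))
        q = len(inter_idx)
        df2 = int(len(df) - k)
        omnibus_f = chi2 / q
        omnibus_p = float(sps.f.sf(omnibus_f, q, df2))
        dfree = (q, df2)

    # post-hoc family: pairwise group contrasts at matched session times
    rows = []
    times = sorted(df[time].unique())
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            for t in times:
                vec = np.zeros(k)
                for g, sign in ((g1, 1.0), (g2, -1.0)):
                    if g != reference:
                        main = _group_term(names, g, interaction=False)
                        inter = _group_term(names, g, interaction=True)
                        if main:
                            vec[names.index(main)] += sign
                        if inter:
                            vec[names.index(inter)] += sign * t
                est, se = lincomb(vec)
                rows.append(dict(contrast=f"{g1} - {g2}", dpt=float(t),
                                 estimate=est, se=se, p_raw=_zp(est, se)))
    posthoc = pd.DataFrame(rows)
    if len(posthoc):
        posthoc["p_holm"] = holm(posthoc["p_raw"].to_numpy())

    return ModelFit(
        model_kind="mlmr_interaction",
        formula_text=formula + f" + (1 | {animal})",
        slopes=slopes,
        omnibus_f=omnibus_f, omnibus_df=dfree, omnibus_p=omnibus_p,
        posthoc=posthoc,
    )


def fit_perfused_ratio(
    data: pd.DataFrame,
    perfused: str = "perfused",
    total: str = "total",
    animal: str = "animal_id",
) -> ModelFit:
    """Through-origin regression of perfused on total sprout counts.

    The slope is the perfused fraction.  With repeated measures per
    animal a mixed model with a per-animal intercept is used; when every
    animal contributes a single observation the random intercept is
    unidentifiable and the fit reduces to through-origin least squares.
    """
    df = data[[animal, perfused, total]].dropna().copy()
    if (df[total] == 0).all():
        raise DegenerateFitError("all totals are zero")
    if (df[perfused] > df[total]).any():
        raise ValueError("perfused count exceeds total count")
    formula = f"{perfused} ~ 0 + {total}"
    repeated = df.groupby(animal).size().max() > 1
    if repeated:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, df, groups=df[animal]).fit(reml=True)
        est, se, p = float(res.params[total]), float(res.bse[total]), float(res.pvalues[total])
    else:
        res = sm.OLS(df[perfused].to_numpy(dtype=float),
                     df[total].to_numpy(dtype=float)[:, None]).fit()
        est, se, p = float(res.params[0]), float(res.bse[0]), float(res.pvalues[0])
    return ModelFit(
        model_kind="through_origin_mixed",
        formula_text=formula + f" + (1 | {animal})",
        slopes={total: (est, se, p)},
    )


def wilcoxon_signed_rank(x, y, alternative: str = "two-sided") -> TestResult:
    """Paired signed-rank test; zero differences dropped by convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    nz = d[d != 0]
    if len(nz) == 0:
        return TestResult("wilcoxon", float("nan"), float("nan"),
                          flag="all pairs equal; no test")
    stat, p = sps.wilcoxon(x, y, zero_method="wilcox", alternative=alternative)
    return TestResult("wilcoxon", float(stat), float(p))


def fisher_exact_2x2(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test; an empty margin yields p = 1, flagged."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult("fisher", float("nan"), 1.0, flag="empty margin")
    stat, p = sps.fisher_exact(t, alternative=alternative)
    return TestResult("fisher", float(stat), float(p))


def fisher_exact_enumerated(table) -> float:
    """Independent two-sided Fisher p by hypergeometric enumeration.

    Oracle used to cross-check the library implementation: sums the
    probabilities of all tables (with the observed margins) whose point
    probability does not exceed the observed one.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pt(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p0 = pt(a)
    return float(sum(pt(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                     if pt(x) <= p0 * (1 + 1e-9)))


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U; exact p for small samples without ties."""
    stat, p = sps.mannwhitneyu(x, y, alternative=alternative)
    return TestResult("mannwhitney", float(stat), float(p))
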