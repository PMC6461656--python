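import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import earwound.stats as ew

warnings.filterwarnings("ignore", module="statsmodels")


# ---------------------------------------------------------------- Holm

def _holm_oracle(pvals):
    """Independent route: the adjusted p of H_i is the smallest alpha at
    which the sequential step-down procedure rejects H_i."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)

    def rejected_at(alpha):
        order = np.argsort(p, kind="stable")
        rej = np.zeros(m, bool)
        for rank, idx in enumerate(order):
            if p[idx] <= alpha / (m - rank):
                rej[idx] = True
            else:
                break
        return rej

    candidates = sorted({min(1.0, (m - r) * p[i])
                         for r, i in enumerate(np.argsort(p, kind="stable"))}
                        | {1.0})
    adj = np.ones(m)
    for i in range(m):
        for a in candidates:
            if rejected_at(a)[i]:
                adj[i] = a
                break
    return adj


def test_holm_worked_example():
    adj = ew.holm([0.01, 0.02, 0.04])
    assert np.allclose(adj, [0.03, 0.04, 0.04])


@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
def test_holm_matches_bruteforce_oracle(pvals):
    adj = ew.holm(pvals)
    oracle = _holm_oracle(pvals)
    assert np.allclose(adj, oracle, atol=1e-12)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0)


# ------------------------------------------------------- exact tests

def test_fisher_matches_hypergeometric_enumeration():
    table = [[9, 1], [2, 5]]
    res = ew.fisher_exact_2x2(table)
    assert res.pvalue == pytest.approx(ew.fisher_exact_enumerated(table), abs=1e-10)
    assert res.pvalue == pytest.approx(0.034502, abs=1e-5)


def test_fisher_empty_margin_flagged():
    res = ew.fisher_exact_2x2([[0, 0], [3, 4]])
    assert res.pvalue == 1.0 and res.flag == "empty margin"


def test_wilcoxon_all_equal_flagged():
    res = ew.wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
    assert res.flag is not None and np.isnan(res.pvalue)


def test_mann_whitney_disjoint_exact():
    res = ew.mann_whitney_u([1, 2, 3], [10, 11, 12])
    assert res.statistic == 0.0
    assert res.pvalue == pytest.approx(0.1)


# -------------------------------------------------------- model fits

def _cohort_counts(rate=1.5, n_animals=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        for t in np.arange(3.5, 6.6, 0.5):
            rows.append((f"a{a}", t, rng.poisson(rate * (t - 3.5))))
    return pd.DataFrame(rows, columns=["animal_id", "dpt", "count"])


def test_poisson_glmm_constant_counts_flat():
    df = _cohort_counts()
    df["count"] = 3
    fit = ew.fit_poisson_glmm(df)
    est, se, p = fit.slopes["count_per_dpt"]
    assert abs(est) < 2 * se + 0.05
    assert p > 0.5


def test_poisson_glmm_all_zero_degenerate():
    df = _cohort_counts()
    df["count"] = 0
    with pytest.raises(ew.DegenerateFitError):
        ew.fit_poisson_glmm(df)


def test_poisson_glmm_slope_scales_with_rate():
    lo = ew.fit_poisson_glmm(_cohort_counts(rate=1.0, n_animals=40, seed=1))
    hi = ew.fit_poisson_glmm(_cohort_counts(rate=2.0, n_animals=40, seed=2))
    e_lo, se_lo, _ = lo.slopes["count_per_dpt"]
    e_hi, se_hi, _ = hi.slopes["count_per_dpt"]
    ratio_se = 2 * (se_hi / e_lo + se_lo * e_hi / e_lo**2)
    assert abs(e_hi / e_lo - 2.0) < max(ratio_se, 0.5)


def test_lmm_exact_linear_response():
    rows = [(f"a{a}", t, 5.0 * t) for a in range(5)
            for t in np.arange(3.5, 6.6, 0.5)]
    df = pd.DataFrame(rows, columns=["animal_id", "dpt", "value"])
    fit = ew.fit_lmm(df)
    est, se, _ = fit.slopes["dpt"]
    assert est == pytest.approx(5.0, abs=1e-6)
    assert se < 1e-4


def test_lmm_too_few_animals_refused():
    df = pd.DataFrame({"animal_id": ["a0"] * 4 + ["a1"] * 4,
                       "dpt": list(range(4)) * 2, "value": np.arange(8.0)})
    with pytest.raises(ew.DegenerateFitError, match="3 animals"):
        ew.fit_lmm(df)


def test_lmm_permutation_destroys_slope(control_table):
    from earwound.analysis import control_lengths
    df = control_lengths(control_table).reset_index(drop=True)
    rng = np.random.default_rng(0)
    n_null = 0
    n_perm = 50
    for _ in range(n_perm):
        perm = df.copy()
        perm["dpt"] = rng.permutation(perm["dpt"].to_numpy())
        fit = ew.fit_lmm(perm)
        n_null += fit.slopes["dpt"][2] > 0.05
    assert n_null >= int(0.9 * n_perm)


def test_perfused_ratio_exact_and_relabel_invariant():
    df = pd.DataFrame({"animal_id": [f"a{i}" for i in range(8)],
                       "total": [2, 4, 6, 3, 5, 7, 8, 4]})
    df["perfused"] = df["total"]
    fit = ew.fit_perfused_ratio(df)
    assert fit.slopes["total"][0] == pytest.approx(1.0)

    df["perfused"] = [1, 3, 4, 2, 3, 5, 5, 3]
    a = ew.fit_perfused_ratio(df).slopes["total"][0]
    df2 = df.copy()
    df2["animal_id"] = [f"z{i}" for i in range(8)][::-1]
    b = ew.fit_perfused_ratio(df2).slopes["total"][0]
    assert a == pytest.approx(b)


def test_perfused_ratio_validates_counts():
    df = pd.DataFrame({"animal_id": ["a0"], "total": [2], "perfused": [3]})
    with pytest.raises(ValueError):
        ew.fit_perfused_ratio(df)
    df = pd.DataFrame({"animal_id": ["a0", "a1"], "total": [0, 0],
                       "perfused": [0, 0]})
    with pytest.raises(ew.DegenerateFitError):
        ew.fit_perfused_ratio(df)


def test_mlmr_relabeled_clone_shows_no_interaction():
    """Identical data relabelled into two groups: interaction is null."""
    base = _cohort_counts(rate=1.5, n_animals=8, seed=3)
    dup = base.copy()
    dup["animal_id"] = dup["animal_id"] + "x"
    base["group"] = "control"
    dup["group"] = "sunitinib"
    df = pd.concat([base, dup]).rename(columns={"count": "value"})
    fit = ew.fit_mlmr_interaction(df)
    assert fit.omnibus_p > 0.01
    assert fit.slopes["control"][0] == pytest.approx(fit.slopes["sunitinib"][0],
                                                     abs=1e-6)
    assert (fit.posthoc["p_holm"] >= fit.posthoc["p_raw"] - 1e-12).all()


def test_mlmr_detects_group_by_time_interaction(four_group_table):
    t = four_group_table
    df = t[(t["metric"] == "sprout_count_distal") & (t["dpt"] <= 6.5)]
    fit = ew.fit_mlmr_interaction(df.dropna(subset=["value"]))
    assert fit.omnibus_p < 0.05
    assert fit.slopes["combo"][0] < fit.slopes["control"][0]
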