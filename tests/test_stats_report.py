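import itertools

import numpy as np
import pandas as pd
import pytest

from steppekin import stats_report as sr
from steppekin.io_formats import SurveyRecord


def _mwu_enumeration_oracle(x, y, alternative):
    """Brute-force label enumeration (valid with ties)."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    u_obs = sr._mwu_u(np.asarray(x, float), np.asarray(y, float))
    ge = le = total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        u = sr._mwu_u(pooled[mask], pooled[~mask])
        ge += u >= u_obs
        le += u <= u_obs
        total += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


def test_mwu_small_exact_example():
    res = sr.mwu([1, 2], [3, 4], alternative="two-sided")
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1 / 3)


def test_mwu_identical_multisets_p_one():
    res = sr.mwu([1, 2, 2, 5], [1, 2, 2, 5])
    assert res.p_value == pytest.approx(1.0)


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
def test_mwu_matches_enumeration_oracle(alternative):
    rng = np.random.default_rng(0)
    for _ in range(16):
        nx, ny = rng.integers(2, 6, size=2)
        # mixed continuous/tied data
        x = rng.choice([0.0, 1.0, 2.5, 3.7, 9.0], size=nx)
        y = rng.choice([0.0, 1.0, 2.5, 3.7, 9.0], size=ny)
        got = sr.mwu(x, y, alternative=alternative).p_value
        want = _mwu_enumeration_oracle(x, y, alternative)
        assert got == pytest.approx(want, abs=1e-12)


def test_mwu_tie_free_matches_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(10):
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        got = sr.mwu(x, y).p_value
        want = _mwu_enumeration_oracle(x, y, "two-sided")
        assert got == pytest.approx(want, abs=1e-12)


def test_mwu_one_tailed_le_two_tailed_in_direction():
    rng = np.random.default_rng(2)
    x = rng.normal(1.0, 1, size=30)
    y = rng.normal(0.0, 1, size=30)
    p1 = sr.mwu(x, y, alternative="greater").p_value
    p2 = sr.mwu(x, y, alternative="two-sided").p_value
    assert p1 <= p2


def test_mwu_large_sample_normal_path():
    rng = np.random.default_rng(3)
    x = rng.normal(0.5, 1, size=40)
    y = rng.normal(0.0, 1, size=40)
    res = sr.mwu(x, y, alternative="greater")
    from scipy.stats import mannwhitneyu

    ref = mannwhitneyu(x, y, alternative="greater", method="asymptotic",
                       use_continuity=False)
    assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-6)


def test_spearman_monotone_extremes():
    x = [1, 2, 3, 4, 5]
    assert sr.spearman(x, [2, 4, 9, 16, 30]).statistic == pytest.approx(1.0)
    assert sr.spearman(x, [30, 16, 9, 4, 2]).statistic == pytest.approx(-1.0)


def test_spearman_exact_permutation_n5():
    rng = np.random.default_rng(4)
    x = rng.normal(size=5)
    y = rng.normal(size=5)
    got = sr.spearman(x, y)
    # independent oracle: all 120 permutations of y
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    for perm in itertools.permutations(ry):
        if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho_obs) - 1e-12:
            count += 1
    assert got.p_value == pytest.approx(count / 120)


def test_chi2_yates_examples():
    res = sr.chi2_yates([[10, 10], [10, 10]])
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)
    res = sr.chi2_yates([[20, 0], [0, 20]])
    # closed form: 4 * (|20-10| - 0.5)^2 / 10
    assert res.statistic == pytest.approx(36.1)
    assert res.p_value < 1e-8
    t = [[13, 7], [4, 16]]
    assert sr.chi2_yates(t).statistic == pytest.approx(
        sr.chi2_yates(np.array(t).T.tolist()).statistic
    )


def test_regression_exact_fit_and_anova_identity():
    df = pd.DataFrame({"x": np.arange(10.0), "z": np.arange(10.0)[::-1]})
    df["outcome"] = 2.0 * df["x"]
    rep = sr.regress_confounders(df, "outcome", ["x"], combinations=[["x", "z"]])
    single = rep["single"]["x"]
    assert single["params"]["Q('x')"] == pytest.approx(2.0)
    assert single["r_squared"] == pytest.approx(1.0)
    anova = rep["multiple"][("x", "z")]["anova"]
    total_ss = float(((df["outcome"] - df["outcome"].mean()) ** 2).sum())
    assert float(anova["sum_sq"].sum()) == pytest.approx(total_ss)


def test_regression_null_pvalues_uniform():
    """Slope p-values under a permuted (null) covariate are ~Uniform(0,1)."""
    from scipy.stats import kstest

    rng = np.random.default_rng(5)
    pvals = []
    for _ in range(200):
        df = pd.DataFrame({"x": rng.normal(size=12),
                           "outcome": rng.normal(size=12)})
        rep = sr.regress_confounders(df, "outcome", ["x"])
        pvals.append(rep["single"]["x"]["pvalues"]["Q('x')"])
    assert kstest(pvals, "uniform").pvalue > 0.01


def _report_inputs(n=40, seed=0):
    rng = np.random.default_rng(seed)
    survey, fit_rows, roh_rows = [], [], []
    for i in range(n):
        iid = f"i{i}"
        d = float(rng.lognormal(np.log(10), 1.2))
        m_lat = 45.0 + d / 111.195
        survey.append(SurveyRecord(iid, "M", "P1", "TM", (45.0, 75.0), None,
                                   (45.0, 75.0), (m_lat, 75.0)))
        fit_rows.append({"individual_id": iid,
                         "F_Median": float(rng.exponential(0.02)),
                         "inbred": bool(rng.random() < 0.3)})
        roh_rows.append({"individual_id": iid,
                         "classC_count": int(rng.poisson(2)),
                         "classC_kb": float(rng.exponential(3000))})
    return survey, pd.DataFrame(fit_rows), pd.DataFrame(roh_rows)


def test_report_join_is_lossless_and_deterministic():
    survey, fits, rohs = _report_inputs()
    rep1 = sr.exogamy_inbreeding_report(survey, fits, rohs)
    rep2 = sr.exogamy_inbreeding_report(survey, fits, rohs)
    assert len(rep1.table) == len(fits)  # all parental birthplaces present
    assert rep1.n_excluded == 0
    pd.testing.assert_frame_equal(rep1.table, rep2.table)
    pd.testing.assert_frame_equal(rep1.bins, rep2.bins)
    assert {r for r in rep1.bins["distance_class"]} == {"<4", "4-20", "20-40",
                                                        ">40"}
    for key, res in rep1.mwu_vs_endogamous.items():
        assert 0.0 <= res.p_value <= 1.0


def test_report_excludes_missing_parental_birthplaces():
    survey, fits, rohs = _report_inputs(n=10)
    survey[0].mother_birthplace = None
    rep = sr.exogamy_inbreeding_report(survey, fits, rohs)
    assert rep.n_excluded == 1
    assert len(rep.table) == 9


def test_population_summary_both_definitions():
    fits = pd.DataFrame({
        "population": ["P1"] * 4 + ["P2"] * 4,
        "F_Median": [0.0, 0.02, 0.05, 0.0, 0.0, 0.0, 0.01, 0.0],
        "inbred": [False, True, True, False, False, False, True, False],
    })
    summ = sr.population_summary(fits)
    p1 = summ[summ["population"] == "P1"].iloc[0]
    assert p1["pct_positive_F"] == pytest.approx(50.0)
    assert p1["pct_lrt_inbred"] == pytest.approx(50.0)
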