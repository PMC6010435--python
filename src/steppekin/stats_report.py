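"""Comparison layer: rank tests, correlations, confounder regressions and
the distance-binned exogamy-vs-inbreeding report.

The headline analysis joins, per individual, the parental-couple distance
(from the survey) with three inbreeding measures (F-Median, number of
class-C ROHs, total class-C ROH kb), bins individuals into the four parental
distance classes (<4, 4-20, 20-40, >40 km) and contrasts each exogamous
class against the endogamous (<4 km) class with Mann-Whitney U tests —
the design that exposes a bell-shaped distance/inbreeding relationship when
kinship endogamy operates at intermediate distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geo_exogamy import DISTANCE_CLASSES, couple_distances, distance_class
from .io_formats import SurveyRecord

MEASURES = ["F_Median", "classC_count", "classC_kb"]


@dataclass
class ComparisonResult:
    test: str
    groups: tuple[str, str] | str
    statistic: float
    p_value: float
    alternative: str = "two-sided"
    n: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# Rank tests


def _mwu_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x (ties counted half)."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def mwu(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> ComparisonResult:
    """Mann-Whitney U test.

    Exact when the sample product n_x * n_y <= 400 (full exact null
    distribution without ties; exhaustive group-label enumeration with ties
    when the number of splits is tractable); otherwise the tie-corrected
    normal approximation. ``alternative='greater'`` tests whether x tends to
    exceed y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    u = _mwu_u(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = nx * ny <= 400

    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
        p = float(res.pvalue)
    elif small and math.comb(nx + ny, nx) <= 200_000:
        # exhaustive enumeration of group labelings (valid under ties)
        ge = le = total = 0
        for comb in itertools.combinations(range(nx + ny), nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(comb)] = True
            u_perm = _mwu_u(pooled[mask], pooled[~mask])
            ge += u_perm >= u
            le += u_perm <= u
            total += 1
        if alternative == "greater":
            p = ge / total
        elif alternative == "less":
            p = le / total
        else:
            p = min(1.0, 2.0 * min(ge, le) / total)
    else:
        mu = nx * ny / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = nx + ny
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u - mu) / math.sqrt(var)
            if alternative == "greater":
                p = float(stats.norm.sf(z))
            elif alternative == "less":
                p = float(stats.norm.cdf(z))
            else:
                p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(
        test="MWU", groups=("x", "y"), statistic=u, p_value=min(p, 1.0),
        alternative=alternative, n=(nx, ny),
    )


def spearman(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> ComparisonResult:
    """Spearman rank correlation (average ranks for ties).

    Exact permutation p-value for n <= 8, t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length samples with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return ComparisonResult(
            test="Spearman", groups=("x", "y"), statistic=math.nan,
            p_value=math.nan, alternative=alternative, n=(n,),
        )
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        count = total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.array(perm))[0, 1])
            if alternative == "greater":
                count += r >= rho - 1e-12
            elif alternative == "less":
                count += r <= rho + 1e-12
            else:
                count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    else:
        res = stats.spearmanr(x, y, alternative=alternative)
        p = float(res.pvalue)
    return ComparisonResult(
        test="Spearman", groups=("x", "y"), statistic=rho, p_value=min(p, 1.0),
        alternative=alternative, n=(n,),
    )


def chi2_yates(table: Sequence[Sequence[float]]) -> ComparisonResult:
    """Yates-corrected chi-squared test of independence for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=True)
    return ComparisonResult(
        test="chi2-Yates", groups="2x2", statistic=float(stat), p_value=float(p),
        n=(int(t.sum()),),
    )


# ---------------------------------------------------------------------------
# Regressions


def regress_confounders(
    pop_table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    combinations: Optional[Sequence[Sequence[str]]] = None,
) -> dict:
    """Per-population confounder analysis of an outcome.

    Fits each covariate alone (OLS; categorical covariates one-hot encoded
    with a reference level), then every requested covariate combination as a
    multiple regression with its ANOVA table. Returns a nested report dict.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    def q(name: str) -> str:
        cat = pop_table[name].dtype == object or str(
            pop_table[name].dtype
        ).startswith("category")
        return f"C(Q('{name}'))" if cat else f"Q('{name}')"

    report: dict = {"single": {}, "multiple": {}}
    for cov in covariates:
        model = smf.ols(f"Q('{outcome}') ~ {q(cov)}", data=pop_table).fit()
        report["single"][cov] = {
            "params": model.params.to_dict(),
            "pvalues": model.pvalues.to_dict(),
            "r_squared": float(model.rsquared),
            "f_pvalue": float(model.f_pvalue),
        }
    for comb in combinations or []:
        rhs = " + ".join(q(c) for c in comb)
        model = smf.ols(f"Q('{outcome}') ~ {rhs}", data=pop_table).fit()
        anova = anova_lm(model, typ=1)
        report["multiple"][tuple(comb)] = {
            "params": model.params.to_dict(),
            "pvalues": model.pvalues.to_dict(),
            "r_squared": float(model.rsquared),
            "anova": anova,
        }
    return report


# ---------------------------------------------------------------------------
# Distance-binned exogamy/inbreeding report


@dataclass
class ExogamyInbreedingReport:
    table: pd.DataFrame  # one row per individual with distance + measures
    bins: pd.DataFrame  # median/quartiles of each measure per distance class
    mwu_vs_endogamous: dict[tuple[str, str], ComparisonResult]
    spearman_exogamous: dict[str, ComparisonResult]
    n_excluded: int


def exogamy_inbreeding_report(
    survey: Sequence[SurveyRecord],
    fits: pd.DataFrame,
    roh: Optional[pd.DataFrame] = None,
    alternative: str = "greater",
    measures: Optional[Sequence[str]] = None,
) -> ExogamyInbreedingReport:
    """Distance-binned inbreeding comparison across parental-distance classes.

    ``fits`` needs columns ``individual_id, F_Median`` (``inbred`` optional);
    ``roh`` needs ``individual_id, classC_count, classC_kb``. Individuals
    without both parental birthplaces are excluded (counted). For each
    exogamous class a MWU against the <4 km class is computed per measure
    (``alternative`` states the configured direction: 'greater' asks whether
    the exogamous class is *more* inbred), plus Spearman correlations of
    log10 parental distance with each measure among exogamous individuals.
    """
    parental = {
        cd.couple_id.split(":", 1)[1]: cd.distance_km
        for cd in couple_distances(survey, "parental")
    }
    n_excluded = len(survey) - len(parental)

    df = fits.copy()
    if roh is not None:
        df = df.merge(roh, on="individual_id", how="left")
    df["parental_distance_km"] = df["individual_id"].map(parental)
    df = df.dropna(subset=["parental_distance_km"]).reset_index(drop=True)
    df["distance_class"] = df["parental_distance_km"].map(distance_class)

    use = [m for m in (measures or MEASURES) if m in df.columns]
    if not use:
        raise ValueError("no inbreeding measure columns found")

    rows = []
    for cls in DISTANCE_CLASSES:
        sub = df[df["distance_class"] == cls]
        row: dict = {"distance_class": cls, "n": len(sub)}
        for m in use:
            v = sub[m].dropna()
            row[f"{m}_median"] = float(v.median()) if len(v) else math.nan
            row[f"{m}_q25"] = float(v.quantile(0.25)) if len(v) else math.nan
            row[f"{m}_q75"] = float(v.quantile(0.75)) if len(v) else math.nan
        rows.append(row)
    bins = pd.DataFrame(rows)

    endo = df[df["distance_class"] == "<4"]
    mwu_res: dict[tuple[str, str], ComparisonResult] = {}
    for cls in DISTANCE_CLASSES[1:]:
        sub = df[df["distance_class"] == cls]
        for m in use:
            a = sub[m].dropna().to_numpy()
            b = endo[m].dropna().to_numpy()
            if len(a) and len(b):
                res = mwu(a, b, alternative=alternative)
                res = ComparisonResult(
                    test="MWU", groups=(cls, "<4"), statistic=res.statistic,
                    p_value=res.p_value, alternative=alternative,
                    n=(len(a), len(b)),
                )
                mwu_res[(cls, m)] = res

    exo = df[df["parental_distance_km"] > 4.0]
    sp_res: dict[str, ComparisonResult] = {}
    for m in use:
        sub = exo.dropna(subset=[m])
        if len(sub) >= 3:
            sp_res[m] = spearman(
                np.log10(sub["parental_distance_km"].to_numpy()),
                sub[m].to_numpy(),
            )
    return ExogamyInbreedingReport(
        table=df, bins=bins, mwu_vs_endogamous=mwu_res,
        spearman_exogamous=sp_res, n_excluded=n_excluded,
    )


def population_summary(
    fits: pd.DataFrame, group_col: str = "population"
) -> pd.DataFrame:
    """Percent inbred per population, both ways the field defines it:
    positive F-Median, and the likelihood-ratio-test call."""
    def agg(sub: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n": len(sub),
                "pct_positive_F": 100.0 * float((sub["F_Median"] > 0).mean()),
                "pct_lrt_inbred": (
                    100.0 * float(sub["inbred"].mean())
                    if "inbred" in sub else math.nan
                ),
                "median_F_Median": float(sub["F_Median"].median()),
            }
        )

    return fits.groupby(group_col).apply(agg, include_groups=False).reset_index()
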