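"""Cohort statistics for the emphysema-heterogeneity analysis.

Covers the full analysis pipeline applied to a subject table: exclusion
rules (bronchodilator response, chronic bronchitis), GOLD spirometric
staging, descriptive summaries, nonparametric group comparisons
(Wilcoxon rank-sum, one-sample chi-square on the upper-dominant
proportion, paired sign test between lungs), piecewise linear regression
of lung function on HI% with a knot at zero, covariate-adjusted multiple
linear regression, and multiple logistic regression for severe (GOLD
III–IV) disease.

Cohorts are plain :class:`pandas.DataFrame` tables using the column
schema of :mod:`emphyhet.io`.  Model fitting is delegated to statsmodels;
the hinge-term construction (HI⁺ = max(0, HI), HI⁻ = min(0, HI)) and the
study-specific conventions live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

PF_OUTCOMES = ("fev1_pct_pred", "fev1_fvc_pct", "rv_tlc_pct", "dlco_pct_pred")
ADJUST_COVARIATES = ("laa_pct", "age", "male", "pack_years")
GOLD_STAGES = ("none", "I", "II", "III", "IV")


class SeparationError(RuntimeError):
    """Logistic fit failed because the outcome is perfectly separated."""


# ---------------------------------------------------------------------------
# Exclusions and staging
# ---------------------------------------------------------------------------


def bronchodilator_response(pre_l: float, post_l: float) -> bool:
    """Positive response: FEV1 increase >= 200 ml AND >= 12% of baseline."""
    delta = post_l - pre_l
    return bool(delta >= 0.2 and delta / pre_l >= 0.12)


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop bronchodilator responders (COPD arm) and chronic-bronchitis subjects.

    A subject with CB = "yes" *or with no CB information* is excluded; a
    COPD subject missing pre/post spirometry is excluded with reason
    ``missing_spirometry``.  Returns the filtered cohort and a disposition
    log whose exclusion counts sum to the input n.
    """
    df = records.copy()
    n_in = len(df)
    reasons = pd.Series("retained", index=df.index, dtype=object)

    is_copd = df["copd"].astype(int) == 1
    pre = pd.to_numeric(df.get("fev1_pre_l"), errors="coerce")
    post = pd.to_numeric(df.get("fev1_post_l"), errors="coerce")
    spiro_missing = is_copd & (pre.isna() | post.isna() | (pre <= 0))
    reasons[spiro_missing] = "missing_spirometry"

    with np.errstate(invalid="ignore", divide="ignore"):
        br = is_copd & ~spiro_missing & (post - pre >= 0.2) & ((post - pre) / pre >= 0.12)
    reasons[br] = "bronchodilator_response"

    cb = df["cb"].astype(object).where(df["cb"].notna(), "")
    cb_bad = (reasons == "retained") & ((cb == "yes") | (cb.astype(str).str.strip() == ""))
    reasons[cb_bad] = "chronic_bronchitis_or_unknown"

    kept = df[reasons == "retained"].copy()
    disposition = {
        "input": n_in,
        "bronchodilator_response": int((reasons == "bronchodilator_response").sum()),
        "chronic_bronchitis_or_unknown": int((reasons == "chronic_bronchitis_or_unknown").sum()),
        "missing_spirometry": int((reasons == "missing_spirometry").sum()),
        "retained": len(kept),
    }
    return kept, disposition


def gold_stage(fev1_pct_pred: float, fev1_fvc: float) -> str:
    """GOLD spirometric stage from post-bronchodilator values.

    ``fev1_fvc`` may be a ratio (0.61) or a percentage (61).  Returns
    "none" when FEV1/FVC >= 0.70, else stages I/II/III/IV at the standard
    80/50/30 FEV1%-predicted breakpoints.
    """
    if not (np.isfinite(fev1_pct_pred) and np.isfinite(fev1_fvc)):
        raise ValueError("non-finite spirometry value")
    ratio = fev1_fvc / 100.0 if fev1_fvc > 1.5 else fev1_fvc
    if ratio >= 0.70:
        return "none"
    if fev1_pct_pred >= 80:
        return "I"
    if fev1_pct_pred >= 50:
        return "II"
    if fev1_pct_pred >= 30:
        return "III"
    return "IV"


# ---------------------------------------------------------------------------
# Descriptive summaries and group tests
# ---------------------------------------------------------------------------

SUMMARY_CONTINUOUS = (
    "age", "pack_years", "fev1_pct_pred", "fev1_fvc_pct",
    "rv_tlc_pct", "dlco_pct_pred", "laa_pct", "hi_pct",
)
SUMMARY_CATEGORICAL = ("male", "gold_stage")


def _median_iqr(x: pd.Series) -> tuple[float, float, float]:
    x = pd.to_numeric(x, errors="coerce").dropna()
    return (float(x.median()), float(x.quantile(0.25)), float(x.quantile(0.75)))


def summarize_cohort(
    records: pd.DataFrame,
    continuous: tuple[str, ...] = SUMMARY_CONTINUOUS,
    categorical: tuple[str, ...] = SUMMARY_CATEGORICAL,
) -> pd.DataFrame:
    """Characteristics table: median (Q1, Q3) / frequency (%) per variable."""
    if records.empty:
        raise ValueError("empty cohort")
    n = len(records)
    rows = []
    for var in continuous:
        med, q1, q3 = _median_iqr(records[var])
        rows.append({
            "variable": var, "level": "", "n": int(records[var].notna().sum()),
            "median": med, "q1": q1, "q3": q3, "count": np.nan, "pct": np.nan,
            "display": f"{med:g}({q1:g},{q3:g})",
        })
    for var in categorical:
        counts = records[var].value_counts()
        for level, k in counts.items():
            rows.append({
                "variable": var, "level": str(level), "n": n,
                "median": np.nan, "q1": np.nan, "q3": np.nan,
                "count": int(k), "pct": 100.0 * k / n,
                "display": f"{k}({100.0 * k / n:.0f}%)",
            })
    return pd.DataFrame(rows)


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: int
    detail: dict = field(default_factory=dict)


def proportion_positive_test(hi_values: "pd.Series | np.ndarray") -> TestResult:
    """One-sample chi-square: is the share of HI > 0 different from 50%?"""
    hi = np.asarray(pd.to_numeric(pd.Series(hi_values), errors="coerce").dropna())
    n = len(hi)
    if n == 0:
        raise ValueError("no HI values")
    k = int((hi > 0).sum())
    chi2 = (k - n / 2) ** 2 / (n / 2) + ((n - k) - n / 2) ** 2 / (n / 2)
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult("one-sample chi-square", float(chi2), p, n,
                      {"n_positive": k, "proportion": k / n})


def left_right_sign_test(left: np.ndarray, right: np.ndarray) -> TestResult:
    """Two-sided sign test on paired left−right HI differences (zeros dropped)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right must be paired")
    diff = left - right
    diff = diff[np.isfinite(diff)]
    nonzero = diff[diff != 0]
    m = len(nonzero)
    if m == 0:
        warnings.warn("all paired differences are zero; sign test is degenerate")
        return TestResult("sign test", 0.0, 1.0, len(diff), {"n_positive": 0})
    k = int((nonzero > 0).sum())
    p = float(sps.binomtest(k, m, 0.5).pvalue)
    return TestResult("sign test", float(k), p, m, {"n_positive": k, "n_nonzero": m})


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney).

    Exact null distribution for small tie-free samples (both n <= 25),
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("Wilcoxon rank-sum", float(res.statistic), float(res.pvalue),
                      len(x) + len(y), {"method": method})


def chi2_2x2(table: np.ndarray, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table (no continuity correction by default)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return TestResult("Pearson chi-square", float(chi2), float(p), int(table.sum()))


@dataclass
class GroupComparison:
    variable: str
    group_stats: dict[str, dict[str, float]]  # group label -> n/median/q1/q3
    test: str
    p_value: float


def compare_groups(
    records: pd.DataFrame,
    variables: tuple[str, ...] = PF_OUTCOMES,
    yates: bool = False,
) -> list[GroupComparison]:
    """Compare lung function between lower- (HI <= 0) and upper- (HI > 0)
    dominant subjects; plus a chi-square on the GOLD I–II vs III–IV dichotomy
    when staged subjects are present."""
    upper = records["hi_pct"] > 0
    groups = {"HI<=0": records[~upper], "HI>0": records[upper]}
    out: list[GroupComparison] = []
    for var in variables:
        samples = {
            g: pd.to_numeric(d[var], errors="coerce").dropna() for g, d in groups.items()
        }
        stats = {
            g: dict(zip(("n", "median", "q1", "q3"), (len(s), *_median_iqr(s)[0:3])))
            if len(s) else {"n": 0}
            for g, s in samples.items()
        }
        if any(len(s) == 0 for s in samples.values()):
            warnings.warn(f"{var}: a dominance group is empty; comparison skipped")
            out.append(GroupComparison(var, stats, "Wilcoxon rank-sum", np.nan))
            continue
        res = wilcoxon_rank_sum(samples["HI<=0"], samples["HI>0"])
        out.append(GroupComparison(var, stats, res.test, res.p_value))

    staged = records[records["gold_stage"].isin(["I", "II", "III", "IV"])]
    if len(staged):
        severe = staged["gold_stage"].isin(["III", "IV"])
        up = staged["hi_pct"] > 0
        table = np.array([
            [int((~up & ~severe).sum()), int((up & ~severe).sum())],
            [int((~up & severe).sum()), int((up & severe).sum())],
        ])
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            res = chi2_2x2(table, correction=yates)
            stats = {
                "HI<=0": {"n": int(table[:, 0].sum()), "gold_iii_iv": int(table[1, 0])},
                "HI>0": {"n": int(table[:, 1].sum()), "gold_iii_iv": int(table[1, 1])},
            }
            out.append(GroupComparison("gold_iii_iv", stats, res.test, res.p_value))
        else:
            warnings.warn("GOLD dichotomy table has an empty margin; comparison skipped")
    return out


# ---------------------------------------------------------------------------
# Regression models
# ---------------------------------------------------------------------------


def hinge_terms(hi: "pd.Series | np.ndarray") -> pd.DataFrame:
    """Piecewise design terms with a knot at zero: HI⁺ and HI⁻."""
    hi = np.asarray(hi, dtype=float)
    return pd.DataFrame({"hi_pos": np.maximum(hi, 0.0), "hi_neg": np.minimum(hi, 0.0)})


@dataclass
class FitResult:
    """Coefficients (or odds ratios), 95% CIs and p-values of one model."""

    family: str  # "linear" | "logistic"
    outcome: str
    table: pd.DataFrame  # index: term; columns: estimate, ci_low, ci_high, p_value
    n: int
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _ols_fit_table(model: sm.OLS) -> tuple[pd.DataFrame, "sm.regression.linear_model.RegressionResults"]:
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "estimate": res.params,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p_value": res.pvalues,
    })
    return table, res


def fit_piecewise_univariate(
    records: pd.DataFrame,
    outcome: str,
    min_per_side: int = 3,
    constrain_equal_slopes: bool = False,
) -> FitResult:
    """Least-squares fit of ``outcome ~ HI⁺ + HI⁻`` (knot at zero).

    With ``constrain_equal_slopes`` the two slopes are forced equal,
    which reduces the model to ordinary linear regression on HI.
    Confidence intervals are t-based.
    """
    data = records[[outcome, "hi_pct"]].apply(pd.to_numeric, errors="coerce").dropna()
    y = data[outcome].to_numpy()
    hinge = hinge_terms(data["hi_pct"])
    warns: list[str] = []
    if constrain_equal_slopes:
        X = pd.DataFrame({"hi": data["hi_pct"].to_numpy()})
    else:
        X = hinge
        n_pos = int((data["hi_pct"] > 0).sum())
        n_neg = int((data["hi_pct"] < 0).sum())
        if min(n_pos, n_neg) == 0:
            raise np.linalg.LinAlgError(
                f"piecewise design is rank deficient: no subjects on one side of 0 "
                f"({n_pos} positive, {n_neg} negative)"
            )
        if min(n_pos, n_neg) < min_per_side:
            warns.append(f"only {min(n_pos, n_neg)} subjects on one side of the knot")
    X = sm.add_constant(X.reset_index(drop=True))
    table, _ = _ols_fit_table(sm.OLS(y, X))
    return FitResult("linear", outcome, table, n=len(y), warnings=warns)


def fit_adjusted_linear(records: pd.DataFrame, outcome: str) -> FitResult:
    """Multiple linear regression of a lung-function outcome on LAA%, the
    HI hinge terms, age, sex and pack-years (complete cases only)."""
    cols = [outcome, "hi_pct", *ADJUST_COVARIATES]
    data = records[cols].apply(pd.to_numeric, errors="coerce").dropna()
    k = 6  # design columns excluding intercept
    if len(data) < k + 2:
        raise ValueError(f"only {len(data)} complete cases for {k + 1} parameters")
    X = pd.concat(
        [
            data[["laa_pct"]].reset_index(drop=True),
            hinge_terms(data["hi_pct"]),
            data[["age", "male", "pack_years"]].reset_index(drop=True),
        ],
        axis=1,
    )
    X = sm.add_constant(X)
    table, _ = _ols_fit_table(sm.OLS(data[outcome].to_numpy(), X))
    return FitResult("linear", outcome, table, n=len(data))


def fit_logistic_gold(records: pd.DataFrame) -> FitResult:
    """Multiple logistic regression for severe COPD (GOLD III–IV).

    Fits 1{GOLD in III–IV} on LAA%, HI⁺, HI⁻, age, sex and pack-years
    among staged (GOLD I–IV) subjects; reports odds ratios with Wald 95%
    CIs on the log-odds scale.  Perfect separation raises
    :class:`SeparationError` instead of diverging silently.
    """
    staged = records[records["gold_stage"].isin(["I", "II", "III", "IV"])]
    cols = ["hi_pct", *ADJUST_COVARIATES]
    data = staged[cols + ["gold_stage"]].dropna(subset=cols)
    if data.empty:
        raise ValueError("no staged COPD subjects")
    y = data["gold_stage"].isin(["III", "IV"]).astype(int).to_numpy()
    if y.min() == y.max():
        raise SeparationError("outcome is constant; odds are degenerate")
    X = pd.concat(
        [
            data[["laa_pct"]].reset_index(drop=True),
            hinge_terms(data["hi_pct"]),
            data[["age", "male", "pack_years"]].reset_index(drop=True),
        ],
        axis=1,
    )
    X = sm.add_constant(X)
    try:
        with warnings.catch_warnings():
            # a few perfectly-predicted observations are tolerable as long as
            # the likelihood still identifies every coefficient; true
            # separation is caught below via convergence / SE diagnostics
            warnings.simplefilter("ignore", category=PerfectSeparationWarning)
            warnings.simplefilter("ignore", category=RuntimeWarning)
            model = sm.Logit(y, X)
            try:
                res = model.fit(disp=0, maxiter=200)
            except np.linalg.LinAlgError:
                # Newton's Hessian can go singular near the optimum on
                # heavy-tailed designs; BFGS avoids the inversion
                res = model.fit(method="bfgs", disp=0, maxiter=500)
    except PerfectSeparationError as exc:
        raise SeparationError(str(exc)) from exc
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular design: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge (possible separation)")
    if not np.isfinite(res.params).all() or not np.isfinite(res.bse).all():
        raise SeparationError("non-finite estimates or standard errors (separation)")
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "estimate": np.exp(res.params),
        "ci_low": np.exp(ci[0]),
        "ci_high": np.exp(ci[1]),
        "p_value": res.pvalues,
    })
    return FitResult("logistic", "gold_iii_iv", table, n=len(y))
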