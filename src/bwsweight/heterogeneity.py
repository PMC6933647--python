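"""Covariate heterogeneity in respondent-level utilities.

The testing cascade mirrors common practice for preference heterogeneity:

1. :func:`screen_interactions` — each covariate is tested independently for
   a joint shift of the whole respondent-level utility vector (multivariate
   general linear hypothesis, Wilks' lambda with Rao's F approximation) at
   a Bonferroni-adjusted threshold ``alpha / n_covariates`` (0.05/10 = 0.005
   for the ten-covariate screen); survivors are re-tested jointly in one
   multivariate model at the same threshold.
2. :func:`stratified_anova` — classical one-way ANOVA of a single outcome's
   respondent-level utilities across covariate strata.
3. :func:`tukey_kramer` — studentized-range post-hoc pairwise comparisons
   honoring unequal group sizes.
4. :func:`experienced_vs_not` — equal-variance two-sample t-test comparing
   respondents who did and did not experience the outcome.

Respondent-level utilities here are posterior means from the hierarchical
fit (one row per respondent, one column per non-reference outcome), which
matches the mean (SD) presentation of stratified utility tables.  Testing
posterior means in a second stage is a tractable approximation to in-model
interaction testing and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DEFAULT_ALPHA = 0.05
#: Covariates with at most this many distinct values are treated as factors.
MAX_FACTOR_LEVELS = 10


# ---------------------------------------------------------------------------
# multivariate general linear hypothesis (Wilks' lambda, Rao's F)
# ---------------------------------------------------------------------------

def _wilks_test(y: np.ndarray, x: np.ndarray, test_cols: Sequence[int]):
    """Test that the coefficient rows ``test_cols`` of a multivariate OLS
    fit are jointly zero.  Returns (wilks_lambda, F, df1, df2, p).
    """
    n, p = y.shape
    r = np.linalg.matrix_rank(x)
    v = n - r  # error df
    if v <= p:
        raise ValueError("too few observations for the multivariate test")
    xtx_inv = np.linalg.pinv(x.T @ x)
    b = xtx_inv @ x.T @ y
    resid = y - x @ b
    e = resid.T @ resid
    l_rows = np.zeros((len(test_cols), x.shape[1]))
    for i, c in enumerate(test_cols):
        l_rows[i, c] = 1.0
    lb = l_rows @ b
    middle = np.linalg.pinv(l_rows @ xtx_inv @ l_rows.T)
    h = lb.T @ middle @ lb
    q = len(test_cols)  # hypothesis df
    sign_e, logdet_e = np.linalg.slogdet(e)
    sign_eh, logdet_eh = np.linalg.slogdet(e + h)
    if sign_e <= 0 or sign_eh <= 0:
        raise ValueError("singular residual covariance; cannot test")
    lam = float(np.exp(logdet_e - logdet_eh))
    # Rao's F approximation
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    else:
        t = 1.0
    w = v - (p - q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f_stat = (1 - lam_t) / lam_t * (df2 / df1)
    p_val = float(stats.f.sf(f_stat, df1, df2))
    return lam, float(f_stat), df1, float(df2), p_val


def _encode(series: pd.Series) -> tuple[np.ndarray, int]:
    """Design columns (no intercept) for one covariate; returns (cols, k)."""
    if (
        series.dtype == object
        or isinstance(series.dtype, pd.CategoricalDtype)
        or series.dtype == bool
        or series.nunique() <= MAX_FACTOR_LEVELS
    ):
        dummies = pd.get_dummies(series.astype("category"), drop_first=True)
        return dummies.to_numpy(dtype=float), dummies.shape[1]
    vals = series.to_numpy(dtype=float)
    return (vals - vals.mean())[:, None], 1


@dataclass
class ScreeningResult:
    """Outcome of the Bonferroni interaction screen."""

    p_values: dict[str, float]
    screened: tuple[str, ...]
    joint_p_values: dict[str, float]
    final: tuple[str, ...]
    alpha_adjusted: float
    skipped: list[str] = field(default_factory=list)


def screen_interactions(
    respondent_utilities: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_covariates: int | None = None,
) -> ScreeningResult:
    """Bonferroni-adjusted multivariate screen of covariate effects.

    ``respondent_utilities``: respondent x outcome table of posterior-mean
    part-worths (index = respondent id).  ``covariates``: table keyed by the
    same respondent ids.  Each covariate is tested marginally; covariates
    passing ``alpha / n_covariates`` are re-tested jointly in one model at
    the same threshold.  Constant covariates are skipped with a warning
    entry rather than tested.
    """
    if n_covariates is None:
        n_covariates = covariates.shape[1]
    if n_covariates < 1:
        raise ValueError("n_covariates must be >= 1")
    alpha_adj = alpha / n_covariates
    common = respondent_utilities.index.intersection(covariates.index)
    y = respondent_utilities.loc[common].to_numpy(dtype=float)
    cov = covariates.loc[common]
    n = len(common)
    intercept = np.ones((n, 1))

    p_values: dict[str, float] = {}
    skipped: list[str] = []
    encoded: dict[str, np.ndarray] = {}
    for name in cov.columns:
        series = cov[name]
        if series.nunique(dropna=True) < 2:
            skipped.append(name)
            continue
        cols, _k = _encode(series)
        encoded[name] = cols
        x = np.hstack([intercept, cols])
        _, _, _, _, p = _wilks_test(y, x, list(range(1, x.shape[1])))
        p_values[name] = p
    screened = tuple(c for c, p in p_values.items() if p < alpha_adj)

    joint_p: dict[str, float] = {}
    final: tuple[str, ...] = ()
    if screened:
        blocks = [encoded[c] for c in screened]
        x = np.hstack([intercept] + blocks)
        offsets = np.cumsum([1] + [b.shape[1] for b in blocks])
        for c, start, stop in zip(screened, offsets[:-1], offsets[1:]):
            _, _, _, _, p = _wilks_test(y, x, list(range(start, stop)))
            joint_p[c] = p
        final = tuple(c for c in screened if joint_p[c] < alpha_adj)
    return ScreeningResult(
        p_values=p_values,
        screened=screened,
        joint_p_values=joint_p,
        final=final,
        alpha_adjusted=alpha_adj,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# stratified comparisons
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    outcome: str
    covariate: str
    f_stat: float
    p_value: float
    strata: dict[object, tuple[int, float, float]]  # level -> (n, mean, sd)


def _stratum_values(
    respondent_utilities: pd.DataFrame,
    covariate: pd.Series,
    outcome: str,
) -> dict[object, np.ndarray]:
    common = respondent_utilities.index.intersection(covariate.index)
    vals = respondent_utilities.loc[common, outcome]
    cov = covariate.loc[common]
    return {
        lev: vals[cov == lev].to_numpy(dtype=float)
        for lev in pd.unique(cov.dropna())
    }


def stratified_anova(
    respondent_utilities: pd.DataFrame,
    covariate: pd.Series,
    outcome: str,
) -> AnovaResult:
    """One-way ANOVA of one outcome's respondent utilities across strata."""
    groups = _stratum_values(respondent_utilities, covariate, outcome)
    groups = {lev: g for lev, g in groups.items() if len(g) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 strata with >= 2 respondents each")
    arrays = list(groups.values())
    if all(np.ptp(g) == 0 for g in arrays):
        raise ValueError(
            "zero within-stratum variance: the F statistic is undefined"
        )
    f_stat, p = stats.f_oneway(*arrays)
    return AnovaResult(
        outcome=outcome,
        covariate=str(covariate.name),
        f_stat=float(f_stat),
        p_value=float(p),
        strata={
            lev: (len(g), float(g.mean()), float(g.std(ddof=1)))
            for lev, g in groups.items()
        },
    )


def tukey_kramer(
    respondent_utilities: pd.DataFrame,
    covariate: pd.Series,
    outcome: str,
) -> pd.DataFrame:
    """All pairwise stratum comparisons, studentized-range adjusted.

    Uses the Tukey-Kramer generalization for unequal group sizes; returns a
    table with one row per stratum pair (group1, group2, meandiff, p_adj,
    lower, upper, reject at 0.05).
    """
    groups = _stratum_values(respondent_utilities, covariate, outcome)
    groups = {lev: g for lev, g in groups.items() if len(g) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 strata for pairwise comparisons")
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate(
        [np.repeat(str(lev), len(g)) for lev, g in groups.items()]
    )
    res = pairwise_tukeyhsd(values, labels, alpha=0.05)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    frame = frame.rename(columns={"p-adj": "p_adj"})
    for col in ("meandiff", "p_adj", "lower", "upper"):
        frame[col] = frame[col].astype(float)
    return frame


@dataclass
class TTestResult:
    outcome: str
    mean_experienced: float
    mean_not: float
    difference: float
    t_stat: float
    p_value: float
    n_experienced: int
    n_not: int


def experienced_vs_not(
    respondent_utilities: pd.DataFrame,
    experience_flags: pd.Series,
    outcome: str,
) -> TTestResult:
    """Student's t-test (equal variance) of an outcome's utilities between
    respondents who experienced that outcome and those who did not."""
    common = respondent_utilities.index.intersection(experience_flags.index)
    vals = respondent_utilities.loc[common, outcome].to_numpy(dtype=float)
    flags = experience_flags.loc[common].astype(bool).to_numpy()
    yes, no = vals[flags], vals[~flags]
    if len(yes) == 0 or len(no) == 0:
        raise ValueError("both experienced and non-experienced groups "
                         "must be non-empty")
    t_stat, p = stats.ttest_ind(yes, no, equal_var=True)
    return TTestResult(
        outcome=outcome,
        mean_experienced=float(yes.mean()),
        mean_not=float(no.mean()),
        difference=float(yes.mean() - no.mean()),
        t_stat=float(t_stat),
        p_value=float(p),
        n_experienced=len(yes),
        n_not=len(no),
    )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def stratified_table(
    respondent_utilities: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Stratum mean (SD) table with ANOVA significance stars.

    One row per (covariate, stratum, outcome) with n, mean, sd, ANOVA p for
    that covariate/outcome, and stars at 0.05 / 0.01 / 0.001.  Strata whose
    ANOVA is degenerate (too small, zero variance) are reported without a
    p-value.
    """
    outcomes = list(outcomes or respondent_utilities.columns)
    rows = []
    for cov_name in covariates.columns:
        cov = covariates[cov_name]
        for outcome in outcomes:
            try:
                res = stratified_anova(respondent_utilities, cov, outcome)
                p: float | None = res.p_value
                strata = res.strata
            except ValueError:
                p = None
                strata = {
                    lev: (len(g), float(g.mean()) if len(g) else np.nan,
                          float(g.std(ddof=1)) if len(g) > 1 else np.nan)
                    for lev, g in _stratum_values(
                        respondent_utilities, cov, outcome
                    ).items()
                }
            for lev, (n, m, sd) in strata.items():
                rows.append(
                    {
                        "covariate": cov_name,
                        "stratum": lev,
                        "outcome": outcome,
                        "n": n,
                        "mean": m,
                        "sd": sd,
                        "anova_p": p,
                        "significance": _stars(p) if p is not None else "",
                    }
                )
    return pd.DataFrame(rows)


def write_stratified_table(
    respondent_utilities: pd.DataFrame,
    covariates: pd.DataFrame,
    path: str | Path,
    outcomes: Sequence[str] | None = None,
) -> None:
    stratified_table(respondent_utilities, covariates, outcomes).to_csv(
        path, index=False
    )
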