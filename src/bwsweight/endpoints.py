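"""Unweighted and weighted treatment comparisons on a composite endpoint.

The battery mirrors the standard presentation of a weighted composite
analysis of a two-arm trial:

unweighted
    Fisher's exact test on any-event vs none; Cox time-to-first-event;
    random-effects (patient random intercept) logistic model; global rank.
weighted
    Marginal Cox model over repeated component events with each event
    record carrying its component weight (cluster-robust by patient);
    Wilcoxon rank-sum on per-patient severity scores (sum of event weights)
    reported as a Probability Index; weighted random-effects logistic model.

Orientation conventions (stated in every output): hazard and odds ratios
are arm A relative to arm B (first arm in sort order); the Probability
Index is P(score_A < score_B) + 0.5 P(tie), so values below 0.5 favor arm
A (lower weighted event burden).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import optimize, stats
from scipy.special import logsumexp
from statsmodels.tools.numdiff import approx_hess

from .simulate import TrialDataset
from .weighting import ComponentWeights

logger = logging.getLogger(__name__)

GH_NODES = 25


@dataclass(frozen=True)
class TrialResult:
    """One treatment-effect estimate with interval and p-value."""

    method: str
    measure: str  # 'odds ratio' | 'hazard ratio' | 'probability index'
    estimate: float
    lower95: float
    upper95: float
    p_value: float
    n_events: int
    weighted: bool
    note: str = ""

    def __post_init__(self) -> None:
        if not (self.lower95 - 1e-9 <= self.estimate <= self.upper95 + 1e-9):
            raise ValueError("interval must bracket the estimate")
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "measure": self.measure,
            "estimate": self.estimate,
            "lower95": self.lower95,
            "upper95": self.upper95,
            "p_value": self.p_value,
            "n_events": self.n_events,
            "weighted": self.weighted,
            "note": self.note,
        }


def _two_arms(trial: TrialDataset) -> tuple[str, str]:
    arms = trial.arms
    if len(arms) != 2:
        raise ValueError(f"expected exactly 2 arms, found {arms}")
    return arms  # type: ignore[return-value]


def _weight_map(
    trial: TrialDataset, weights: ComponentWeights | None
) -> dict[str, float]:
    if weights is None:
        return {c: 1.0 for c in trial.components}
    missing = [c for c in trial.components if c not in weights.weights]
    if missing:
        raise KeyError(f"no weight for component(s): {missing}")
    return dict(weights.weights)


# ---------------------------------------------------------------------------
# unweighted analyses
# ---------------------------------------------------------------------------

def fisher_composite(trial: TrialDataset) -> TrialResult:
    """Fisher's exact test on patients with >= 1 component event vs none.

    Odds ratio is the conditional maximum-likelihood estimate with an exact
    (central hypergeometric) confidence interval, arm A vs arm B.
    """
    arm_a, arm_b = _two_arms(trial)
    has_event = trial.patients["patient"].isin(trial.events["patient"])
    arm = trial.patients["arm"]
    a_ev = int((has_event & (arm == arm_a)).sum())
    b_ev = int((has_event & (arm == arm_b)).sum())
    n_a = int((arm == arm_a).sum())
    n_b = int((arm == arm_b).sum())
    table = [[a_ev, n_a - a_ev], [b_ev, n_b - b_ev]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    res = stats.contingency.odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return TrialResult(
        method="fisher_exact",
        measure="odds ratio",
        estimate=float(res.statistic),
        lower95=float(ci.low),
        upper95=float(ci.high),
        p_value=float(p),
        n_events=a_ev + b_ev,
        weighted=False,
        note=f"any-event patients: {arm_a} {a_ev}/{n_a}, {arm_b} {b_ev}/{n_b}",
    )


def _cox_result(
    df: pd.DataFrame,
    method: str,
    weighted: bool,
    n_events: int,
    cluster: bool,
    note: str = "",
) -> TrialResult:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cluster:
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                weights_col="w",
                cluster_col="patient",
                robust=True,
            )
        else:
            cph.fit(df[["time", "event", "arm_a"]],
                    duration_col="time", event_col="event")
    coef = float(cph.params_["arm_a"])
    se = float(cph.standard_errors_["arm_a"])
    z = coef / se
    p = 2 * stats.norm.sf(abs(z))
    return TrialResult(
        method=method,
        measure="hazard ratio",
        estimate=float(np.exp(coef)),
        lower95=float(np.exp(coef - 1.96 * se)),
        upper95=float(np.exp(coef + 1.96 * se)),
        p_value=float(p),
        n_events=n_events,
        weighted=weighted,
        note=note,
    )


def time_to_first_event(trial: TrialDataset) -> TrialResult:
    """Cox model on each patient's earliest component event.

    Later events are censored away by construction; patients without any
    event are censored at follow-up.
    """
    arm_a, _ = _two_arms(trial)
    if not len(trial.events):
        raise ValueError("no events in the trial; cannot fit a Cox model")
    first = trial.events.groupby("patient")["event_time"].min()
    df = trial.patients.copy()
    df["time"] = df["patient"].map(first).fillna(df["followup"])
    df["event"] = df["patient"].isin(first.index).astype(int)
    df["arm_a"] = (df["arm"] == arm_a).astype(float)
    n_events = int(df["event"].sum())
    return _cox_result(
        df, "time_to_first_event", weighted=False,
        n_events=n_events, cluster=False,
        note="HR arm A vs B; first component event per patient",
    )


# ---------------------------------------------------------------------------
# weighted analyses
# ---------------------------------------------------------------------------

def weighted_recurrent_tte(
    trial: TrialDataset, weights: ComponentWeights
) -> TrialResult:
    """Marginal Cox model over repeated, weighted component events.

    Every component event enters as its own record from randomization
    (time 0) carrying its component weight as an observation weight;
    event-free patients contribute one censored record at follow-up with
    weight 1.  Variance is cluster-robust by patient, so patients with
    several events do not masquerade as independent.  With unit weights and
    at most one event per patient this reduces exactly to the
    time-to-first-event model.
    """
    arm_a, _ = _two_arms(trial)
    wmap = _weight_map(trial, weights)
    if not len(trial.events):
        raise ValueError("no events in the trial; cannot fit a Cox model")
    ev = trial.events.merge(trial.patients, on="patient")
    rows = pd.DataFrame(
        {
            "patient": ev["patient"],
            "time": ev["event_time"],
            "event": 1,
            "w": ev["component"].map(wmap),
            "arm_a": (ev["arm"] == arm_a).astype(float),
        }
    )
    censored = trial.patients[
        ~trial.patients["patient"].isin(trial.events["patient"])
    ]
    cens = pd.DataFrame(
        {
            "patient": censored["patient"],
            "time": censored["followup"],
            "event": 0,
            "w": 1.0,
            "arm_a": (censored["arm"] == arm_a).astype(float),
        }
    )
    df = pd.concat([rows, cens], ignore_index=True)
    return _cox_result(
        df, "weighted_recurrent_tte", weighted=True,
        n_events=len(rows), cluster=True,
        note="HR arm A vs B; one weighted record per component event",
    )


def global_rank_test(
    trial: TrialDataset,
    weights: ComponentWeights | None = None,
    score: str = "sum",
) -> TrialResult:
    """Wilcoxon rank-sum on per-patient severity scores, as a Probability
    Index.

    The severity score is the sum (default) or maximum of the weights of a
    patient's events — zero for event-free patients — so repeated events
    raise severity under the default.  The Probability Index is
    P(score_A < score_B) + 0.5 P(tie): below 0.5 favors arm A.  Its CI uses
    the placement-variance (DeLong-type) normal approximation; the p-value
    is the two-sided Wilcoxon rank-sum p with midrank tie handling.
    """
    arm_a, arm_b = _two_arms(trial)
    if score not in ("sum", "max"):
        raise ValueError("score must be 'sum' or 'max'")
    wmap = _weight_map(trial, weights)
    ev = trial.events.copy()
    ev["w"] = ev["component"].map(wmap)
    agg = ev.groupby("patient")["w"].agg("sum" if score == "sum" else "max")
    scores = trial.patients["patient"].map(agg).fillna(0.0).to_numpy()
    arm = trial.patients["arm"].to_numpy()
    a, b = scores[arm == arm_a], scores[arm == arm_b]
    n_a, n_b = len(a), len(b)

    # placements: p_i = P(random B beats A_i), q_j = P(random A below B_j)
    p_place = np.array(
        [((b > x).sum() + 0.5 * (b == x).sum()) / n_b for x in a]
    )
    pi = float(p_place.mean())
    q_place = np.array(
        [((a < x).sum() + 0.5 * (a == x).sum()) / n_a for x in b]
    )
    var = (
        (p_place.var(ddof=1) / n_a if n_a > 1 else 0.0)
        + (q_place.var(ddof=1) / n_b if n_b > 1 else 0.0)
    )
    half = 1.96 * np.sqrt(var)
    if np.all(scores == scores[0]):
        p_val = 1.0
    else:
        p_val = float(
            stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        )
    return TrialResult(
        method="global_rank_wilcoxon",
        measure="probability index",
        estimate=pi,
        lower95=max(0.0, pi - half),
        upper95=min(1.0, pi + half),
        p_value=p_val,
        n_events=len(ev),
        weighted=weights is not None,
        note=f"PI = P(score_{arm_a} < score_{arm_b}) + 0.5 P(tie); "
             f"score = {score} of event weights",
    )


# ---------------------------------------------------------------------------
# random-effects logistic model (patient random intercept)
# ---------------------------------------------------------------------------

def _glmm_loglik(
    params: np.ndarray,
    x: np.ndarray,  # (n_patients,) arm indicator
    s: np.ndarray,  # (n_patients,) weighted event count  sum_j w_j y_ij
    w_total: float,  # sum_j w_j (same for every patient)
    nodes: np.ndarray,
    log_gh_w: np.ndarray,
) -> float:
    b0, b1, sig = params
    eta = b0 + b1 * x[:, None] + np.sqrt(2.0) * sig * nodes[None, :]
    # sum_j w_j [y eta - log(1+e^eta)] collapses because eta is j-free
    contrib = eta * s[:, None] - w_total * np.logaddexp(0.0, eta)
    per_patient = logsumexp(log_gh_w[None, :] + contrib, axis=1) - 0.5 * np.log(np.pi)
    return float(per_patient.sum())


def random_effects_composite(
    trial: TrialDataset,
    weights: ComponentWeights | None = None,
) -> TrialResult:
    """Logistic model of component events with a patient random intercept.

    Each patient x component binary outcome is a Bernoulli observation with
    linear predictor ``b0 + b1 * arm_A + u_patient``,
    ``u ~ N(0, sigma^2)``.  When component weights are supplied each
    observation's log-likelihood contribution is multiplied by its weight
    (normalized to mean 1, so constant weights reduce exactly to the
    unweighted fit).  The marginal likelihood integrates the random
    intercept by Gauss-Hermite quadrature; the odds ratio for arm A vs B is
    Wald-based.
    """
    arm_a, _ = _two_arms(trial)
    wmap = _weight_map(trial, weights)
    comps = list(trial.components)
    w_vec = np.array([wmap[c] for c in comps])
    w_vec = w_vec / w_vec.mean()  # scale-free likelihood weighting

    pats = trial.patients.reset_index(drop=True)
    x = (pats["arm"] == arm_a).to_numpy(dtype=float)
    # weighted per-patient event totals  s_i = sum_j w_j y_ij
    y = np.zeros((len(pats), len(comps)))
    pid_pos = {pid: i for i, pid in enumerate(pats["patient"])}
    comp_pos = {c: j for j, c in enumerate(comps)}
    for pid, comp, _t in trial.events.itertuples(index=False):
        y[pid_pos[pid], comp_pos[comp]] = 1.0
    s = y @ w_vec
    w_total = float(w_vec.sum())

    nodes, gh_w = np.polynomial.hermite.hermgauss(GH_NODES)
    log_gh_w = np.log(gh_w)

    def negll(params: np.ndarray) -> float:
        return -_glmm_loglik(params, x, s, w_total, nodes, log_gh_w)

    res = optimize.minimize(
        negll,
        x0=np.array([-1.0, 0.0, 0.5]),
        method="L-BFGS-B",
        bounds=[(-20, 20), (-10, 10), (0.0, 10.0)],
        options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
    )
    if not res.success:
        raise RuntimeError(
            f"random-effects model failed to converge: {res.message}"
        )
    b0, b1, sig = res.x
    hess = approx_hess(res.x, negll)
    try:
        cov = np.linalg.inv(hess)
        var_b1 = cov[1, 1]
    except np.linalg.LinAlgError:
        var_b1 = np.nan
    if not np.isfinite(var_b1) or var_b1 <= 0:
        # sigma on the boundary can degenerate the 3x3 Hessian; condition on it
        cov2 = np.linalg.inv(approx_hess(
            res.x[:2], lambda p: negll(np.array([p[0], p[1], sig]))
        ))
        var_b1 = cov2[1, 1]
    se = float(np.sqrt(var_b1))
    z = b1 / se
    return TrialResult(
        method="random_effects_logistic",
        measure="odds ratio",
        estimate=float(np.exp(b1)),
        lower95=float(np.exp(b1 - 1.96 * se)),
        upper95=float(np.exp(b1 + 1.96 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        n_events=int(y.sum()),
        weighted=weights is not None,
        note=f"OR arm A vs B; random-intercept SD {sig:.3f}",
    )


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

def analyze_all(
    trial: TrialDataset,
    weights: ComponentWeights | None,
) -> list[TrialResult]:
    """Run the full unweighted + weighted battery.

    With ``weights=None`` unit weights are used everywhere, so the weighted
    and unweighted global-rank and random-effects entries coincide.
    """
    results = [
        fisher_composite(trial),
        time_to_first_event(trial),
        random_effects_composite(trial, None),
        global_rank_test(trial, None),
    ]
    eff_weights = weights
    if eff_weights is None:
        from .weighting import ComponentWeights as _CW

        k = len(trial.components)
        eff_weights = _CW(
            components=tuple(trial.components),
            utilities_used={c: 0.0 for c in trial.components},
            weights={c: (k - 1) / k for c in trial.components},
        )
        # equal weights: rank/odds analyses are invariant to the common value
    weighted = [
        weighted_recurrent_tte(trial, eff_weights),
        global_rank_test(trial, eff_weights),
        random_effects_composite(trial, eff_weights),
    ]
    return results + weighted


def comparison_table(results: Sequence[TrialResult]) -> pd.DataFrame:
    """Additional-file-style comparison table of the analysis battery."""
    return pd.DataFrame([r.as_dict() for r in results])


def km_coordinates(
    trial: TrialDataset,
    weights: ComponentWeights | None = None,
) -> pd.DataFrame:
    """Kaplan-Meier-style survival coordinates per arm as plain text.

    Unweighted: first-event times per patient.  With weights: one record
    per component event with its weight (the weighted repeated-events
    curve).  Returns a tidy frame (arm, time, survival).
    """
    frames = []
    for arm in trial.arms:
        pats = trial.patients[trial.patients["arm"] == arm]
        if weights is None:
            first = trial.events.groupby("patient")["event_time"].min()
            t = pats["patient"].map(first).fillna(pats["followup"])
            e = pats["patient"].isin(first.index).astype(int)
            w = None
        else:
            wmap = _weight_map(trial, weights)
            ev = trial.events.merge(pats, on="patient")
            cens = pats[~pats["patient"].isin(trial.events["patient"])]
            t = pd.concat([ev["event_time"], cens["followup"]])
            e = pd.concat(
                [pd.Series(1, index=ev.index), pd.Series(0, index=cens.index)]
            )
            w = pd.concat(
                [ev["component"].map(wmap), pd.Series(1.0, index=cens.index)]
            )
        kmf = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kmf.fit(t, event_observed=e, weights=w, label=arm)
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"arm": arm, "time": sf.index, "survival": sf[arm].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)
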