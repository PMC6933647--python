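"""Utility estimation from best-worst scaling responses.

The observation model is the sequential (exploded) best-worst logit: within
a shown set S with utilities u, the best pick b has probability
``exp(u_b) / sum_{j in S} exp(u_j)`` and, given b, the worst pick w has
probability ``exp(-u_w) / sum_{j in S, j != b} exp(-u_j)``.  Utilities are
identified relative to the reference level, whose utility is fixed at zero.

Two estimators are provided:

* :func:`fit_pooled_mnl` — a single shared part-worth vector maximizing the
  pooled likelihood (quasi-Newton), with Wald intervals.  Serves as a fast
  point estimate, an independent oracle in the homogeneity limit, and the
  initializer for the hierarchical sampler.
* :func:`fit_hb_mnl` — the hierarchical Bayesian multinomial logit:
  respondent part-worths ``beta_r ~ MVN(mu, Sigma)`` with conjugate Gibbs
  updates for ``mu`` (normal) and ``Sigma`` (inverse-Wishart) and a
  random-walk Metropolis-Hastings update for each ``beta_r``, whose proposal
  scale adapts toward ~30% acceptance during burn-in and is frozen after.

Priors (weakly informative): ``mu ~ N(0, 100 I)``,
``Sigma ~ InvWishart(K + 2, I)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .catalog import OutcomeCatalog
from .simulate import ChoiceResponses

logger = logging.getLogger(__name__)

MU_PRIOR_VAR = 100.0
TARGET_ACCEPT = 0.30
ADAPT_UP, ADAPT_DOWN = 1.1, 0.9


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def bw_task_likelihood(
    utilities: np.ndarray,
    shown: tuple[int, ...],
    best: int,
    worst: int,
) -> float:
    """P(best) * P(worst | best) for one choice set.

    ``utilities`` is indexed by item id (the reference item's entry should
    be 0); ``shown`` are the item ids presented; ``best``/``worst`` the
    picked ids.  Returns a probability in (0, 1).
    """
    if best == worst:
        raise ValueError("best and worst picks must differ")
    if best not in shown or worst not in shown:
        raise ValueError("best and worst must be among the shown items")
    u = np.asarray([utilities[i] for i in shown], dtype=float)
    b_pos = shown.index(best)
    w_pos = shown.index(worst)
    log_p_best = u[b_pos] - logsumexp(u)
    nu = -u
    mask = np.ones(len(u), dtype=bool)
    mask[b_pos] = False
    log_p_worst = nu[w_pos] - logsumexp(nu[mask])
    return float(np.exp(log_p_best + log_p_worst))


@dataclass(frozen=True)
class _TaskArrays:
    """Index arrays for vectorized likelihood evaluation.

    Non-reference items are mapped to columns 0..K-1 of the part-worth
    matrix; the reference maps to a phantom column K whose utility is 0.
    """

    shown: np.ndarray  # (n_rows, k_items) part-worth column indices
    best_pos: np.ndarray  # (n_rows,) position of best within the row
    worst_pos: np.ndarray
    respondent: np.ndarray  # (n_rows,) respondent slot 0..R-1
    respondent_ids: np.ndarray  # (R,) original ids
    n_respondents: int
    k: int  # number of non-reference outcomes


def _task_arrays(responses: ChoiceResponses) -> _TaskArrays:
    cat = responses.catalog
    nonref = list(cat.non_reference)
    col = {lab: j for j, lab in enumerate(nonref)}
    col[cat.reference] = len(nonref)  # phantom zero-utility column
    d = responses.data
    item_cols = responses.item_columns
    shown = np.stack(
        [d[c].map(col).to_numpy(dtype=int) for c in item_cols], axis=1
    )
    best = d["best"].map(col).to_numpy(dtype=int)
    worst = d["worst"].map(col).to_numpy(dtype=int)
    best_pos = (shown == best[:, None]).argmax(axis=1)
    worst_pos = (shown == worst[:, None]).argmax(axis=1)
    ids = np.sort(d["respondent"].unique())
    slot = {rid: i for i, rid in enumerate(ids)}
    resp = d["respondent"].map(slot).to_numpy(dtype=int)
    return _TaskArrays(
        shown=shown,
        best_pos=best_pos,
        worst_pos=worst_pos,
        respondent=resp,
        respondent_ids=ids,
        n_respondents=len(ids),
        k=len(nonref),
    )


def _row_loglik(beta_rows: np.ndarray, ta: _TaskArrays) -> np.ndarray:
    """Log-likelihood of each data row given per-row part-worth vectors.

    ``beta_rows`` has shape (n_rows, K); a zero column is appended for the
    reference item.
    """
    full = np.concatenate(
        [beta_rows, np.zeros((beta_rows.shape[0], 1))], axis=1
    )
    u = np.take_along_axis(full, ta.shown, axis=1)  # (rows, items)
    lse = logsumexp(u, axis=1)
    rows = np.arange(u.shape[0])
    lbest = u[rows, ta.best_pos] - lse
    nu = -u
    nu[rows, ta.best_pos] = -np.inf
    lworst = nu[rows, ta.worst_pos] - logsumexp(nu, axis=1)
    return lbest + lworst


def _respondent_loglik(beta: np.ndarray, ta: _TaskArrays) -> np.ndarray:
    """Per-respondent log-likelihood for (R, K) part-worths."""
    ll_rows = _row_loglik(beta[ta.respondent], ta)
    out = np.zeros(ta.n_respondents)
    np.add.at(out, ta.respondent, ll_rows)
    return out


def drop_incomplete_respondents(data: pd.DataFrame) -> pd.DataFrame:
    """Remove respondents with any missing best/worst pick.

    Mirrors the survey practice of excluding respondents who did not
    clearly mark a best and a worst outcome on every choice set.
    """
    bad = data.loc[data["best"].isna() | data["worst"].isna(), "respondent"]
    if len(bad):
        logger.info("dropping %d incomplete respondents", bad.nunique())
    return data[~data["respondent"].isin(set(bad))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RespondentPartworths:
    respondent_id: object
    beta: np.ndarray  # (K,) non-reference part-worths


@dataclass(frozen=True)
class PopulationParameters:
    mu: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class UtilityEstimates:
    """Per-outcome posterior (or Wald) summaries, reference anchored at 0."""

    catalog: OutcomeCatalog
    mean: dict[str, float]
    lower95: dict[str, float]
    upper95: dict[str, float]
    n_respondents: int
    method: str = "hb"

    def __post_init__(self) -> None:
        ref = self.catalog.reference
        if abs(self.mean[ref]) > 1e-12:
            raise ValueError("reference outcome mean must be exactly 0")
        for lab in self.mean:
            if not (
                self.lower95[lab] - 1e-9
                <= self.mean[lab]
                <= self.upper95[lab] + 1e-9
            ):
                raise ValueError(f"interval does not bracket mean for {lab!r}")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "outcome": list(self.mean),
                "mean": list(self.mean.values()),
                "lower95": [self.lower95[o] for o in self.mean],
                "upper95": [self.upper95[o] for o in self.mean],
            }
        )

    def to_json(self, path) -> None:
        self.as_frame().to_json(path, orient="records", indent=2)

    @classmethod
    def from_mapping(
        cls,
        catalog: OutcomeCatalog,
        table: dict[str, tuple[float, float, float]],
        n_respondents: int = 0,
        method: str = "published",
    ) -> "UtilityEstimates":
        return cls(
            catalog=catalog,
            mean={o: v[0] for o, v in table.items()},
            lower95={o: v[1] for o, v in table.items()},
            upper95={o: v[2] for o, v in table.items()},
            n_respondents=n_respondents,
            method=method,
        )


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws (post burn-in) of the hierarchical model."""

    catalog: OutcomeCatalog
    mu: np.ndarray  # (n_kept, K)
    sigma: np.ndarray  # (n_kept, K, K)
    beta_mean: np.ndarray  # (R, K) running mean over retained draws
    beta_draws: np.ndarray  # (n_kept_thin, R, K) thinned respondent draws
    beta_thin: int
    respondent_ids: np.ndarray
    n_iter: int
    burn_in: int
    acceptance_trace: np.ndarray  # (n_iter,) mean MH acceptance per iteration
    seed: int

    def __post_init__(self) -> None:
        if self.mu.shape[0] != self.n_iter - self.burn_in:
            raise ValueError("retained draw count must equal n_iter - burn_in")
        if ((self.acceptance_trace < 0) | (self.acceptance_trace > 1)).any():
            raise ValueError("acceptance rates must lie in [0, 1]")


def respondent_utilities(draws: PosteriorDraws) -> list[RespondentPartworths]:
    """Posterior-mean part-worths per respondent (over retained draws)."""
    if draws.mu.shape[0] == 0:
        raise ValueError("no retained draws")
    return [
        RespondentPartworths(respondent_id=rid, beta=draws.beta_mean[i].copy())
        for i, rid in enumerate(draws.respondent_ids)
    ]


def respondent_utilities_frame(
    draws: PosteriorDraws, catalog: OutcomeCatalog | None = None
) -> pd.DataFrame:
    """Respondent-level posterior means as a respondent x outcome table."""
    catalog = catalog or draws.catalog
    df = pd.DataFrame(
        draws.beta_mean, columns=list(catalog.non_reference)
    )
    df.insert(0, "respondent", draws.respondent_ids)
    return df.set_index("respondent")


# ---------------------------------------------------------------------------
# pooled maximum likelihood
# ---------------------------------------------------------------------------

def fit_pooled_mnl(responses: ChoiceResponses) -> UtilityEstimates:
    """Single shared part-worth vector by maximum likelihood.

    Raises ``RuntimeError`` naming the runaway outcome when the MLE is
    unbounded (complete separation, e.g. an item never picked best in a
    tiny dataset).
    """
    data = drop_incomplete_respondents(responses.data)
    if not len(data):
        raise ValueError("no complete respondents")
    responses = ChoiceResponses(responses.catalog, data)
    ta = _task_arrays(responses)
    cat = responses.catalog

    def negll(beta: np.ndarray) -> float:
        return -float(
            _row_loglik(np.tile(beta, (ta.shown.shape[0], 1)), ta).sum()
        )

    x0 = np.zeros(ta.k)
    res = optimize.minimize(negll, x0, method="BFGS")
    beta = res.x
    # the MLE is unbounded iff pushing further along the fitted direction
    # never hurts the likelihood (complete separation)
    diverged = not np.isfinite(res.fun) or (
        np.abs(beta).max() > 1e-6 and negll(2 * beta) <= negll(beta) + 1e-10
    )
    if diverged:
        worst = cat.non_reference[int(np.abs(beta).argmax())]
        raise RuntimeError(
            f"pooled MLE diverged: utility for {worst!r} is unbounded "
            "(likely complete separation in a small dataset)"
        )
    # Wald intervals from the numerically estimated inverse Hessian
    cov = res.hess_inv
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    mean = {lab: float(b) for lab, b in zip(cat.non_reference, beta)}
    lower = {lab: float(b - 1.96 * s) for lab, b, s in zip(cat.non_reference, beta, se)}
    upper = {lab: float(b + 1.96 * s) for lab, b, s in zip(cat.non_reference, beta, se)}
    mean[cat.reference] = 0.0
    lower[cat.reference] = 0.0
    upper[cat.reference] = 0.0
    return UtilityEstimates(
        catalog=cat,
        mean=mean,
        lower95=lower,
        upper95=upper,
        n_respondents=ta.n_respondents,
        method="pooled_mnl",
    )


# ---------------------------------------------------------------------------
# hierarchical Bayes sampler
# ---------------------------------------------------------------------------

def mu_full_conditional(
    beta: np.ndarray, sigma: np.ndarray, prior_var: float = MU_PRIOR_VAR
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form moments of mu | beta, Sigma (conjugate normal)."""
    r_n, k = beta.shape
    sigma_inv = np.linalg.inv(sigma)
    prec = r_n * sigma_inv + np.eye(k) / prior_var
    cov = np.linalg.inv(prec)
    mean = cov @ (sigma_inv @ beta.sum(axis=0))
    return mean, cov


def _draw_mu(
    rng: np.random.Generator, beta: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    mean, cov = mu_full_conditional(beta, sigma)
    return rng.multivariate_normal(mean, cov)


def _draw_sigma(
    rng: np.random.Generator,
    beta: np.ndarray,
    mu: np.ndarray,
    s0: np.ndarray,
    nu0: int,
) -> np.ndarray:
    dev = beta - mu
    return stats.invwishart.rvs(
        df=nu0 + beta.shape[0], scale=s0 + dev.T @ dev, random_state=rng
    )


def _summaries_from_draws(
    catalog: OutcomeCatalog,
    mu_draws: np.ndarray,
    n_respondents: int,
    anchor: str,
) -> UtilityEstimates:
    """Posterior means and equal-tailed 95% intervals, anchored.

    ``fixed``: the reference utility is structurally zero in every draw, so
    its interval is degenerate at 0.  ``shifted``: draws are sum-to-zero
    centered across all outcomes (reference included) and then point-shifted
    by the reference's posterior mean, so the reference's reported mean is
    exactly 0 with a non-degenerate interval while the adverse outcomes'
    posterior means coincide with ``fixed`` mode.
    """
    labs = list(catalog.non_reference)
    ref = catalog.reference
    n_out = len(catalog)
    if anchor == "fixed":
        draws = {lab: mu_draws[:, j] for j, lab in enumerate(labs)}
        draws[ref] = np.zeros(mu_draws.shape[0])
    elif anchor == "shifted":
        center = mu_draws.sum(axis=1) / n_out  # ref contributes 0 to the sum
        ref_centered = -center
        shift = -ref_centered.mean()
        draws = {
            lab: mu_draws[:, j] - center + shift for j, lab in enumerate(labs)
        }
        draws[ref] = ref_centered + shift
    else:
        raise ValueError("anchor must be 'fixed' or 'shifted'")
    mean = {lab: float(d.mean()) for lab, d in draws.items()}
    lower = {lab: float(np.percentile(d, 2.5)) for lab, d in draws.items()}
    upper = {lab: float(np.percentile(d, 97.5)) for lab, d in draws.items()}
    # the reference mean is 0 by construction; pin it against float drift
    ordered = [*catalog.outcomes]
    return UtilityEstimates(
        catalog=catalog,
        mean={o: (0.0 if o == ref else mean[o]) for o in ordered},
        lower95={o: lower[o] for o in ordered},
        upper95={o: upper[o] for o in ordered},
        n_respondents=n_respondents,
        method=f"hb[{anchor}]",
    )


def fit_hb_mnl(
    responses: ChoiceResponses,
    n_iter: int = 10_000,
    burn_in: int = 5_000,
    seed: int = 0,
    anchor: str = "shifted",
    beta_thin: int = 10,
    init_rho: float = 0.3,
) -> tuple[PosteriorDraws, UtilityEstimates]:
    """Gibbs + Metropolis-Hastings sampler for the hierarchical BWS model.

    Each iteration: (1) draw ``mu`` from its conjugate normal full
    conditional; (2) draw ``Sigma`` from its conjugate inverse-Wishart full
    conditional; (3) update every respondent's ``beta_r`` with one
    random-walk MH step ``beta' = beta + rho * L z`` (L the Cholesky factor
    of the current ``Sigma``), accepting on the product of the exploded-logit
    likelihood and the MVN(mu, Sigma) prior.  ``rho`` is multiplied by 1.1
    (0.9) whenever the rolling acceptance rate exceeds (falls below) 0.30,
    during burn-in only.

    Returns the retained draws and the anchored utility summaries.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    data = drop_incomplete_respondents(responses.data)
    if not len(data):
        raise ValueError("no complete respondents")
    responses = ChoiceResponses(responses.catalog, data)
    ta = _task_arrays(responses)
    cat = responses.catalog
    k, r_n = ta.k, ta.n_respondents
    rng = np.random.default_rng(seed)

    # initialize at the pooled MLE when it exists, at zero otherwise
    try:
        pooled = fit_pooled_mnl(responses)
        beta = np.tile(
            np.array([pooled.mean[lab] for lab in cat.non_reference]),
            (r_n, 1),
        )
    except RuntimeError:
        beta = np.zeros((r_n, k))
    mu = beta[0].copy()
    sigma = np.eye(k)
    ll = _respondent_loglik(beta, ta)

    nu0 = k + 2
    s0 = np.eye(k)

    n_kept = n_iter - burn_in
    mu_draws = np.empty((n_kept, k))
    sigma_draws = np.empty((n_kept, k, k))
    beta_sum = np.zeros((r_n, k))
    kept_thin = []
    accept_trace = np.empty(n_iter)
    rho = init_rho
    rolling = TARGET_ACCEPT

    non_finite = ~np.isfinite(ll)
    if non_finite.any():
        bad = ta.respondent_ids[non_finite][0]
        raise RuntimeError(f"non-finite likelihood for respondent {bad!r}")

    for it in range(n_iter):
        # (1) mu | beta, Sigma  (conjugate normal)
        mu = _draw_mu(rng, beta, sigma)

        # (2) Sigma | beta, mu  (conjugate inverse-Wishart)
        sigma = _draw_sigma(rng, beta, mu, s0, nu0)

        # (3) beta_r | mu, Sigma, data  (random-walk MH, all respondents)
        chol = np.linalg.cholesky(sigma)
        prop = beta + rho * rng.standard_normal((r_n, k)) @ chol.T
        ll_prop = _respondent_loglik(prop, ta)
        sig_inv = np.linalg.inv(sigma)
        dev_old = beta - mu
        dev_new = prop - mu
        lp_old = -0.5 * np.einsum("ij,jk,ik->i", dev_old, sig_inv, dev_old)
        lp_new = -0.5 * np.einsum("ij,jk,ik->i", dev_new, sig_inv, dev_new)
        log_alpha = (ll_prop + lp_new) - (ll + lp_old)
        accept = np.log(rng.random(r_n)) < log_alpha
        beta[accept] = prop[accept]
        ll[accept] = ll_prop[accept]
        rate = float(accept.mean())
        accept_trace[it] = rate
        rolling = 0.95 * rolling + 0.05 * rate
        if it < burn_in:
            rho *= ADAPT_UP if rolling > TARGET_ACCEPT else ADAPT_DOWN

        if it >= burn_in:
            j = it - burn_in
            mu_draws[j] = mu
            sigma_draws[j] = sigma
            beta_sum += beta
            if j % beta_thin == 0:
                kept_thin.append(beta.copy())

    draws = PosteriorDraws(
        catalog=cat,
        mu=mu_draws,
        sigma=sigma_draws,
        beta_mean=beta_sum / n_kept,
        beta_draws=np.array(kept_thin),
        beta_thin=beta_thin,
        respondent_ids=ta.respondent_ids,
        n_iter=n_iter,
        burn_in=burn_in,
        acceptance_trace=accept_trace,
        seed=seed,
    )
    estimates = _summaries_from_draws(cat, mu_draws, r_n, anchor)
    logger.info(
        "HB fit: %d respondents, %d iterations (%d burn-in), "
        "final acceptance %.2f, rho %.3f",
        r_n, n_iter, burn_in, accept_trace[-1], rho,
    )
    return draws, estimates
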