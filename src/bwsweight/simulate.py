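"""Synthetic BWS responses and two-arm trial event data.

Two generators make every downstream stage testable without any external
download:

* :func:`simulate_choices` draws respondent part-worths from a population
  multivariate normal and answers each choice set with the sequential
  best-worst (exploded) logit: the best item from ``softmax(beta)`` over the
  shown set, then the worst from ``softmax(-beta)`` over the remainder.
* :func:`simulate_trial` draws independent Bernoulli component events per
  patient with arm-specific probabilities and uniform (default) or
  exponential event times over the follow-up window.

Both are pure functions of their inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import OutcomeCatalog
from .design import ChoiceDesign

DEFAULT_FOLLOWUP_DAYS = 365.0


@dataclass(frozen=True)
class TruePreferences:
    """Data-generating population preferences.

    ``mu`` and ``sigma`` are over the catalog's non-reference outcomes in
    catalog order; the reference level's utility is identically zero for
    every respondent (it is the anchor, not a random effect).
    ``covariate_effects`` maps covariate name -> level -> additive shift
    vector on ``mu``.
    """

    catalog: OutcomeCatalog
    mu: np.ndarray
    sigma: np.ndarray
    covariate_effects: dict[str, dict[object, np.ndarray]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        k = len(self.catalog.non_reference)
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.shape != (k,):
            raise ValueError(f"mu must have shape ({k},), got {mu.shape}")
        if sigma.shape != (k, k):
            raise ValueError(f"sigma must have shape ({k},{k})")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("sigma must be symmetric")
        eigvals = np.linalg.eigvalsh(sigma)
        if eigvals.min() < -1e-10:
            raise ValueError("sigma must be positive semi-definite")
        for cov, levels in self.covariate_effects.items():
            for lev, shift in levels.items():
                if np.asarray(shift).shape != (k,):
                    raise ValueError(
                        f"covariate_effects[{cov!r}][{lev!r}] has wrong shape"
                    )
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class ChoiceResponses:
    """Long-format best/worst picks, one row per (respondent, task)."""

    catalog: OutcomeCatalog
    data: pd.DataFrame  # respondent, version, task, item1..itemk, best, worst, cov_*

    def __post_init__(self) -> None:
        d = self.data
        item_cols = self.item_columns
        shown = d[item_cols].to_numpy()
        if (d["best"].to_numpy() == d["worst"].to_numpy()).any():
            raise ValueError("best equals worst in some row")
        for col in ("best", "worst"):
            ok = (d[col].to_numpy()[:, None] == shown).any(axis=1)
            if not ok.all():
                raise ValueError(f"{col} pick not among shown items")
        if d.duplicated(subset=["respondent", "version", "task"]).any():
            raise ValueError("duplicate (respondent, task) rows")

    @property
    def item_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("item")]

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("cov_")]

    @property
    def n_respondents(self) -> int:
        return self.data["respondent"].nunique()

    def covariates(self) -> pd.DataFrame:
        """One row per respondent with the cov_* columns (prefix stripped)."""
        cols = self.covariate_columns
        out = (
            self.data.groupby("respondent")[cols].first()
            if cols
            else self.data.groupby("respondent")[[]].first()
        )
        out.columns = [c.removeprefix("cov_") for c in out.columns]
        return out

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, catalog: OutcomeCatalog) -> "ChoiceResponses":
        return cls(catalog, pd.read_csv(Path(path)))


@dataclass(frozen=True)
class TrialDataset:
    """Two-arm component-event data.

    ``patients``: one row per patient (patient, arm, followup).
    ``events``: one row per (patient, component) event (patient, component,
    event_time), at most one event per pair, times within follow-up.
    """

    patients: pd.DataFrame
    events: pd.DataFrame
    components: tuple[str, ...]

    def __post_init__(self) -> None:
        arms = self.patients["arm"].unique()
        if len(arms) < 2:
            raise ValueError("trial needs two non-empty arms")
        if (self.patients["followup"] <= 0).any():
            raise ValueError("followup times must be positive")
        if len(self.events):
            merged = self.events.merge(self.patients, on="patient")
            if (merged["event_time"] > merged["followup"]).any():
                raise ValueError("event time exceeds follow-up")
            if (merged["event_time"] < 0).any():
                raise ValueError("negative event time")
            if self.events.duplicated(["patient", "component"]).any():
                raise ValueError("more than one event per (patient, component)")

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(sorted(self.patients["arm"].unique()))

    def arm_sizes(self) -> dict[str, int]:
        return self.patients["arm"].value_counts().to_dict()

    def to_long(self) -> pd.DataFrame:
        """One row per (patient, component); event_time NaN when censored."""
        grid = self.patients.merge(
            pd.DataFrame({"component": list(self.components)}), how="cross"
        )
        out = grid.merge(self.events, on=["patient", "component"], how="left")
        return out[["patient", "arm", "component", "event_time", "followup"]]

    def to_wide(self) -> pd.DataFrame:
        """One row per patient with one time_<component> column each."""
        wide = self.patients.copy()
        for comp in self.components:
            sub = self.events[self.events["component"] == comp]
            wide = wide.merge(
                sub[["patient", "event_time"]].rename(
                    columns={"event_time": f"time_{comp}"}
                ),
                on="patient",
                how="left",
            )
        return wide

    def to_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TrialDataset":
        components = tuple(pd.unique(df["component"]))
        patients = (
            df[["patient", "arm", "followup"]]
            .drop_duplicates("patient")
            .reset_index(drop=True)
        )
        events = (
            df.dropna(subset=["event_time"])[["patient", "component", "event_time"]]
            .reset_index(drop=True)
        )
        return cls(patients=patients, events=events, components=components)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialDataset":
        return cls.from_long(pd.read_csv(Path(path)))

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "TrialDataset":
        time_cols = [c for c in df.columns if c.startswith("time_")]
        components = tuple(c.removeprefix("time_") for c in time_cols)
        patients = df[["patient", "arm", "followup"]].copy()
        rows = []
        for col, comp in zip(time_cols, components):
            sub = df.loc[df[col].notna(), ["patient", col]]
            for pid, t in sub.itertuples(index=False):
                rows.append((pid, comp, float(t)))
        events = pd.DataFrame(rows, columns=["patient", "component", "event_time"])
        return cls(patients=patients, events=events, components=components)


def _utilities_matrix(
    beta: np.ndarray, catalog: OutcomeCatalog
) -> np.ndarray:
    """Expand (R, K) non-reference part-worths to (R, n_outcomes) with ref=0."""
    n = len(catalog)
    full = np.zeros((beta.shape[0], n))
    nonref = [catalog.index(lab) for lab in catalog.non_reference]
    full[:, nonref] = beta
    return full


def simulate_choices(
    design: ChoiceDesign,
    truth: TruePreferences,
    n_respondents: int,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> ChoiceResponses:
    """Draw best/worst picks for ``n_respondents`` under the exploded logit.

    Respondents are assigned questionnaire versions round-robin by index.
    Each respondent r draws part-worths ``beta_r ~ MVN(mu + shifts, sigma)``
    where shifts come from ``truth.covariate_effects`` evaluated on that
    respondent's row of ``covariates`` (if given); ``covariates`` must be
    indexed 0..n_respondents-1.
    """
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    if truth.catalog.outcomes != design.catalog.outcomes:
        raise ValueError("truth catalog does not match design catalog")
    catalog = design.catalog
    rng = np.random.default_rng(seed)
    k = len(catalog.non_reference)

    mu_r = np.tile(truth.mu, (n_respondents, 1))
    if truth.covariate_effects:
        if covariates is None:
            raise ValueError("covariate_effects given but no covariates table")
        for cov, levels in truth.covariate_effects.items():
            vals = covariates[cov].to_numpy()
            for lev, shift in levels.items():
                mu_r[vals == lev] += np.asarray(shift, dtype=float)

    # one Cholesky draw per respondent (sigma may be singular -> eigen fallback)
    try:
        chol = np.linalg.cholesky(truth.sigma + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(truth.sigma)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    beta = mu_r + rng.standard_normal((n_respondents, k)) @ chol.T
    util = _utilities_matrix(beta, catalog)

    rows = []
    for r in range(n_respondents):
        version = r % design.n_versions
        for task_id, items in design.version_tasks(version):
            u = util[r, list(items)]
            p_best = np.exp(u - u.max())
            p_best /= p_best.sum()
            b_pos = rng.choice(len(items), p=p_best)
            nu = -u.copy()
            nu[b_pos] = -np.inf
            p_worst = np.exp(nu - nu[np.isfinite(nu)].max())
            p_worst /= p_worst.sum()
            w_pos = rng.choice(len(items), p=p_worst)
            rows.append(
                (r, version, task_id)
                + tuple(catalog.outcomes[i] for i in items)
                + (catalog.outcomes[items[b_pos]], catalog.outcomes[items[w_pos]])
            )
    k_items = design.items_per_task
    cols = (
        ["respondent", "version", "task"]
        + [f"item{j+1}" for j in range(k_items)]
        + ["best", "worst"]
    )
    data = pd.DataFrame(rows, columns=cols)
    if covariates is not None:
        cov = covariates.copy()
        cov.columns = [f"cov_{c}" for c in cov.columns]
        cov["respondent"] = range(n_respondents)
        data = data.merge(cov, on="respondent", how="left")
    return ChoiceResponses(catalog=catalog, data=data)


def simulate_trial(
    arm_sizes: dict[str, int] | tuple[int, int],
    component_probs: dict[str, dict[str, float]],
    followup_days: float = DEFAULT_FOLLOWUP_DAYS,
    seed: int = 0,
    time_distribution: str = "uniform",
    exp_rate: float | None = None,
) -> TrialDataset:
    """Simulate independent Bernoulli component events for a two-arm trial.

    ``component_probs`` maps arm -> component -> event probability.  Each
    patient experiences each component independently; event times are drawn
    uniform(0, followup) by default, or truncated-exponential with rate
    ``exp_rate`` (per day) when ``time_distribution='exponential'``.
    """
    if isinstance(arm_sizes, (tuple, list)):
        arm_sizes = {"A": arm_sizes[0], "B": arm_sizes[1]}
    if any(n < 1 for n in arm_sizes.values()):
        raise ValueError("arm sizes must be positive")
    if followup_days <= 0:
        raise ValueError("followup_days must be positive")
    for arm, comps in component_probs.items():
        for comp, p in comps.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {arm}/{comp} outside [0,1]")
    if time_distribution not in ("uniform", "exponential"):
        raise ValueError("time_distribution must be 'uniform' or 'exponential'")

    components: tuple[str, ...] = tuple(
        dict.fromkeys(c for comps in component_probs.values() for c in comps)
    )
    rng = np.random.default_rng(seed)
    pat_rows = []
    ev_rows = []
    pid = 0
    for arm in sorted(arm_sizes):
        probs = component_probs.get(arm, {})
        for _ in range(arm_sizes[arm]):
            pat_rows.append((pid, arm, followup_days))
            for comp in components:
                p = probs.get(comp, 0.0)
                if rng.random() < p:
                    if time_distribution == "uniform":
                        t = rng.uniform(0.0, followup_days)
                    else:
                        rate = exp_rate if exp_rate is not None else 1.0 / followup_days
                        # inverse-CDF draw truncated to the follow-up window
                        u = rng.random()
                        t = -np.log1p(-u * (1 - np.exp(-rate * followup_days))) / rate
                    ev_rows.append((pid, comp, float(t)))
            pid += 1
    patients = pd.DataFrame(pat_rows, columns=["patient", "arm", "followup"])
    events = pd.DataFrame(ev_rows, columns=["patient", "component", "event_time"])
    return TrialDataset(patients=patients, events=events, components=components)
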