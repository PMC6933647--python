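"""Composite-endpoint analysis battery: oracles, identities, symmetries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bwsweight as bw


def _trial(patients_rows, events_rows, components):
    patients = pd.DataFrame(
        patients_rows, columns=["patient", "arm", "followup"]
    )
    events = pd.DataFrame(
        events_rows, columns=["patient", "component", "event_time"]
    )
    return bw.TrialDataset(patients, events, tuple(components))


def _unit_weights(components):
    k = len(components)
    return bw.ComponentWeights(
        components=tuple(components),
        utilities_used={c: -1.0 for c in components},
        weights={c: (k - 1) / k if k > 1 else 0.5 for c in components},
    ) if k > 1 else None


def _weights(mapping):
    # helper for explicit non-normalized weights; bypasses the sum-to-k-1
    # invariant check by construction through equal utilities when needed
    obj = object.__new__(bw.ComponentWeights)
    object.__setattr__(obj, "components", tuple(mapping))
    object.__setattr__(obj, "utilities_used", {c: 0.0 for c in mapping})
    object.__setattr__(obj, "weights", dict(mapping))
    object.__setattr__(obj, "overridden", ())
    return obj


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def test_fisher_symmetric_table_is_null():
    rows = [(i, "A" if i < 20 else "B", 100.0) for i in range(40)]
    events = [(i, "x", 50.0) for i in list(range(10)) + list(range(20, 30))]
    trial = _trial(rows, events, ["x"])
    res = bw.fisher_composite(trial)
    assert res.estimate == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_fisher_p_matches_hypergeometric_sum():
    """Exact p from brute-force enumeration of the hypergeometric tail."""
    n_a, n_b, a_ev, b_ev = 498, 502, 168, 174
    rows = [(i, "A", 365.0) for i in range(n_a)] + [
        (n_a + i, "B", 365.0) for i in range(n_b)
    ]
    events = [(i, "x", 100.0) for i in range(a_ev)] + [
        (n_a + i, "x", 100.0) for i in range(b_ev)
    ]
    trial = _trial(rows, events, ["x"])
    res = bw.fisher_composite(trial)
    # two-sided Fisher p: sum of all table probabilities <= observed
    m = a_ev + b_ev
    rv = stats.hypergeom(n_a + n_b, m, n_a)
    p_obs = rv.pmf(a_ev)
    p_brute = sum(
        rv.pmf(x)
        for x in range(max(0, m - n_b), min(m, n_a) + 1)
        if rv.pmf(x) <= p_obs * (1 + 1e-12)
    )
    assert res.p_value == pytest.approx(p_brute, rel=1e-8)


def test_fisher_or_invariant_to_doubling():
    def build(scale):
        rows = [(i, "A", 10.0) for i in range(30 * scale)] + [
            (1000 + i, "B", 10.0) for i in range(40 * scale)
        ]
        events = [(i, "x", 5.0) for i in range(12 * scale)] + [
            (1000 + i, "x", 5.0) for i in range(9 * scale)
        ]
        return _trial(rows, events, ["x"])

    r1 = bw.fisher_composite(build(1))
    r2 = bw.fisher_composite(build(2))
    # conditional-MLE OR is scale-stable within numerical tolerance
    assert r1.estimate == pytest.approx(r2.estimate, rel=0.02)


# ---------------------------------------------------------------------------
# time to first event
# ---------------------------------------------------------------------------

def test_identical_arms_hazard_ratio_one():
    rows, events = [], []
    times = [30.0, 60.0, 90.0, 120.0, 150.0]
    for i, t in enumerate(times):
        rows += [(i, "A", 365.0), (100 + i, "B", 365.0)]
        events += [(i, "x", t), (100 + i, "x", t)]
    for i in range(5, 20):
        rows += [(i, "A", 365.0), (100 + i, "B", 365.0)]
    trial = _trial(rows, events, ["x"])
    res = bw.time_to_first_event(trial)
    assert res.estimate == pytest.approx(1.0, abs=1e-5)


def test_doubled_hazard_recovered():
    """Exponential closed form: doubling one arm's rate gives HR ~ 2."""
    rng = np.random.default_rng(0)
    n = 4000
    rows, events = [], []
    for i in range(n):
        arm = "A" if i < n // 2 else "B"
        rate = 2 / 365.0 if arm == "A" else 1 / 365.0
        t = rng.exponential(1 / rate)
        fu = 365.0
        rows.append((i, arm, fu))
        if t <= fu:
            events.append((i, "x", t))
    trial = _trial(rows, events, ["x"])
    res = bw.time_to_first_event(trial)
    assert res.estimate == pytest.approx(2.0, rel=0.1)


def test_second_event_ignored_by_first_event_analysis(pilon_trial):
    res1 = bw.time_to_first_event(pilon_trial)
    # give one already-eventful patient a later second event
    ev = pilon_trial.events
    by_patient = ev.groupby("patient").size()
    pid = by_patient[by_patient == 1].index[0]
    done = set(ev.loc[ev["patient"] == pid, "component"])
    other = next(c for c in pilon_trial.components if c not in done)
    first_time = float(ev.loc[ev["patient"] == pid, "event_time"].iloc[0])
    extra = pd.DataFrame(
        [(pid, other, min(first_time + 1.0, 365.0))],
        columns=["patient", "component", "event_time"],
    )
    trial2 = bw.TrialDataset(
        pilon_trial.patients,
        pd.concat([ev, extra], ignore_index=True),
        pilon_trial.components,
    )
    res2 = bw.time_to_first_event(trial2)
    assert res2.estimate == pytest.approx(res1.estimate, abs=1e-12)


def test_no_events_raises():
    rows = [(0, "A", 10.0), (1, "B", 10.0)]
    trial = _trial(rows, [], ["x"])
    with pytest.raises(ValueError):
        bw.time_to_first_event(trial)


# ---------------------------------------------------------------------------
# weighted recurrent events
# ---------------------------------------------------------------------------

def test_unit_weights_single_events_reduce_to_first_event(pilon_trial):
    """weights=1 and at most one event per patient => the marginal
    recurrent-events model IS the time-to-first-event model."""
    first = pilon_trial.events.sort_values("event_time").groupby("patient").head(1)
    single = bw.TrialDataset(
        pilon_trial.patients, first.reset_index(drop=True),
        pilon_trial.components,
    )
    w = _weights({c: 1.0 for c in pilon_trial.components})
    r_rec = bw.weighted_recurrent_tte(single, w)
    r_ttf = bw.time_to_first_event(single)
    assert r_rec.estimate == pytest.approx(r_ttf.estimate, abs=1e-6)


def test_arm_swap_inverts_hazard_ratio(pilon_trial, pilon_weights):
    res = bw.weighted_recurrent_tte(pilon_trial, pilon_weights)
    swapped_patients = pilon_trial.patients.copy()
    swapped_patients["arm"] = swapped_patients["arm"].map({"A": "B", "B": "A"})
    swapped = bw.TrialDataset(
        swapped_patients, pilon_trial.events, pilon_trial.components
    )
    res_swapped = bw.weighted_recurrent_tte(swapped, pilon_weights)
    assert res_swapped.estimate == pytest.approx(1 / res.estimate, rel=1e-6)


def test_missing_weight_named(pilon_trial):
    w = _weights({"Deep surgical site infection": 0.9})
    with pytest.raises(KeyError, match="Bone healing"):
        bw.weighted_recurrent_tte(pilon_trial, w)


def test_weighted_hr_below_unweighted_on_pilon_profile(
    pilon_trial, pilon_weights
):
    """Arm A trades high-weight events for low-weight ones, so weighting
    moves the hazard ratio in A's favor."""
    hr_unweighted = bw.time_to_first_event(pilon_trial).estimate
    hr_weighted = bw.weighted_recurrent_tte(pilon_trial, pilon_weights).estimate
    assert hr_weighted < hr_unweighted


# ---------------------------------------------------------------------------
# global rank / probability index
# ---------------------------------------------------------------------------

def test_identical_score_multisets_give_half():
    rows = [(i, "A", 10.0) for i in range(6)] + [
        (10 + i, "B", 10.0) for i in range(6)
    ]
    events = [(0, "x", 1.0), (1, "x", 2.0), (10, "x", 1.0), (11, "x", 2.0)]
    trial = _trial(rows, events, ["x"])
    res = bw.global_rank_test(trial, None)
    assert res.estimate == pytest.approx(0.5)
    assert res.p_value == pytest.approx(1.0, abs=0.05)


def test_strict_dominance_hits_boundary():
    rows = [(i, "A", 10.0) for i in range(4)] + [
        (10 + i, "B", 10.0) for i in range(4)
    ]
    events = [(10 + i, "x", 1.0) for i in range(4)]  # only B has events
    trial = _trial(rows, events, ["x"])
    res = bw.global_rank_test(trial, None)
    # every A score (0) below every B score (1): PI = 1 by orientation
    assert res.estimate == pytest.approx(1.0)


def test_u_statistic_matches_pair_enumeration():
    """4-patient toy instance: U equals the brute-force count over all
    cross-arm pairs (ties as one half)."""
    rows = [(0, "A", 10.0), (1, "A", 10.0), (2, "B", 10.0), (3, "B", 10.0)]
    events = [(0, "x", 1.0), (2, "x", 2.0), (2, "y", 3.0)]
    w = _weights({"x": 0.6, "y": 0.9})
    trial = _trial(rows, events, ["x", "y"])
    res = bw.global_rank_test(trial, w)
    scores_a, scores_b = [0.6, 0.0], [1.5, 0.0]
    brute = np.mean(
        [
            1.0 if a < b else (0.5 if a == b else 0.0)
            for a in scores_a
            for b in scores_b
        ]
    )
    assert res.estimate == pytest.approx(brute, abs=1e-12)


def test_rank_score_max_option(pilon_trial, pilon_weights):
    r_sum = bw.global_rank_test(pilon_trial, pilon_weights, score="sum")
    r_max = bw.global_rank_test(pilon_trial, pilon_weights, score="max")
    assert r_sum.method == r_max.method
    assert r_sum.estimate != r_max.estimate  # multi-event patients differ


# ---------------------------------------------------------------------------
# random effects
# ---------------------------------------------------------------------------

def test_glmm_limits_to_marginal_or_without_heterogeneity():
    """With independent components (no patient effect), the random-effects
    OR approaches the collapsed-table marginal OR."""
    rng = np.random.default_rng(1)
    n = 2000
    rows, events = [], []
    for i in range(n):
        arm = "A" if i < n // 2 else "B"
        p = 0.10 if arm == "A" else 0.18
        rows.append((i, arm, 365.0))
        for comp in ("x", "y", "z"):
            if rng.random() < p:
                events.append((i, comp, 100.0))
    trial = _trial(rows, events, ["x", "y", "z"])
    res = bw.random_effects_composite(trial, None)
    y = np.zeros((n, 3))
    for pid, comp, _ in events:
        y[pid, "xyz".index(comp)] = 1
    p_a, p_b = y[: n // 2].mean(), y[n // 2:].mean()
    marginal_or = (p_a / (1 - p_a)) / (p_b / (1 - p_b))
    assert res.estimate == pytest.approx(marginal_or, rel=0.1)


def test_constant_weights_equal_unweighted_fit(pilon_trial):
    r1 = bw.random_effects_composite(pilon_trial, None)
    w = _weights({c: 0.37 for c in pilon_trial.components})
    r2 = bw.random_effects_composite(pilon_trial, w)
    assert r2.estimate == pytest.approx(r1.estimate, abs=1e-6)
    # p-value goes through a finite-difference Hessian; allow its noise
    assert r2.p_value == pytest.approx(r1.p_value, abs=1e-4)


def test_permuted_arms_center_on_null():
    """Randomly relabeling arms gives OR ~ 1 on average (null calibration
    of the random-effects model)."""
    rng = np.random.default_rng(2)
    base = bw.simulate_trial((150, 150), {
        "A": {"x": 0.2, "y": 0.1}, "B": {"x": 0.2, "y": 0.1}
    }, seed=3)
    log_ors = []
    for _ in range(20):
        pats = base.patients.copy()
        pats["arm"] = rng.permutation(pats["arm"].to_numpy())
        trial = bw.TrialDataset(pats, base.events, base.components)
        log_ors.append(np.log(bw.random_effects_composite(trial, None).estimate))
    assert abs(np.mean(log_ors)) < 0.15


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

def test_analyze_all_row_count_and_structure(pilon_trial, pilon_weights):
    results = bw.analyze_all(pilon_trial, pilon_weights)
    assert len(results) == 7
    table = bw.comparison_table(results)
    assert {"method", "estimate", "p_value", "weighted"} <= set(table.columns)
    assert table["weighted"].sum() == 3


def test_analyze_all_without_weights_collapses(pilon_trial):
    results = bw.analyze_all(pilon_trial, None)
    by = {(r.method, r.weighted): r for r in results}
    r_u = by[("global_rank_wilcoxon", False)]
    r_w = by[("global_rank_wilcoxon", True)]
    assert r_w.estimate == pytest.approx(r_u.estimate, abs=1e-12)
    g_u = by[("random_effects_logistic", False)]
    g_w = by[("random_effects_logistic", True)]
    assert g_w.estimate == pytest.approx(g_u.estimate, abs=1e-6)


def test_km_coordinates_monotone(pilon_trial, pilon_weights):
    for w in (None, pilon_weights):
        coords = bw.km_coordinates(pilon_trial, w)
        for arm, grp in coords.groupby("arm"):
            surv = grp.sort_values("time")["survival"].to_numpy()
            assert (np.diff(surv) <= 1e-12).all()
            assert surv[0] == pytest.approx(1.0)
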