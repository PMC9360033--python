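"""Multi-state engine: dataset bookkeeping, Aalen–Johansen occupancy,
per-transition Cox fits, prediction and contributing factors."""

import warnings

import numpy as np
import pandas as pd
import pytest

from amlclass import (
    OutcomeRecord,
    State,
    TransitionHazard,
    aalen_johansen,
    build_multistate_dataset,
    contributing_factors,
    fit_transition_cox,
    predict_state_occupancy,
    simulate_trajectories,
)
from amlclass.multistate import TRANSITIONS, bootstrap_occupancy

STATE_COLS = [s.name for s in State]


def o(pid, t_last, dead, t_cr=None, t_relapse=None):
    return OutcomeRecord(pid, t_last=t_last, dead=dead, t_cr=t_cr,
                         t_relapse=t_relapse)


# -- dataset construction ----------------------------------------------------

def test_full_trajectory_yields_five_records():
    ds, excl = build_multistate_dataset(
        [o("p", 1.5, True, t_cr=0.3, t_relapse=1.0)]
    )
    assert not excl
    recs = {(r.from_state, r.to_state): r for r in ds.itertuples()}
    assert set(recs) == {(1, 2), (1, 4), (2, 3), (2, 5), (3, 6)}
    assert recs[(1, 2)].status == 1 and recs[(1, 2)].t_exit == 0.3
    assert recs[(1, 4)].status == 0 and recs[(1, 4)].t_exit == 0.3
    assert recs[(2, 3)].status == 1 and recs[(2, 3)].t_entry == 0.3
    assert recs[(2, 5)].status == 0 and recs[(2, 5)].t_exit == 1.0
    assert recs[(3, 6)].status == 1 and recs[(3, 6)].t_exit == 1.5


def test_censored_pre_cr_yields_two_censored_records():
    ds, _ = build_multistate_dataset([o("p", 2.0, False)])
    assert len(ds) == 2
    assert set(ds["status"]) == {0}
    assert set(zip(ds["from_state"], ds["to_state"])) == {(1, 2), (1, 4)}


def test_relapse_without_cr_excluded_with_reason():
    ds, excl = build_multistate_dataset([o("bad", 2.0, True, t_relapse=1.0)])
    assert len(ds) == 0
    assert excl[0].patient_id == "bad"


def test_death_disambiguation_by_relapse_presence():
    # death with CR and no relapse -> 2->5 event
    ds, _ = build_multistate_dataset([o("p", 1.0, True, t_cr=0.2)])
    ev = ds[ds["status"] == 1]
    assert list(zip(ev["from_state"], ev["to_state"])) == [(1, 2), (2, 5)]


def test_cohort_transition_counts_match_direct_endpoint_counts(strict_cohort):
    """Event counts per transition equal counts derived straight from the
    raw outcome sequences (counting oracle)."""
    outcomes = strict_cohort.outcomes
    ds, excl = build_multistate_dataset(outcomes)
    kept = {x.patient_id for x in excl}
    raw = [oc for oc in outcomes if oc.patient_id not in kept]
    expected = {
        (1, 2): sum(1 for x in raw if x.t_cr is not None),
        (1, 4): sum(1 for x in raw if x.t_cr is None and x.dead),
        (2, 3): sum(1 for x in raw if x.t_relapse is not None),
        (2, 5): sum(1 for x in raw if x.t_cr is not None
                    and x.t_relapse is None and x.dead),
        (3, 6): sum(1 for x in raw if x.t_relapse is not None and x.dead),
    }
    for (i, j), n in expected.items():
        sub = ds[(ds["from_state"] == i) & (ds["to_state"] == j)]
        assert int(sub["status"].sum()) == n, (i, j)


# -- Aalen–Johansen ----------------------------------------------------------

def _empirical_occupancy(outcomes, t):
    counts = np.zeros(6)
    for x in outcomes:
        if x.t_relapse is not None and x.dead and x.t_last <= t:
            s = State.DEATH_AFTER_RELAPSE
        elif x.t_relapse is None and x.t_cr is not None and x.dead and x.t_last <= t:
            s = State.DEATH_IN_CR
        elif x.t_cr is None and x.dead and x.t_last <= t:
            s = State.DEATH_NO_CR
        elif x.t_relapse is not None and x.t_relapse <= t:
            s = State.RELAPSE
        elif x.t_cr is not None and x.t_cr <= t:
            s = State.ALIVE_CR
        else:
            s = State.ALIVE_INDUCTION
        counts[int(s) - 1] += 1
    return counts / len(outcomes)


@pytest.fixture(scope="module")
def uncensored_outcomes():
    """200 patients followed to death (administrative censoring far beyond
    every event time)."""
    rng = np.random.default_rng(5)
    cov = pd.DataFrame({"z": rng.integers(0, 2, 200)},
                       index=[f"u{i}" for i in range(200)])
    hazards = {
        (1, 2): TransitionHazard(2.0, {"z": -0.4}),
        (1, 4): TransitionHazard(0.6, {"z": 0.5}),
        (2, 3): TransitionHazard(0.5, {"z": 0.4}),
        (2, 5): TransitionHazard(0.25),
        (3, 6): TransitionHazard(1.2),
    }
    return simulate_trajectories(cov, hazards, censoring_window=(500.0, 501.0),
                                 seed=7), cov


def test_aalen_johansen_equals_counting_oracle_without_censoring(
    uncensored_outcomes,
):
    outcomes, _ = uncensored_outcomes
    ds, excl = build_multistate_dataset(outcomes)
    assert not excl
    grid = np.array([0.25, 0.5, 1.0, 2.0, 5.0, 20.0])
    aj = aalen_johansen(ds, grid=grid)
    for k, t in enumerate(grid):
        np.testing.assert_allclose(
            aj.loc[k, STATE_COLS].to_numpy(float),
            _empirical_occupancy(outcomes, t),
            atol=1e-12,
        )


def test_occupancy_rows_sum_to_one_and_absorbing_monotone(strict_cohort):
    ds, _ = build_multistate_dataset(strict_cohort.outcomes)
    aj = aalen_johansen(ds)
    sums = aj[STATE_COLS].sum(axis=1).to_numpy()
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    for s in ("DEATH_NO_CR", "DEATH_IN_CR", "DEATH_AFTER_RELAPSE"):
        assert (np.diff(aj[s].to_numpy()) >= -1e-12).all()


def test_no_events_occupancy_stays_at_start():
    ds, _ = build_multistate_dataset(
        [o(f"c{i}", 2.0, False) for i in range(5)]
    )
    aj = aalen_johansen(ds, grid=np.array([0.0, 1.0, 3.0]))
    np.testing.assert_allclose(aj["ALIVE_INDUCTION"], 1.0)


def test_single_patient_in_cr_occupancy():
    ds, _ = build_multistate_dataset([o("p", 2.0, False, t_cr=0.5)])
    aj = aalen_johansen(ds, grid=np.array([1.0]))
    assert aj.loc[0, "ALIVE_CR"] == pytest.approx(1.0)


# -- Cox per transition ------------------------------------------------------

def test_cox_without_covariates_reproduces_nonparametric(strict_cohort):
    ds, _ = build_multistate_dataset(strict_cohort.outcomes)
    grid = np.linspace(0.0, 5.0, 41)
    aj = aalen_johansen(ds, grid=grid)
    model = fit_transition_cox(ds, [])
    pred = predict_state_occupancy(model, {}, grid=grid)
    np.testing.assert_allclose(
        pred.occupancy[STATE_COLS].to_numpy(),
        aj[STATE_COLS].to_numpy(),
        atol=1e-8,
    )


def test_simulated_hazard_ratio_two_recovered_within_3_se():
    rng = np.random.default_rng(21)
    n = 2000
    cov = pd.DataFrame({"x": rng.integers(0, 2, n)},
                       index=[f"s{i}" for i in range(n)])
    hazards = {
        (1, 2): TransitionHazard(2.0),
        (1, 4): TransitionHazard(0.3),
        (2, 3): TransitionHazard(0.5, {"x": np.log(2.0)}),
        (2, 5): TransitionHazard(0.1),
        (3, 6): TransitionHazard(1.0),
    }
    outcomes = simulate_trajectories(cov, hazards, censoring_window=(4.0, 9.0),
                                     seed=22)
    ds, _ = build_multistate_dataset(outcomes, cov)
    model = fit_transition_cox(ds, {(2, 3): ["x"]})
    fit = model.transition(2, 3)
    assert abs(fit.beta[0] - np.log(2.0)) < 3 * fit.se[0]


def test_null_covariate_beta_within_3_se():
    rng = np.random.default_rng(31)
    n = 1500
    cov = pd.DataFrame({"x": rng.normal(size=n)},
                       index=[f"n{i}" for i in range(n)])
    outcomes = simulate_trajectories(cov, seed=32)
    ds, _ = build_multistate_dataset(outcomes, cov)
    model = fit_transition_cox(ds, ["x"])
    for (i, j) in TRANSITIONS:
        fit = model.transition(i, j)
        if fit.estimable and fit.n_events > 20:
            assert abs(fit.beta[0]) < 3 * fit.se[0], (i, j)


def test_zero_event_transition_flagged_unestimable():
    ds, _ = build_multistate_dataset(
        [o(f"p{i}", 1.0, False, t_cr=0.2) for i in range(10)]
        + [o("q", 0.5, True)]
    )
    with pytest.warns(UserWarning, match="zero events"):
        model = fit_transition_cox(ds, [])
    assert not model.transition(2, 3).estimable
    assert model.transition(1, 4).estimable


def test_prediction_monotone_in_death_covariate(strict_cohort):
    ds, _ = build_multistate_dataset(strict_cohort.outcomes,
                                     strict_cohort.covariates)
    model = fit_transition_cox(ds, ["risk_adverse"])
    beta = model.transition(1, 4).beta[0]
    lo = predict_state_occupancy(model, {"risk_adverse": 0.0})
    hi = predict_state_occupancy(model, {"risk_adverse": 1.0})
    p_lo = lo.occupancy["DEATH_NO_CR"].iloc[-1]
    p_hi = hi.occupancy["DEATH_NO_CR"].iloc[-1]
    if beta > 0:
        assert p_hi >= p_lo
    else:
        assert p_hi <= p_lo


def test_prediction_starts_with_all_mass_in_start_state(strict_cohort):
    ds, _ = build_multistate_dataset(strict_cohort.outcomes)
    model = fit_transition_cox(ds, [])
    for start in (State.ALIVE_INDUCTION, State.ALIVE_CR):
        pred = predict_state_occupancy(model, {}, start=start,
                                       grid=np.array([0.0, 1.0]))
        assert pred.occupancy.loc[0, start.name] == pytest.approx(1.0)


def test_outlier_covariate_raises_warning_flag(strict_cohort):
    ds, _ = build_multistate_dataset(strict_cohort.outcomes,
                                     strict_cohort.covariates)
    model = fit_transition_cox(ds, ["age_decades"])
    ok = predict_state_occupancy(model, {"age_decades": 0.0})
    assert not ok.outlier_warnings
    wild = predict_state_occupancy(model, {"age_decades": 40.0})
    assert wild.outlier_warnings


def test_model_json_round_trip(tmp_path, strict_cohort):
    from amlclass.multistate import TransitionModel

    ds, _ = build_multistate_dataset(strict_cohort.outcomes,
                                     strict_cohort.covariates)
    model = fit_transition_cox(ds, ["risk_adverse"])
    model.to_json(tmp_path / "m.json")
    back = TransitionModel.from_json(tmp_path / "m.json")
    for key in model.fits:
        np.testing.assert_allclose(back.fits[key].beta, model.fits[key].beta)
        np.testing.assert_allclose(back.fits[key].baseline_increments,
                                   model.fits[key].baseline_increments)
    pred_a = predict_state_occupancy(model, {"risk_adverse": 1.0})
    pred_b = predict_state_occupancy(back, {"risk_adverse": 1.0})
    np.testing.assert_allclose(pred_a.occupancy.to_numpy(),
                               pred_b.occupancy.to_numpy())


def test_bootstrap_ci_brackets_point_estimate(strict_cohort):
    ds, _ = build_multistate_dataset(strict_cohort.outcomes,
                                     strict_cohort.covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = bootstrap_occupancy(ds, ["risk_adverse"],
                                   {"risk_adverse": 1.0}, n_boot=20, seed=4)
    assert pred.lower is not None
    mid = pred.occupancy[STATE_COLS].to_numpy()
    assert (pred.lower[STATE_COLS].to_numpy() <= mid + 1e-9).mean() > 0.95
    assert (pred.upper[STATE_COLS].to_numpy() >= mid - 1e-9).mean() > 0.95


# -- contributing factors ----------------------------------------------------

def test_contributing_factor_formula_and_sign(strict_cohort):
    ds, _ = build_multistate_dataset(strict_cohort.outcomes,
                                     strict_cohort.covariates)
    model = fit_transition_cox(ds, ["age_decades", "risk_adverse"])
    fit = model.transition(1, 4)
    med = fit.medians["age_decades"]
    cf = contributing_factors(model, {"age_decades": med + 2.0}, (1, 4))
    assert cf["age_decades"] == pytest.approx(fit.beta[0] * 2.0)
    # unspecified covariate imputed at median -> exactly zero
    assert cf["risk_adverse"] == 0.0
    # covariates exactly at the medians -> all zero
    cf0 = contributing_factors(model, dict(fit.medians), (1, 4))
    assert all(v == 0.0 for v in cf0.values())


def test_contributing_factor_negative_for_protective_above_median():
    from amlclass.multistate import TransitionFit, TransitionModel

    fit = TransitionFit(
        covariates=("z",), beta=np.array([-0.5]), se=np.array([0.1]),
        baseline_times=np.array([1.0]), baseline_increments=np.array([0.1]),
        medians={"z": 1.0}, lower_q={"z": 0.0}, upper_q={"z": 2.0},
        n_events=10,
    )
    model = TransitionModel({(1, 2): fit})
    cf = contributing_factors(model, {"z": 3.0}, (1, 2))
    assert cf["z"] == pytest.approx(-1.0)


def test_unknown_covariate_rejected(strict_cohort):
    ds, _ = build_multistate_dataset(strict_cohort.outcomes,
                                     strict_cohort.covariates)
    model = fit_transition_cox(ds, ["age_decades"])
    with pytest.raises(ValueError, match="unknown"):
        contributing_factors(model, {"nope": 1.0}, (1, 2))
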