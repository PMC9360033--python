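"""Six-state multi-state model of the AML treatment journey.

States: alive post-induction (1), alive in complete remission (2), alive in
relapse (3), death without CR (4), death in CR (5), death after relapse
(6).  Permitted transitions: 1→2, 1→4, 2→3, 2→5, 3→6; the three death
states are absorbing and the transition graph is acyclic.  All clocks run
forward from diagnosis (time in years).

The module builds the long-format transition dataset from outcome
timepoints, estimates non-parametric state-occupancy probabilities by
Aalen–Johansen product integration, fits one Cox proportional-hazards
model per transition, h_ij(t|Z) = h_ij,0(t) exp(beta_ij' Z), predicts
patient-level occupancy curves, and decomposes a patient's log-hazard on a
transition into per-covariate contributing factors
beta_ij^(k) (z^(k) − median^(k)).
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort import OutcomeRecord


class State(enum.IntEnum):
    ALIVE_INDUCTION = 1
    ALIVE_CR = 2
    RELAPSE = 3
    DEATH_NO_CR = 4
    DEATH_IN_CR = 5
    DEATH_AFTER_RELAPSE = 6


#: Permitted transitions (from, to); death states are absorbing.
TRANSITIONS: tuple[tuple[State, State], ...] = (
    (State.ALIVE_INDUCTION, State.ALIVE_CR),
    (State.ALIVE_INDUCTION, State.DEATH_NO_CR),
    (State.ALIVE_CR, State.RELAPSE),
    (State.ALIVE_CR, State.DEATH_IN_CR),
    (State.RELAPSE, State.DEATH_AFTER_RELAPSE),
)

_CORE_COLS = ["patient_id", "from_state", "to_state", "t_entry", "t_exit", "status"]


@dataclass(frozen=True)
class ExcludedPatient:
    patient_id: str
    reason: str


def build_multistate_dataset(
    outcomes: Sequence[OutcomeRecord],
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[ExcludedPatient]]:
    """Expand outcome timepoints into one row per at-risk transition.

    Each patient contributes a (possibly censored) record for every
    transition they were at risk for.  A patient who relapses and dies
    yields five rows: 1→2 event, 1→4 censored at CR, 2→3 event, 2→5
    censored at relapse, 3→6 event at death.  Patients with inconsistent
    or degenerate timepoints (relapse without CR, non-increasing times)
    are excluded and reported, mirroring how cohorts with missing
    timepoints are handled.

    ``covariates``: optional DataFrame indexed by patient_id; its columns
    are merged onto every transition row.
    """
    rows: list[dict] = []
    excluded: list[ExcludedPatient] = []
    for o in outcomes:
        if not o.is_consistent():
            excluded.append(ExcludedPatient(o.patient_id, "inconsistent timepoints"))
            continue
        segs: list[tuple[State, State, float, float, int]] = []
        if o.t_cr is None:
            # never reached CR: at risk for CR and death-without-CR until t_last
            segs.append((State.ALIVE_INDUCTION, State.ALIVE_CR, 0.0, o.t_last, 0))
            segs.append(
                (State.ALIVE_INDUCTION, State.DEATH_NO_CR, 0.0, o.t_last, int(o.dead))
            )
        else:
            segs.append((State.ALIVE_INDUCTION, State.ALIVE_CR, 0.0, o.t_cr, 1))
            segs.append((State.ALIVE_INDUCTION, State.DEATH_NO_CR, 0.0, o.t_cr, 0))
            if o.t_relapse is None:
                segs.append((State.ALIVE_CR, State.RELAPSE, o.t_cr, o.t_last, 0))
                segs.append(
                    (State.ALIVE_CR, State.DEATH_IN_CR, o.t_cr, o.t_last, int(o.dead))
                )
            else:
                segs.append((State.ALIVE_CR, State.RELAPSE, o.t_cr, o.t_relapse, 1))
                segs.append((State.ALIVE_CR, State.DEATH_IN_CR, o.t_cr, o.t_relapse, 0))
                segs.append((
                    State.RELAPSE, State.DEATH_AFTER_RELAPSE,
                    o.t_relapse, o.t_last, int(o.dead),
                ))
        if any(t_exit <= t_entry for _, _, t_entry, t_exit, _ in segs):
            excluded.append(
                ExcludedPatient(o.patient_id, "degenerate (zero-length) interval")
            )
            continue
        for from_s, to_s, t_entry, t_exit, status in segs:
            rows.append({
                "patient_id": o.patient_id,
                "from_state": int(from_s),
                "to_state": int(to_s),
                "t_entry": t_entry,
                "t_exit": t_exit,
                "status": status,
            })
    df = pd.DataFrame(rows, columns=_CORE_COLS)
    if covariates is not None and len(df):
        df = df.join(covariates, on="patient_id")
    return df, excluded


# ---------------------------------------------------------------------------
# non-parametric occupancy (Aalen–Johansen)

def _risk_intervals(dataset: pd.DataFrame) -> pd.DataFrame:
    """One (patient, from_state) sojourn interval, deduplicated across the
    competing destination rows."""
    return dataset.drop_duplicates(
        subset=["patient_id", "from_state"]
    )[["patient_id", "from_state", "t_entry", "t_exit"]]


def _transition_increments(
    dataset: pd.DataFrame,
) -> tuple[np.ndarray, dict[tuple[int, int], np.ndarray]]:
    """Nelson–Aalen hazard increments dN_ij(t)/Y_i(t) at each event time."""
    events = dataset[dataset["status"] == 1]
    times = np.unique(events["t_exit"].to_numpy())
    sojourn = _risk_intervals(dataset)
    increments: dict[tuple[int, int], np.ndarray] = {}
    for (i, j) in TRANSITIONS:
        ev = events[(events["from_state"] == i) & (events["to_state"] == j)]
        dN = np.zeros(len(times))
        if len(ev):
            idx = np.searchsorted(times, ev["t_exit"].to_numpy())
            np.add.at(dN, idx, 1.0)
        at_risk = sojourn[sojourn["from_state"] == i]
        entry = at_risk["t_entry"].to_numpy()
        exit_ = at_risk["t_exit"].to_numpy()
        # Y_i(t) = # patients with entry < t <= exit
        Y = np.array([(np.sum((entry < t) & (t <= exit_))) for t in times])
        with np.errstate(invalid="ignore", divide="ignore"):
            dA = np.where(Y > 0, dN / np.maximum(Y, 1), 0.0)
        increments[(int(i), int(j))] = dA
    return times, increments


def _product_integrate(
    times: np.ndarray,
    increments: Mapping[tuple[int, int], np.ndarray],
    grid: np.ndarray,
    start: State,
) -> pd.DataFrame:
    """P(t) = prod over event times <= t of (I + dA), from the start state."""
    n_states = len(State)
    p = np.zeros(n_states)
    p[int(start) - 1] = 1.0
    out = np.zeros((len(grid), n_states))
    k = 0  # index into event times
    for g_idx, t in enumerate(grid):
        while k < len(times) and times[k] <= t:
            step = np.eye(n_states)
            for (i, j), dA in increments.items():
                a = dA[k]
                if a > 0:
                    step[i - 1, j - 1] += a
                    step[i - 1, i - 1] -= a
            # guard against a discrete increment overshooting probability 1
            for r in range(n_states):
                if step[r, r] < 0:
                    off = step[r, :].copy()
                    off[r] = 0.0
                    step[r, :] = off / off.sum()
                    step[r, r] = 0.0
            p = p @ step
            k += 1
        out[g_idx] = p
    cols = [s.name for s in State]
    df = pd.DataFrame(out, columns=cols)
    df.insert(0, "time", grid)
    return df


def default_grid(dataset: pd.DataFrame, markers: Sequence[float] = (1.0, 3.0)) -> np.ndarray:
    """Union of observed event times, 0, and the 1y/3y display markers."""
    events = dataset[dataset["status"] == 1]["t_exit"].to_numpy()
    grid = np.unique(np.concatenate([[0.0], events, np.asarray(markers, float)]))
    return grid


def aalen_johansen(
    dataset: pd.DataFrame,
    grid: np.ndarray | None = None,
    start: State = State.ALIVE_INDUCTION,
) -> pd.DataFrame:
    """Non-parametric state-occupancy probabilities P(t) on a time grid.

    Product integration of the Nelson–Aalen transition-hazard increments;
    rows sum to 1 and absorbing-state occupancy is non-decreasing.  With no
    events the occupancy stays at the initial distribution.
    """
    if grid is None:
        grid = default_grid(dataset)
    grid = np.asarray(grid, dtype=float)
    times, increments = _transition_increments(dataset)
    return _product_integrate(times, increments, grid, start)


# ---------------------------------------------------------------------------
# semi-parametric (per-transition Cox) model

@dataclass
class TransitionFit:
    """One transition's Cox fit: coefficients, their SEs, the Breslow
    baseline cumulative-hazard step function, and the at-risk covariate
    medians / 95%-range used for imputation and outlier flagging."""

    covariates: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    baseline_times: np.ndarray
    baseline_increments: np.ndarray
    medians: dict[str, float]
    lower_q: dict[str, float]
    upper_q: dict[str, float]
    n_events: int
    estimable: bool = True


@dataclass
class TransitionModel:
    """Per-transition Cox models over the fixed six-state space."""

    fits: dict[tuple[int, int], TransitionFit]

    def transition(self, from_state: State | int, to_state: State | int) -> TransitionFit:
        key = (int(from_state), int(to_state))
        if key not in self.fits:
            raise KeyError(f"no such transition {key}; allowed: {sorted(self.fits)}")
        return self.fits[key]

    # -- serialization (JSON bundle for the CLI calculator) -----------------
    def to_json(self, path: str | Path) -> None:
        payload = {}
        for (i, j), f in self.fits.items():
            payload[f"{i}->{j}"] = {
                "covariates": list(f.covariates),
                "beta": f.beta.tolist(),
                "se": f.se.tolist(),
                "baseline_times": f.baseline_times.tolist(),
                "baseline_increments": f.baseline_increments.tolist(),
                "medians": f.medians,
                "lower_q": f.lower_q,
                "upper_q": f.upper_q,
                "n_events": f.n_events,
                "estimable": f.estimable,
            }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionModel":
        raw = json.loads(Path(path).read_text())
        fits = {}
        for key, f in raw.items():
            i, j = key.split("->")
            fits[(int(i), int(j))] = TransitionFit(
                covariates=tuple(f["covariates"]),
                beta=np.asarray(f["beta"], float),
                se=np.asarray(f["se"], float),
                baseline_times=np.asarray(f["baseline_times"], float),
                baseline_increments=np.asarray(f["baseline_increments"], float),
                medians=f["medians"],
                lower_q=f["lower_q"],
                upper_q=f["upper_q"],
                n_events=f["n_events"],
                estimable=f["estimable"],
            )
        return cls(fits)


def _normalize_spec(
    covariate_spec: Sequence[str] | Mapping[tuple[int, int], Sequence[str]] | None,
) -> dict[tuple[int, int], tuple[str, ...]]:
    if covariate_spec is None:
        covariate_spec = []
    if isinstance(covariate_spec, Mapping):
        return {
            (int(i), int(j)): tuple(covariate_spec.get((i, j), ()))
            for (i, j) in TRANSITIONS
        }
    return {(int(i), int(j)): tuple(covariate_spec) for (i, j) in TRANSITIONS}


def _breslow_baseline(
    sub: pd.DataFrame, covs: tuple[str, ...], beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow baseline hazard increments dH0(t) = dN(t) / sum_at_risk exp(bz)
    on the transition's event-time grid (left-truncation aware)."""
    ev_times = np.unique(sub.loc[sub["status"] == 1, "t_exit"].to_numpy())
    entry = sub["t_entry"].to_numpy()
    exit_ = sub["t_exit"].to_numpy()
    status = sub["status"].to_numpy()
    if covs:
        lin = sub[list(covs)].to_numpy(float) @ beta
    else:
        lin = np.zeros(len(sub))
    expz = np.exp(lin)
    dH0 = np.zeros(len(ev_times))
    for k, t in enumerate(ev_times):
        at_risk = (entry < t) & (t <= exit_)
        dN = np.sum((exit_ == t) & (status == 1))
        denom = expz[at_risk].sum()
        dH0[k] = dN / denom if denom > 0 else 0.0
    return ev_times, dH0


def fit_transition_cox(
    dataset: pd.DataFrame,
    covariate_spec: Sequence[str] | Mapping[tuple[int, int], Sequence[str]] | None = None,
) -> TransitionModel:
    """Fit one Cox model per transition with transition-specific Breslow
    baselines (Markov, clock-forward: entry times are handled as left
    truncation).

    ``covariate_spec``: either one covariate list for all transitions or a
    mapping (from, to) → list.  With an empty list the model is the
    non-parametric estimator.  A transition with zero events is flagged
    unestimable.
    """
    spec = _normalize_spec(covariate_spec)
    fits: dict[tuple[int, int], TransitionFit] = {}
    for (i, j) in TRANSITIONS:
        key = (int(i), int(j))
        covs = spec[key]
        sub = dataset[
            (dataset["from_state"] == int(i)) & (dataset["to_state"] == int(j))
        ].copy()
        n_events = int(sub["status"].sum()) if len(sub) else 0
        medians = {c: float(sub[c].median()) for c in covs} if len(sub) else {c: 0.0 for c in covs}
        lower_q = {c: float(sub[c].quantile(0.025)) for c in covs} if len(sub) else {}
        upper_q = {c: float(sub[c].quantile(0.975)) for c in covs} if len(sub) else {}
        if n_events == 0:
            warnings.warn(f"transition {key}: zero events, unestimable", stacklevel=2)
            fits[key] = TransitionFit(
                covariates=covs,
                beta=np.zeros(len(covs)),
                se=np.full(len(covs), np.nan),
                baseline_times=np.empty(0),
                baseline_increments=np.empty(0),
                medians=medians,
                lower_q=lower_q,
                upper_q=upper_q,
                n_events=0,
                estimable=False,
            )
            continue
        if covs:
            cph = CoxPHFitter()
            cph.fit(
                sub[["t_entry", "t_exit", "status", *covs]],
                duration_col="t_exit",
                event_col="status",
                entry_col="t_entry",
            )
            beta = cph.params_.reindex(list(covs)).to_numpy()
            se = cph.standard_errors_.reindex(list(covs)).to_numpy()
        else:
            beta = np.empty(0)
            se = np.empty(0)
        times, dH0 = _breslow_baseline(sub, covs, beta)
        fits[key] = TransitionFit(
            covariates=covs,
            beta=beta,
            se=se,
            baseline_times=times,
            baseline_increments=dH0,
            medians=medians,
            lower_q=lower_q,
            upper_q=upper_q,
            n_events=n_events,
        )
    return TransitionModel(fits)


def impute_covariates(
    model: TransitionModel,
    z: Mapping[str, float],
    transition: tuple[int, int],
) -> dict[str, float]:
    """Complete a covariate vector for one transition, filling unspecified
    covariates with that transition's at-risk medians."""
    fit = model.transition(*transition)
    out = {}
    for c in fit.covariates:
        out[c] = float(z[c]) if c in z and z[c] is not None else fit.medians[c]
    return out


@dataclass
class OccupancyPrediction:
    occupancy: pd.DataFrame  # time + one column per state
    outlier_warnings: list[str] = field(default_factory=list)
    lower: pd.DataFrame | None = None  # bootstrap percentile bands
    upper: pd.DataFrame | None = None


def _model_increments(
    model: TransitionModel, z: Mapping[str, float]
) -> tuple[np.ndarray, dict[tuple[int, int], np.ndarray], list[str]]:
    all_times = np.unique(
        np.concatenate(
            [f.baseline_times for f in model.fits.values()] or [np.empty(0)]
        )
    )
    increments: dict[tuple[int, int], np.ndarray] = {}
    warns: list[str] = []
    for key, f in model.fits.items():
        zz = impute_covariates(model, z, key)
        for c in f.covariates:
            if c in z and z[c] is not None:
                lo, hi = f.lower_q.get(c), f.upper_q.get(c)
                if lo is not None and not (lo <= zz[c] <= hi):
                    warns.append(
                        f"covariate {c}={zz[c]:g} outside the training "
                        f"95% range [{lo:g}, {hi:g}] for transition {key}"
                    )
        hr = float(np.exp(
            np.dot(f.beta, [zz[c] for c in f.covariates]) if f.covariates else 0.0
        ))
        dA = np.zeros(len(all_times))
        if len(f.baseline_times):
            idx = np.searchsorted(all_times, f.baseline_times)
            dA[idx] = f.baseline_increments * hr
        increments[key] = dA
    return all_times, increments, sorted(set(warns))


def predict_state_occupancy(
    model: TransitionModel,
    z: Mapping[str, float],
    start: State = State.ALIVE_INDUCTION,
    grid: np.ndarray | None = None,
) -> OccupancyPrediction:
    """Patient-level stacked state-occupancy probabilities.

    The patient's hazard on each transition is the transition baseline
    scaled by exp(beta'z); occupancy follows by product integration, so
    probabilities sum to 1 at every time.  Unspecified covariates are
    imputed at the transition medians; specified covariates outside the
    training 95%-quantile range raise an outlier warning flag on the
    returned prediction.  ``start`` may be ALIVE_CR to predict from
    attainment of complete remission.
    """
    times, increments, warns = _model_increments(model, z)
    if grid is None:
        markers = np.array([1.0, 3.0])
        grid = np.unique(np.concatenate([[0.0], times, markers]))
    grid = np.asarray(grid, dtype=float)
    occ = _product_integrate(times, increments, grid, State(start))
    return OccupancyPrediction(occupancy=occ, outlier_warnings=warns)


def bootstrap_occupancy(
    dataset: pd.DataFrame,
    covariate_spec,
    z: Mapping[str, float],
    start: State = State.ALIVE_INDUCTION,
    grid: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> OccupancyPrediction:
    """Occupancy prediction with percentile bootstrap confidence bands,
    resampling patients (not transition records) with replacement."""
    model = fit_transition_cox(dataset, covariate_spec)
    pred = predict_state_occupancy(model, z, start, grid)
    grid_used = pred.occupancy["time"].to_numpy()
    rng = np.random.default_rng(seed)
    ids = dataset["patient_id"].unique()
    samples = []
    for _ in range(n_boot):
        take = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for r, pid in enumerate(take):
            part = dataset[dataset["patient_id"] == pid].copy()
            part["patient_id"] = f"b{r}"
            parts.append(part)
        boot_ds = pd.concat(parts, ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_transition_cox(boot_ds, covariate_spec)
                p = predict_state_occupancy(m, z, start, grid_used)
            samples.append(p.occupancy[[s.name for s in State]].to_numpy())
        except Exception:  # convergence failure on a degenerate resample
            continue
    if samples:
        arr = np.stack(samples)
        lo = np.percentile(arr, 2.5, axis=0)
        hi = np.percentile(arr, 97.5, axis=0)
        cols = [s.name for s in State]
        lower = pd.DataFrame(lo, columns=cols)
        lower.insert(0, "time", grid_used)
        upper = pd.DataFrame(hi, columns=cols)
        upper.insert(0, "time", grid_used)
        pred.lower, pred.upper = lower, upper
    return pred


def contributing_factors(
    model: TransitionModel,
    z: Mapping[str, float],
    transition: tuple[int, int],
) -> dict[str, float]:
    """Per-covariate contributing factors beta^(k) (z^(k) − median^(k)) on
    one transition's log-hazard.  Negative values mark low-risk covariate
    values relative to the cohort median; a covariate at (or imputed to)
    the median contributes exactly zero."""
    fit = model.transition(*transition)
    unknown = set(z) - set(fit.covariates)
    if unknown:
        raise ValueError(
            f"unknown covariates for transition {transition}: {sorted(unknown)}"
        )
    zz = impute_covariates(model, z, transition)
    return {
        c: float(b * (zz[c] - fit.medians[c]))
        for c, b in zip(fit.covariates, fit.beta)
    }
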