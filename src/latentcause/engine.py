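"""Trial-by-trial inference and learning.

Each trial is processed in two stages. First, before the outcome is
observed, a *response posterior* over causes (prior x CS likelihood)
yields the US prediction and the anticipatory conditioned response.
Then the outcome is revealed and the learner alternates a fixed number
of E-steps (posterior over the K existing causes plus one new-cause
candidate, now including the US likelihood) and M-steps (delta-rule
weight updates scaled by the posterior). The number of alternations is
set by the free interval after the trial — one "rumination" step per
whole time unit, up to a maximum — which is what makes the model
sensitive to the retrieval-extinction interval. Finally the trial is
hard-assigned to the maximum-posterior candidate (local MAP) and its
sufficient statistics are committed; earlier assignments are never
revisited.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    CauseStats,
    ModelParams,
    ModelState,
    Trial,
    crp_prior,
    cs_log_likelihood,
    normalize_log,
    us_log_likelihood,
    us_mean,
)
from . import interventions

__all__ = [
    "TrialResult",
    "ResultsTable",
    "response_posterior",
    "learning_posterior",
    "conditioned_response",
    "us_prediction",
    "m_step",
    "num_em_iterations",
    "process_trial",
    "run_schedule",
]


@dataclass(frozen=True)
class TrialResult:
    """Per-trial record of predictions, posteriors and the assignment."""

    index: int
    time: float
    phase: str
    features: np.ndarray
    outcome: float | None
    cr: float
    us_prediction: float
    response_posterior: np.ndarray
    learning_posterior: np.ndarray
    map_cause: int
    n_em_iters: int
    weights_snapshot: list[np.ndarray]


@dataclass
class ResultsTable:
    """Ordered per-trial results of one schedule run."""

    rows: list[TrialResult] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, i: int) -> TrialResult:
        return self.rows[i]

    def __iter__(self):
        return iter(self.rows)

    def phase_rows(self, phase: str) -> list[TrialResult]:
        return [r for r in self.rows if r.phase == phase]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial table; posterior columns padded with NaN."""
        if self.rows:
            n_feat = self.rows[0].features.shape[0]
            max_q = max(len(r.learning_posterior) for r in self.rows)
        else:
            n_feat, max_q = 0, 0
        records = []
        for r in self.rows:
            rec: dict[str, object] = {
                "trial": r.index,
                "time": r.time,
                "phase": r.phase,
            }
            for d in range(n_feat):
                rec[f"x{d}"] = r.features[d]
            rec["us"] = np.nan if r.outcome is None else r.outcome
            rec["cr"] = r.cr
            rec["us_prediction"] = r.us_prediction
            rec["map_cause"] = r.map_cause
            rec["n_em_iters"] = r.n_em_iters
            q = r.learning_posterior
            for k in range(max_q):
                rec[f"q_{k}"] = q[k] if k < len(q) else np.nan
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self, state: ModelState | None = None) -> dict:
        """Per-phase mean CR plus, when given the final state, weights."""
        frame = self.to_frame()
        out: dict[str, object] = {
            "n_trials": len(self.rows),
            "mean_cr_by_phase": (
                frame.groupby("phase")["cr"].mean().to_dict() if self.rows else {}
            ),
        }
        if state is not None:
            out["n_causes"] = state.n_causes
            out["final_weights"] = [c.weights.tolist() for c in state.causes]
        return out

    def to_summary_json(self, state: ModelState | None = None) -> str:
        return json.dumps(self.summary(state), sort_keys=True)


def _candidate_log_scores(
    state: ModelState,
    x: np.ndarray,
    now: float,
    params: ModelParams,
    r: float | None = None,
    new_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Unnormalized log posterior over K existing causes + the new slot."""
    if state.n_causes == 0:
        # A first cause must be instantiable even at alpha == 0 (the
        # alpha=0 model is a single-cause learner, not an empty one).
        return np.zeros(1)
    with np.errstate(divide="ignore"):  # alpha=0 -> log 0 on the new slot
        log_prior = np.log(crp_prior(state, now, params.alpha))
    candidates = list(state.causes) + [state.new_cause()]
    scores = log_prior.copy()
    for k, cause in enumerate(candidates):
        scores[k] += cs_log_likelihood(x, cause, params.sigma_x_sq)
        if r is not None:
            if k < state.n_causes:
                r_hat = us_mean(cause, x)
            else:
                w = cause.weights if new_weights is None else new_weights
                r_hat = float(w @ x)
            scores[k] += us_log_likelihood(r, r_hat, params.sigma_r_sq)
    return scores


def response_posterior(
    state: ModelState, x: np.ndarray, now: float, params: ModelParams
) -> np.ndarray:
    """Posterior over causes given the CS alone (the US is not yet seen)."""
    return normalize_log(_candidate_log_scores(state, x, now, params))


def learning_posterior(
    state: ModelState,
    x: np.ndarray,
    r: float,
    now: float,
    params: ModelParams,
    new_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior over causes given CS and US (one local-MAP E-step).

    Sufficient statistics are those committed from earlier trials only;
    ``new_weights`` optionally supplies the within-trial weights of the
    not-yet-instantiated new-cause candidate.
    """
    return normalize_log(
        _candidate_log_scores(state, x, now, params, r=r, new_weights=new_weights)
    )


def conditioned_response(r_tilde: float, theta: float, lambda_: float) -> float:
    """Sigmoidal read-out: probability that the US exceeds ``theta``.

    CR = 1 - Phi(theta; r_tilde, lambda_), with ``lambda_`` a *variance*.
    Strictly increasing in the US prediction; approaches a step function
    as ``lambda_`` shrinks.
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be strictly positive")
    return float(norm.sf(theta, loc=r_tilde, scale=math.sqrt(lambda_)))


def us_prediction(state: ModelState, q: np.ndarray, x: np.ndarray) -> float:
    """Posterior-weighted US prediction; the new-cause slot predicts 0."""
    x = np.asarray(x, dtype=float)
    r_tilde = 0.0
    for k, cause in enumerate(state.causes):
        r_tilde += float(q[k]) * us_mean(cause, x)
    return r_tilde


def m_step(
    state: ModelState,
    q: np.ndarray,
    x: np.ndarray,
    r: float,
    eta: float,
    new_weights: np.ndarray | None = None,
) -> np.ndarray | None:
    """Delta-rule weight update for every candidate cause.

    For cause k, delta_k = q_k (r - w_k . x) and w_k += eta * x * delta_k.
    Existing causes are updated in place; the new-cause candidate's
    within-trial weights are returned (unchanged ``None`` if not given).
    """
    x = np.asarray(x, dtype=float)
    for k, cause in enumerate(state.causes):
        delta = float(q[k]) * (r - us_mean(cause, x))
        cause.weights = cause.weights + eta * x * delta
    if new_weights is not None:
        delta = float(q[state.n_causes]) * (r - float(new_weights @ x))
        new_weights = new_weights + eta * x * delta
    return new_weights


def num_em_iterations(gap_to_next_event: float, params: ModelParams) -> int:
    """Rumination budget: one E/M alternation per whole free time unit.

    At least one alternation always happens (the trial itself); the
    ceiling is ``params.max_em_iters``.
    """
    if gap_to_next_event <= 0:
        raise ValueError("gap to the next event must be positive")
    return min(params.max_em_iters, max(1, math.floor(gap_to_next_event)))


def process_trial(
    state: ModelState, trial: Trial, n_iters: int, params: ModelParams
) -> TrialResult:
    """Run one trial through the model, mutating ``state``.

    The conditioned response is read out strictly before the outcome
    enters any computation. E and M steps then alternate ``n_iters``
    times with weights compounding across iterations and sufficient
    statistics frozen at their pre-trial values; the trial is finally
    committed to the argmax of the last E-step (ties to the lowest,
    i.e. oldest, cause index).
    """
    if state.causes and trial.time < max(max(c.times) for c in state.causes if c.times):
        raise ValueError("trial time regressed below the committed history")
    if trial.dim != state.dim:
        raise ValueError("trial feature dimension does not match the state")
    if n_iters < 1:
        raise ValueError("n_iters must be at least 1")

    x = trial.features
    q_resp = response_posterior(state, x, trial.time, params)
    r_tilde = us_prediction(state, q_resp, x)
    cr = conditioned_response(r_tilde, params.theta, params.lambda_)

    if trial.outcome is None:
        # Pure probe: no outcome observed, no associative learning.
        q_learn = q_resp
        new_weights = np.zeros(state.dim)
        n_done = 0
    else:
        r = float(trial.outcome)
        new_weights = np.zeros(state.dim)
        q_learn = q_resp
        for _ in range(n_iters):
            q_learn = learning_posterior(
                state, x, r, trial.time, params, new_weights=new_weights
            )
            new_weights = m_step(state, q_learn, x, r, params.eta, new_weights)
        n_done = n_iters

    z = int(np.argmax(q_learn))  # np.argmax takes the lowest index on ties
    if z == state.n_causes:
        cause = state.new_cause()
        cause.weights = new_weights
        state.causes.append(cause)
    state.causes[z].observe(trial)
    state.assignments.append(z)
    state.trial_index += 1

    return TrialResult(
        index=state.trial_index - 1,
        time=trial.time,
        phase=trial.phase,
        features=x.copy(),
        outcome=trial.outcome,
        cr=cr,
        us_prediction=r_tilde,
        response_posterior=q_resp,
        learning_posterior=q_learn,
        map_cause=z,
        n_em_iters=n_done,
        weights_snapshot=[c.weights.copy() for c in state.causes],
    )


def validate_schedule(schedule: list[Trial]) -> None:
    """Reject schedules with non-increasing times or mixed dimensions."""
    for a, b in zip(schedule, schedule[1:]):
        if b.time <= a.time:
            raise ValueError("schedule times must strictly increase")
    dims = {t.dim for t in schedule}
    if len(dims) > 1:
        raise ValueError("all trials in a schedule must share one feature dimension")


def run_schedule(
    schedule: list[Trial],
    params: ModelParams | None = None,
    return_state: bool = False,
):
    """Process a full schedule and return the per-trial results.

    The rumination budget of each trial is set by the gap to the next
    scheduled event — the next trial, or an amnestic injection attached
    to the current trial, whichever the schedule defines — and the final
    trial receives ``params.final_trial_iters``. Injections are applied
    at their stated lags through the recency-gated activation rule. The
    run is deterministic: identical inputs give identical tables.
    """
    params = params or ModelParams()
    validate_schedule(schedule)
    if not schedule:
        table = ResultsTable()
        return (table, ModelState(dim=0)) if return_state else table

    state = ModelState(dim=schedule[0].dim)
    table = ResultsTable()
    for i, trial in enumerate(schedule):
        if trial.psi is not None:
            gap = trial.psi.lag
            n_iters = num_em_iterations(gap, params) if gap > 0 else 1
        elif i + 1 < len(schedule):
            n_iters = num_em_iterations(schedule[i + 1].time - trial.time, params)
        else:
            n_iters = params.final_trial_iters
        result = process_trial(state, trial, n_iters, params)
        table.rows.append(result)
        if trial.psi is not None:
            window = (
                trial.psi.window if trial.psi.window is not None else params.psi_window
            )
            activation = interventions.psi_activation(
                state, result, trial.time + trial.psi.lag, window
            )
            if trial.psi.decrement:
                interventions.apply_psi(state, activation)
    return (table, state) if return_state else table
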