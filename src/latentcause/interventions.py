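"""Amnestic-agent modeling and stimulus-feature extensions.

A protein-synthesis inhibitor (PSI) injected after a trial weakens each
cause's associative weights in proportion to the posterior probability
that the cause was active on that trial: w_k <- w_k * (1 - q_k). A
recency gate formalizes why delayed injections are inert: if the
injection arrives more than ``window`` time units after the trial, no
cause is considered active any more and the decrement has no target.

The drug state itself can additionally be represented as an ordinary
stimulus feature (state-dependency), in which case it takes part in the
CS likelihood and the US prediction like any other feature.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable

import numpy as np

from .core import ModelState, Trial
from .core import PsiEvent  # noqa: F401  (re-exported; defined with Trial)

if TYPE_CHECKING:  # pragma: no cover
    from .engine import TrialResult

__all__ = ["PsiEvent", "psi_activation", "apply_psi", "inject_state_feature"]


def psi_activation(
    state: ModelState,
    last_result: "TrialResult",
    admin_time: float,
    window: float,
) -> np.ndarray:
    """Cause activations targeted by an injection after ``last_result``.

    Within the recency gate (lag <= window, closed boundary) the
    activation is the last trial's learning posterior restricted to the
    causes that actually exist; outside it no cause is active and the
    all-zero vector is returned.
    """
    lag = admin_time - last_result.time
    if lag < 0:
        raise ValueError("administration cannot precede the trial it follows")
    if lag > window:
        return np.zeros(state.n_causes)
    # The learning posterior has one trailing slot for a new-cause
    # candidate; it is part of the activation only if that candidate was
    # actually instantiated on the trial.
    return np.asarray(last_result.learning_posterior[: state.n_causes], dtype=float)


def apply_psi(state: ModelState, activation: np.ndarray) -> ModelState:
    """Decrement every cause's weights: w_k <- w_k * (1 - q_k).

    Sufficient statistics (counts, means, times) are untouched; the
    memory trace is weakened, not erased.
    """
    activation = np.asarray(activation, dtype=float)
    if activation.shape[0] != state.n_causes:
        raise ValueError("activation is not aligned with the instantiated causes")
    if np.any(activation < 0) or np.any(activation > 1):
        raise ValueError("activation entries must lie in [0, 1]")
    for q_k, cause in zip(activation, state.causes):
        cause.weights = cause.weights * (1.0 - float(q_k))
    return state


def inject_state_feature(
    schedule: list[Trial], drug_trials: Iterable[int]
) -> list[Trial]:
    """Append a drug-state feature: 1 on ``drug_trials``, 0 elsewhere.

    Returns a new schedule of dimension D+1 with all other trial fields
    preserved. The appended feature is an ordinary CS — no special
    casing anywhere downstream.
    """
    drug = set(drug_trials)
    bad = [i for i in drug if not 0 <= i < len(schedule)]
    if bad:
        raise ValueError(f"drug trial indices out of range: {sorted(bad)}")
    out = []
    for i, t in enumerate(schedule):
        feats = np.concatenate([t.features, [1.0 if i in drug else 0.0]])
        out.append(
            Trial(
                time=t.time,
                features=feats,
                outcome=t.outcome,
                phase=t.phase,
                psi=t.psi,
            )
        )
    return out
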