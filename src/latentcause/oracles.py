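"""Brute-force references and randomized schedules for verification.

Everything here exists to check the incremental engine against an
independent computation: a closed-form Rescorla-Wagner recursion, a
from-scratch recomputation of sufficient statistics, and an exact
posterior over cause assignments obtained by enumerating every
partition of a short trial prefix. The exact-enumeration oracle is a
diagnostic of the local-MAP approximation, not part of the production
path. This is also the only module with any randomness; the model core
is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    CauseStats,
    ModelParams,
    Trial,
    cs_log_likelihood,
    normalize_log,
    temporal_kernel,
    us_log_likelihood,
)

__all__ = [
    "RandomScheduleConfig",
    "rw_reference",
    "stats_from_scratch",
    "enumerate_exact_posterior",
    "generate_schedule",
]

_MAX_ENUM_TRIALS = 8


@dataclass(frozen=True)
class RandomScheduleConfig:
    """Reproducible random-schedule settings for property tests."""

    n_trials: int
    dim: int = 1
    seed: int = 0
    time_gap_range: tuple[float, float] = (0.5, 5.0)
    feature_sparsity: float = 0.0
    reinforcement_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_trials < 0 or self.dim < 1:
            raise ValueError("invalid schedule size")
        lo, hi = self.time_gap_range
        if not 0 < lo <= hi:
            raise ValueError("time gaps must be positive")
        if not 0 <= self.feature_sparsity <= 1:
            raise ValueError("feature_sparsity must lie in [0, 1]")
        if not 0 <= self.reinforcement_prob <= 1:
            raise ValueError("reinforcement_prob must lie in [0, 1]")


def rw_reference(schedule: list[Trial], eta: float) -> np.ndarray:
    """Closed-form Rescorla-Wagner weight trajectory.

    One update per trial: w <- w + eta * x * (r - w . x). Returns the
    (n_trials, D) array of post-update weights. Probe trials (outcome
    ``None``) leave the weights unchanged.
    """
    if not schedule:
        return np.zeros((0, 0))
    w = np.zeros(schedule[0].dim)
    traj = []
    for t in schedule:
        if t.outcome is not None:
            delta = float(t.outcome) - float(w @ t.features)
            w = w + eta * t.features * delta
        traj.append(w.copy())
    return np.array(traj)


def stats_from_scratch(
    trials: list[Trial], assignments: list[int]
) -> list[CauseStats]:
    """Recompute every cause's sufficient statistics by direct summation."""
    if len(trials) != len(assignments):
        raise ValueError("one assignment per trial is required")
    if not trials:
        return []
    n_causes = max(assignments) + 1 if assignments else 0
    if sorted(set(assignments)) != list(range(n_causes)):
        raise ValueError("assignments must use contiguous cause labels")
    causes = [CauseStats(dim=trials[0].dim) for _ in range(n_causes)]
    for trial, z in zip(trials, assignments):
        causes[z].observe(trial)
    return causes


def _history_log_joint(
    trials: list[Trial], history: tuple[int, ...], params: ModelParams
) -> float:
    """Log joint of one full assignment history under the internal model.

    Weights are held at zero throughout (pre-learning), so the US term
    is constant across partitions; it is included for completeness.
    """
    log_p = 0.0
    causes: list[CauseStats] = []
    for t_idx, (trial, z) in enumerate(zip(trials, history)):
        k_existing = len(causes)
        if t_idx == 0:
            prior = 1.0 if z == 0 else 0.0
        else:
            mass = [c.kernel_mass(trial.time) for c in causes] + [params.alpha]
            total = sum(mass)
            prior = mass[z] / total if total > 0 else (1.0 if z == 0 else 0.0)
        if prior == 0.0:
            return -math.inf
        log_p += math.log(prior)
        if z == k_existing:
            causes.append(CauseStats(dim=trial.dim))
        log_p += cs_log_likelihood(trial.features, causes[z], params.sigma_x_sq)
        if trial.outcome is not None:
            log_p += us_log_likelihood(
                float(trial.outcome), 0.0, params.sigma_r_sq
            )
        causes[z].observe(trial)
    return log_p


def enumerate_exact_posterior(
    trials: list[Trial], params: ModelParams
) -> dict:
    """Exact posterior over cause assignments by full enumeration.

    Sums over every canonically-labelled assignment history of the
    prefix (Bell-number growth, hence the hard guard at
    ``len(trials) <= 8``). Returns the marginal posterior over the last
    trial's cause, the per-history posterior, and the MAP history.
    Weights are fixed at zero, so this is an oracle for the structure
    side of inference (run the engine with eta=0 to compare).
    """
    t = len(trials)
    if t == 0:
        raise ValueError("need at least one trial")
    if t > _MAX_ENUM_TRIALS:
        raise ValueError(
            f"exact enumeration is guarded at {_MAX_ENUM_TRIALS} trials "
            f"(got {t}); the partition count grows like the Bell numbers"
        )

    histories: list[tuple[int, ...]] = [()]
    for _ in range(t):
        nxt = []
        for h in histories:
            k = max(h) + 1 if h else 0
            for z in range(k + 1):
                nxt.append(h + (z,))
        histories = nxt

    log_joints = np.array(
        [_history_log_joint(trials, h, params) for h in histories]
    )
    finite = np.isfinite(log_joints)
    if not finite.any():
        raise ValueError("no assignment history has positive probability")
    post = np.zeros(len(histories))
    post[finite] = normalize_log(log_joints[finite])

    n_last = max(h[-1] for h in histories) + 1
    marginal = np.zeros(n_last)
    for p, h in zip(post, histories):
        marginal[h[-1]] += p
    map_idx = int(np.argmax(post))
    return {
        "histories": histories,
        "posterior": post,
        "marginal_last": marginal,
        "map_history": histories[map_idx],
    }


def generate_schedule(config: RandomScheduleConfig) -> list[Trial]:
    """Reproducible random schedule with strictly increasing times."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.time_gap_range
    gaps = rng.uniform(lo, hi, size=config.n_trials)
    times = np.cumsum(gaps)
    trials = []
    for i in range(config.n_trials):
        x = (rng.random(config.dim) >= config.feature_sparsity).astype(float)
        r = 1.0 if rng.random() < config.reinforcement_prob else 0.0
        trials.append(Trial(time=float(times[i]), features=x, outcome=r))
    return trials
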