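"""Domain types and the internal generative model.

The model assumes each trial was generated by a single latent cause. A
cause emits a CS configuration from an isotropic Gaussian (with a
conjugate zero-mean prior on the per-feature means) and a US whose mean
is a cause-specific linear function of the CS features. A priori, causes
follow a time-sensitive Chinese restaurant process: the probability that
an old cause generated the current trial is proportional to a power-law
kernel sum over the trials already assigned to it, while a brand-new
cause has constant mass ``alpha``.

Everything here is deterministic and side-effect free; the trial-by-trial
engine lives in :mod:`latentcause.engine`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Trial",
    "PsiEvent",
    "ModelParams",
    "CauseStats",
    "ModelState",
    "temporal_kernel",
    "crp_prior",
    "feature_predictive",
    "cs_log_likelihood",
    "us_mean",
    "us_log_likelihood",
    "normalize_log",
    "validate_posterior",
]

LOG_2PI = math.log(2.0 * math.pi)

# Variance of the zero-mean prior on a cause's per-feature mean. The
# internal model fixes this to 1; it is deliberately not a parameter.
MU_PRIOR_VAR = 1.0


@dataclass(frozen=True)
class PsiEvent:
    """A protein-synthesis-inhibitor (amnestic agent) administration.

    Attached to the trial it follows. ``lag`` is the delay between the
    trial and the injection, in model time units. ``window`` is the
    recency gate: if the injection arrives more than ``window`` units
    after the trial, no cause counts as active and the agent has no
    target (``None`` defers to ``ModelParams.psi_window``). ``decrement``
    can be switched off to model the drug state without its
    weight-weakening action.
    """

    lag: float = 0.0
    window: float | None = None
    decrement: bool = True

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("PSI lag must be nonnegative")
        if self.window is not None and self.window <= 0:
            raise ValueError("PSI window must be positive")


@dataclass(frozen=True)
class Trial:
    """One timestamped observation: CS features, US outcome, phase tag.

    ``time`` is in model time units (24 hr corresponds to 20 units).
    ``features`` is the CS configuration x_t — typically unit impulses,
    but fractional values are allowed (e.g. a 0.8-similar context).
    ``outcome`` is the US intensity r_t; ``None`` marks a pure probe on
    which no outcome is observed (the US likelihood and the weight
    update are then skipped). ``psi`` optionally attaches an amnestic
    injection administered after this trial.
    """

    time: float
    features: np.ndarray
    outcome: float | None = None
    phase: str = "other"
    psi: PsiEvent | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.features, dtype=float)
        if x.ndim != 1:
            raise ValueError("trial features must be a 1-D vector")
        if not np.all(np.isfinite(x)):
            raise ValueError("trial features must be finite")
        object.__setattr__(self, "features", x)
        if self.time < 0 or not math.isfinite(self.time):
            raise ValueError("trial time must be a finite nonnegative real")
        if self.outcome is not None and not math.isfinite(self.outcome):
            raise ValueError("trial outcome must be finite")

    @property
    def dim(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters with the standard simulation defaults.

    alpha
        Concentration of the time-sensitive CRP; the unnormalized mass
        of a brand-new cause. ``alpha=0`` recovers the Rescorla-Wagner
        model exactly.
    eta
        Delta-rule learning rate (absorbs the 1/sigma_r_sq gradient
        factor).
    sigma_r_sq
        US emission variance; lower values make the learner more
        sensitive to US prediction errors.
    sigma_x_sq
        CS emission variance.
    theta, lambda_
        Threshold and variance of the sigmoidal response mapping
        CR = 1 - Phi(theta; us_prediction, lambda_).
    max_em_iters
        Ceiling on the number of E/M alternations ("rumination" steps)
        following a trial; one step per whole time unit of free interval.
    psi_window
        Recency gate for amnestic injections, in time units.
    final_trial_iters
        E/M alternations granted to the last trial of a schedule, whose
        trailing interval is unspecified.
    """

    alpha: float = 0.1
    eta: float = 0.3
    sigma_r_sq: float = 0.4
    sigma_x_sq: float = 1.0
    theta: float = 0.02
    lambda_: float = 0.01
    max_em_iters: int = 3
    psi_window: float = 3.0
    final_trial_iters: int = 1

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must lie in (0, 1]")
        if self.sigma_r_sq <= 0 or self.sigma_x_sq <= 0 or self.lambda_ <= 0:
            raise ValueError("variances must be strictly positive")
        if self.max_em_iters < 1 or self.final_trial_iters < 1:
            raise ValueError("iteration counts must be positive integers")
        if self.psi_window <= 0:
            raise ValueError("psi_window must be positive")

    def with_overrides(self, **overrides: float) -> "ModelParams":
        return replace(self, **overrides)


@dataclass
class CauseStats:
    """Sufficient statistics and associative weights of one latent cause.

    ``count`` is the number of trials hard-assigned to the cause so far,
    ``feature_sum`` the running per-feature sum over those trials (so
    ``feature_sum / count`` is the running mean), ``times`` their
    timestamps (inputs to the CRP kernel sum), and ``weights`` the
    cause's CS->US associative weight vector.
    """

    dim: int
    count: int = 0
    feature_sum: np.ndarray = None  # type: ignore[assignment]
    times: list[float] = field(default_factory=list)
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_sum is None:
            self.feature_sum = np.zeros(self.dim)
        if self.weights is None:
            self.weights = np.zeros(self.dim)
        self.feature_sum = np.asarray(self.feature_sum, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)

    def kernel_mass(self, now: float) -> float:
        """Unnormalized CRP mass of this cause at query time ``now``."""
        return float(sum(temporal_kernel(now - t) for t in self.times))

    def observe(self, trial: Trial) -> None:
        """Commit a trial to this cause's sufficient statistics."""
        self.count += 1
        self.feature_sum = self.feature_sum + trial.features
        self.times.append(trial.time)

    def copy(self) -> "CauseStats":
        return CauseStats(
            dim=self.dim,
            count=self.count,
            feature_sum=self.feature_sum.copy(),
            times=list(self.times),
            weights=self.weights.copy(),
        )


@dataclass
class ModelState:
    """The learner's memory: instantiated causes plus the hard history.

    Causes are kept in creation order, so indices are stable. Every
    entry of ``assignments`` indexes an existing cause.
    """

    dim: int
    causes: list[CauseStats] = field(default_factory=list)
    assignments: list[int] = field(default_factory=list)
    trial_index: int = 0

    @property
    def n_causes(self) -> int:
        return len(self.causes)

    def new_cause(self) -> CauseStats:
        """A fresh candidate cause: zero statistics, zero weights."""
        return CauseStats(dim=self.dim)

    def copy(self) -> "ModelState":
        return ModelState(
            dim=self.dim,
            causes=[c.copy() for c in self.causes],
            assignments=list(self.assignments),
            trial_index=self.trial_index,
        )

    def to_json(self) -> str:
        """Serialize to JSON for debugging snapshots."""
        payload = {
            "dim": self.dim,
            "trial_index": self.trial_index,
            "assignments": self.assignments,
            "causes": [
                {
                    "count": c.count,
                    "feature_sum": c.feature_sum.tolist(),
                    "times": c.times,
                    "weights": c.weights.tolist(),
                }
                for c in self.causes
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, payload: str) -> "ModelState":
        data = json.loads(payload)
        state = cls(dim=data["dim"], trial_index=data["trial_index"])
        state.assignments = list(data["assignments"])
        for c in data["causes"]:
            state.causes.append(
                CauseStats(
                    dim=state.dim,
                    count=c["count"],
                    feature_sum=np.asarray(c["feature_sum"]),
                    times=list(c["times"]),
                    weights=np.asarray(c["weights"]),
                )
            )
        return state


def temporal_kernel(delta_t: float) -> float:
    """Power-law kernel K(dt) = 1/dt, with K(0) defined as 0.

    The zero at the origin means simultaneous events lend each other no
    cause-sharing mass; it also makes remote pairs of events
    progressively indistinguishable (temporal compression).
    """
    if delta_t < 0:
        raise ValueError("temporal_kernel requires a nonnegative interval")
    if delta_t == 0:
        return 0.0
    return 1.0 / delta_t


def crp_prior(state: ModelState, now: float, alpha: float) -> np.ndarray:
    """Time-sensitive CRP prior over the K existing causes plus one new slot.

    The unnormalized mass of old cause k is the kernel sum over the
    trials assigned to it; the new-cause slot carries mass ``alpha``.
    Returns a normalized probability vector of length K+1.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    mass = np.array([c.kernel_mass(now) for c in state.causes] + [alpha])
    total = mass.sum()
    if total <= 0:
        raise ValueError(
            "degenerate prior: no old-cause mass and alpha == 0 leaves no valid cause"
        )
    return mass / total


def feature_predictive(
    cause: CauseStats, sigma_x_sq: float
) -> tuple[np.ndarray, float]:
    """Posterior-predictive mean and (shared) variance of the CS features.

    With a standard-normal prior on each per-feature emission mean and
    N trials assigned to the cause, the predictive for a new trial is
    Gaussian with mean ``N * xbar / (N + sigma_x_sq)`` per feature and a
    single shared variance ``sigma_x_sq / (N + sigma_x_sq) + sigma_x_sq``.
    The variance is shared across features because assignment happens
    per-trial, so all features have the same count.
    """
    if sigma_x_sq <= 0:
        raise ValueError("sigma_x_sq must be strictly positive")
    n = cause.count
    denom = n + sigma_x_sq / MU_PRIOR_VAR
    x_hat = cause.feature_sum / denom
    nu_sq = sigma_x_sq / denom + sigma_x_sq
    return x_hat, float(nu_sq)


def _gauss_logpdf(x: float, mean: float, var: float) -> float:
    d = x - mean
    return -0.5 * (LOG_2PI + math.log(var)) - d * d / (2.0 * var)


def cs_log_likelihood(
    x: np.ndarray, cause: CauseStats, sigma_x_sq: float
) -> float:
    """Log posterior-predictive density of a CS configuration under a cause."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != cause.dim:
        raise ValueError("feature dimension mismatch")
    x_hat, nu_sq = feature_predictive(cause, sigma_x_sq)
    d = x - x_hat
    return float(
        -0.5 * x.shape[0] * (LOG_2PI + math.log(nu_sq))
        - float(d @ d) / (2.0 * nu_sq)
    )


def us_mean(cause: CauseStats, x: np.ndarray) -> float:
    """US prediction of one cause: inner product of weights and features."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != cause.dim:
        raise ValueError("feature dimension mismatch")
    return float(cause.weights @ x)


def us_log_likelihood(r: float, r_hat: float, sigma_r_sq: float) -> float:
    """Log Gaussian density of the US under a cause's prediction."""
    if sigma_r_sq <= 0:
        raise ValueError("sigma_r_sq must be strictly positive")
    return _gauss_logpdf(r, r_hat, sigma_r_sq)


def normalize_log(log_mass: Sequence[float]) -> np.ndarray:
    """Exponentiate-and-normalize with a max-subtraction guard.

    Entries of ``-inf`` (zero prior mass) are supported; the result is
    renormalized to sum to 1 at machine precision.
    """
    log_mass = np.asarray(log_mass, dtype=float)
    m = np.max(log_mass)
    if not np.isfinite(m):
        raise ValueError("all candidates have zero probability")
    p = np.exp(log_mass - m)
    p /= p.sum()
    return p


def validate_posterior(q: np.ndarray, n_slots: int | None = None) -> np.ndarray:
    """Check nonnegativity and normalization of a posterior vector."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("posterior has negative entries")
    if abs(q.sum() - 1.0) > 1e-12:
        raise ValueError("posterior does not sum to 1")
    if n_slots is not None and q.shape[0] != n_slots:
        raise ValueError("posterior has the wrong number of slots")
    return q
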