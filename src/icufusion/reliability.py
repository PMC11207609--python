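"""Fault tolerance of a repairable streaming cluster, closed form + Monte Carlo.

Model: an ``I``-node cluster whose node lifetimes ``t_i`` are i.i.d.
exponential with mean ``1/lambda`` (hours) and whose repair durations are
i.i.d. exponential with mean ``r`` hours.  Each node fails at most once per
cycle.  Writing ``t_(1) <= ... <= t_(I)`` for the order statistics, the
cluster *fails* when, at the instant ``t_(I)`` of the last failure, every
earlier-failed node is still under repair — i.e. all ``I`` nodes are down
simultaneously.

With ``gamma = mean_repair / mean_lifetime``, memorylessness of the repairs
and the independent exponential spacings ``t_(k+1) - t_(k) ~ Exp((I-k) *
lambda)`` give the closed form

    PF(I) = prod_{k=1}^{I-1} (I-k) * gamma / ((I-k) * gamma + k)

which specializes to ``PF(2) = gamma / (1 + gamma)`` and
``PF(3) = 2 gamma^2 / ((2 gamma + 1)(gamma + 2))``.

:func:`simulate_failure` is the independent Monte-Carlo oracle over the same
timing model; :func:`max_repair_time` inverts PF(I) to find the repair
deadline that keeps the failure probability below a target (with a one-year
mean lifetime of 8760 h and target 1e-6 for three nodes it lands near 8.8 h,
i.e. a nine-hour repair window); :func:`improvement` quantifies the gain of
a third node, ``(PF2 - PF3) / PF2``, which exceeds 99.9% for gamma <= 1e-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HOURS_PER_YEAR",
    "ReliabilityParams",
    "FailureTimeline",
    "FailureEstimate",
    "pf2",
    "pf3",
    "pf_general",
    "improvement",
    "simulate_failure",
    "sample_timeline",
    "max_repair_time",
    "UnattainableTargetError",
]

HOURS_PER_YEAR = 8760.0  # 365 days


class UnattainableTargetError(ValueError):
    """No repair time in the search bracket reaches the target probability."""


@dataclass(frozen=True)
class ReliabilityParams:
    """Cluster parameters; ``gamma`` is always recomputed from the means."""

    I: int
    mean_lifetime: float  # hours, = 1/lambda
    mean_repair: float  # hours

    def __post_init__(self) -> None:
        if self.I < 2:
            raise ValueError(f"node count I must be >= 2, got {self.I}")
        if self.mean_lifetime <= 0:
            raise ValueError(f"mean_lifetime must be positive, got {self.mean_lifetime}")
        if self.mean_repair <= 0:
            raise ValueError(f"mean_repair must be positive, got {self.mean_repair}")

    @property
    def gamma(self) -> float:
        return self.mean_repair / self.mean_lifetime


@dataclass
class FailureTimeline:
    """One realization of the failure/repair cycle (times in hours).

    ``tau`` are failure instants (cycle origin at 0), ``tau_star`` the
    corresponding repair completions, ``d`` the repair durations.
    """

    lifetimes: np.ndarray  # t_i, unsorted
    order_stats: np.ndarray  # t_(i), ascending
    tau: np.ndarray  # failure instants = order stats
    tau_star: np.ndarray  # repair completions
    d: np.ndarray  # repair durations

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.order_stats) >= 0):
            raise ValueError("order statistics must be ascending")
        if not np.all(self.tau_star > self.tau):
            raise ValueError("repair completion must follow failure")


@dataclass(frozen=True)
class FailureEstimate:
    estimate: float
    standard_error: float
    n_replications: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.estimate <= 1:
            raise ValueError("estimate must be a probability")


def _check_gamma(gamma: float) -> None:
    if gamma < 0:
        raise ValueError(f"gamma must be non-negative, got {gamma}")


def pf2(gamma: float) -> float:
    """Two-node cluster failure probability, ``gamma / (1 + gamma)``."""
    _check_gamma(gamma)
    return gamma / (1.0 + gamma)


def pf3(gamma: float) -> float:
    """Three-node cluster failure probability,
    ``2 gamma^2 / ((2 gamma + 1)(gamma + 2))``."""
    _check_gamma(gamma)
    return 2.0 * gamma**2 / ((2.0 * gamma + 1.0) * (gamma + 2.0))


def pf_general(I: int, gamma: float) -> float:
    """All-down probability for an ``I``-node cluster.

    ``prod_{k=1}^{I-1} (I-k) gamma / ((I-k) gamma + k)``; reduces exactly to
    :func:`pf2` at I=2 and :func:`pf3` at I=3.
    """
    if I < 2:
        raise ValueError(f"node count I must be >= 2, got {I}")
    _check_gamma(gamma)
    p = 1.0
    for k in range(1, I):
        m = I - k
        p *= m * gamma / (m * gamma + k)
    return p


def improvement(gamma: float) -> float:
    """Relative failure-probability reduction of a third node,
    ``(PF2 - PF3) / PF2 = 1 - 2 gamma (1 + gamma) / ((2 gamma + 1)(gamma + 2))``."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive (0/0 at gamma=0), got {gamma}")
    return 1.0 - 2.0 * gamma * (1.0 + gamma) / ((2.0 * gamma + 1.0) * (gamma + 2.0))


def sample_timeline(params: ReliabilityParams, seed: int = 0) -> FailureTimeline:
    """Draw one failure/repair realization of the timing model."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(params.mean_lifetime, params.I)
    order = np.argsort(t)
    ts = t[order]
    d = rng.exponential(params.mean_repair, params.I)[order]
    return FailureTimeline(lifetimes=t, order_stats=ts, tau=ts, tau_star=ts + d, d=d)


def simulate_failure(
    I: int,
    mean_lifetime: float,
    mean_repair: float,
    n_replications: int,
    seed: int = 0,
    event: str = "all_down",
) -> FailureEstimate:
    """Monte-Carlo estimate of the cluster failure probability.

    Each replication draws ``I`` exponential lifetimes and repair durations.
    Under the default ``event="all_down"`` a replication fails iff every
    earlier-failed node is still unrepaired at the last failure instant
    ``t_(I)`` — the event whose probability the closed forms give.
    ``event="any_overlap"`` is the conservative indicator derived from the
    sufficient operating condition ``t_(i) + d_i <= t_(I)`` for all i: it
    counts a failure as soon as any single repair overruns ``t_(I)``.
    """
    params = ReliabilityParams(I=I, mean_lifetime=mean_lifetime, mean_repair=mean_repair)
    if n_replications < 1:
        raise ValueError(f"n_replications must be >= 1, got {n_replications}")
    if event not in ("all_down", "any_overlap"):
        raise ValueError(f"unknown event {event!r}")
    rng = np.random.default_rng(seed)
    failures = 0
    chunk = 200_000
    remaining = n_replications
    while remaining > 0:
        n = min(chunk, remaining)
        t = rng.exponential(params.mean_lifetime, (n, I))
        d = rng.exponential(params.mean_repair, (n, I))
        order = np.argsort(t, axis=1)
        ts = np.take_along_axis(t, order, axis=1)
        ds = np.take_along_axis(d, order, axis=1)
        overrun = ts[:, :-1] + ds[:, :-1] > ts[:, -1:]
        if event == "all_down":
            failures += int(np.all(overrun, axis=1).sum())
        else:
            failures += int(np.any(overrun, axis=1).sum())
        remaining -= n
    p = failures / n_replications
    se = math.sqrt(p * (1.0 - p) / n_replications)
    return FailureEstimate(estimate=p, standard_error=se, n_replications=n_replications, seed=seed)


def max_repair_time(
    I: int,
    mean_lifetime: float,
    target_pf: float,
    gamma_bracket: tuple[float, float] = (1e-9, 1e3),
) -> tuple[float, int]:
    """Mean repair time (hours) at which PF(I) equals ``target_pf``.

    Solves ``pf_general(I, r / mean_lifetime) == target_pf`` by monotone
    root-finding on log-gamma to 1e-9 relative tolerance.  Returns the exact
    solution and its value rounded to the nearest hour.
    """
    if not 0 < target_pf < 1:
        raise UnattainableTargetError(
            f"target probability must be strictly inside (0, 1), got {target_pf}"
        )
    if mean_lifetime <= 0:
        raise ValueError(f"mean_lifetime must be positive, got {mean_lifetime}")
    lo, hi = gamma_bracket

    def objective(log_gamma: float) -> float:
        return math.log(pf_general(I, math.exp(log_gamma))) - math.log(target_pf)

    f_lo, f_hi = objective(math.log(lo)), objective(math.log(hi))
    if f_lo > 0 or f_hi < 0:
        raise UnattainableTargetError(
            f"PF({I}) does not reach {target_pf} inside gamma bracket {gamma_bracket}"
        )
    log_gamma = brentq(objective, math.log(lo), math.log(hi), rtol=1e-12, xtol=1e-14)
    repair_h = math.exp(log_gamma) * mean_lifetime
    return repair_h, round(repair_h)
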