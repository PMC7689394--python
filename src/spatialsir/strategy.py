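"""Control-strategy optimization in the (K, Q) structural parameter space.

A country sits at (K0, Q0) with lattice epidemic threshold
beta_c_2d(K0, Q0).  When an epidemic with infection probability
beta > beta_c_2d arrives, quarantine strategies move the country to a
point with beta_c_2d(K, Q) >= beta: reducing K alone (local quarantine,
within cities), Q alone (global quarantine, between cities), or both
(mixed).  The candidate points live on the critical line
beta_c_2d(K, Q) = beta*(1 + eps) (a small margin keeps the target
strictly below threshold, since the line itself is the open boundary);
a weight function — Euclidean distance in (K, Q) by default, standing
in for the social and economic cost of removing links — is minimized
over the line, restricted to K <= K0, Q <= Q0 because quarantines only
remove infection channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .exceptions import InfeasibleError, ParameterError
from .theory import SQUARE, LatticeSpec, critical_beta_2d, critical_Q

__all__ = [
    "StrategyProblem",
    "CriticalLine",
    "OptimizationResult",
    "critical_line",
    "euclidean_weight",
    "optimize_strategy",
    "classify_social_strategy",
    "q_to_k_inter",
]

Weight = Callable[[float, float], float]


@dataclass
class StrategyProblem:
    """One country + one epidemic.

    ``epsilon`` is the relative margin by which the target threshold
    exceeds beta.  ``weight`` defaults to Euclidean distance from
    (K0, Q0).
    """

    K0: float
    Q0: float
    beta: float
    lattice: LatticeSpec = SQUARE
    epsilon: float = 1e-3
    weight: Optional[Weight] = field(default=None)

    def __post_init__(self) -> None:
        if self.K0 <= 0 or self.Q0 <= 0:
            raise ParameterError("K0 and Q0 must be positive")
        if not (0.0 < self.beta <= 1.0):
            raise ParameterError("beta must lie in (0, 1]")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")
        if self.weight is None:
            self.weight = euclidean_weight(self.K0, self.Q0)

    @property
    def needs_action(self) -> bool:
        """False when the country already sits below threshold."""
        return self.beta > critical_beta_2d(self.K0, self.Q0, self.lattice)


@dataclass(frozen=True)
class CriticalLine:
    """Discretized beta_c_2d(K, Q) = beta_target line."""

    K: np.ndarray
    Q: np.ndarray
    beta_target: float
    skipped: int  # grid K values with no admissible Q


@dataclass(frozen=True)
class OptimizationResult:
    K_opt: float
    Q_opt: float
    W_opt: float
    strategy: str  # 'local' | 'global' | 'mixed'


def euclidean_weight(K0: float, Q0: float) -> Weight:
    """Euclidean distance from (K0, Q0) in raw parameter units — the
    minimal-total-reduction cost proxy."""

    def w(K: float, Q: float) -> float:
        return float(np.hypot(K0 - K, Q0 - Q))

    return w


def critical_line(
    beta: float,
    lattice: LatticeSpec = SQUARE,
    K_range: tuple[float, float] = (0.5, 20.0),
    n_points: int = 200,
    epsilon: float = 1e-3,
) -> CriticalLine:
    """Sample the critical line beta_c_2d(K, Q) = beta*(1+eps).

    For each K in the range the matching Q comes from the numeric
    inversion; K values below the feasibility bound 1/beta_target admit
    no Q (the threshold stays below beta even as Q -> infinity) and are
    skipped with a count.
    """
    beta_target = min(beta * (1.0 + epsilon), 1.0)
    if beta_target <= 0:
        raise ParameterError("beta must be positive")
    Ks = np.linspace(K_range[0], K_range[1], n_points)
    out_K, out_Q = [], []
    skipped = 0
    for K in Ks:
        if K <= 0 or beta_target <= 1.0 / K:
            skipped += 1
            continue
        out_K.append(float(K))
        out_Q.append(critical_Q(beta_target, float(K), lattice))
    if not out_K:
        raise InfeasibleError(
            f"no K in {K_range} admits a critical Q at beta={beta}; "
            "widen the range or lower beta"
        )
    return CriticalLine(
        K=np.asarray(out_K), Q=np.asarray(out_Q), beta_target=beta_target, skipped=skipped
    )


def _label(K0: float, Q0: float, K: float, Q: float, tol: float = 1e-3) -> str:
    """Strategy class from which coordinates moved; ``tol`` is relative
    and coarse enough to absorb the critical-line grid resolution."""
    moved_K = K < K0 * (1.0 - tol)
    moved_Q = Q < Q0 * (1.0 - tol)
    if moved_K and moved_Q:
        return "mixed"
    if moved_K:
        return "local"
    return "global"


def optimize_strategy(problem: StrategyProblem, n_points: int = 400) -> OptimizationResult:
    """Minimize the weight over the critical line within the quarantine
    region K <= K0, Q <= Q0.

    Ties (within 1e-12 of the optimum) break toward the smaller total
    relative reduction (K0-K)/K0 + (Q0-Q)/Q0.  Because beta_c_2d grows
    without bound as Q -> 0, a pure between-cities quarantine is always
    feasible, so the restricted line is never empty when the problem
    needs action at all.
    """
    if not problem.needs_action:
        return OptimizationResult(
            K_opt=problem.K0,
            Q_opt=problem.Q0,
            W_opt=0.0,
            strategy="none",
        )
    beta_target = min(problem.beta * (1.0 + problem.epsilon), 1.0)
    K_min = 1.0 / beta_target
    # K grid spans (K_min, K0]; Q(K) on the line decreases with K, and we
    # keep only Q <= Q0
    lo = min(K_min * (1.0 + 1e-9), problem.K0)
    line = critical_line(
        problem.beta,
        problem.lattice,
        K_range=(lo, problem.K0),
        n_points=n_points,
        epsilon=problem.epsilon,
    )
    mask = line.Q <= problem.Q0 * (1.0 + 1e-12)
    if not mask.any():
        raise InfeasibleError(
            "no point on the critical line lies within the quarantine region; "
            "only the social strategy (reducing beta itself) remains"
        )
    Ks, Qs = line.K[mask], line.Q[mask]
    w = np.array([problem.weight(k, q) for k, q in zip(Ks, Qs)])
    best = w.min()
    tied = np.flatnonzero(w <= best + 1e-12)
    if tied.size > 1:
        reduction = (problem.K0 - Ks[tied]) / problem.K0 + (problem.Q0 - Qs[tied]) / problem.Q0
        pick = tied[int(np.argmin(reduction))]
    else:
        pick = int(tied[0])
    K_opt, Q_opt = float(Ks[pick]), float(Qs[pick])
    return OptimizationResult(
        K_opt=K_opt,
        Q_opt=Q_opt,
        W_opt=float(w[pick]),
        strategy=_label(problem.K0, problem.Q0, K_opt, Q_opt),
    )


def classify_social_strategy(
    beta: float, beta_prime: float, K: float, Q: float, lattice: LatticeSpec = SQUARE
) -> bool:
    """True when reducing the infection probability to beta' alone
    suffices: beta' < beta_c_2d(K, Q)."""
    if not (0.0 <= beta_prime <= beta):
        raise ParameterError("beta' must lie in [0, beta]")
    return beta_prime < critical_beta_2d(K, Q, lattice)


def q_to_k_inter(Q: float, zeta: int) -> float:
    """Translate a per-community inter-link budget Q into the per-node
    rate k_inter = Q / zeta**2 (zeta rarely changes on epidemic
    timescales, so Q is controlled through k_inter)."""
    if zeta < 1:
        raise ParameterError("zeta must be a positive integer")
    return Q / (zeta * zeta)
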