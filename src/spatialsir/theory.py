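"""Closed-form epidemic-threshold theory for spatial modular networks.

The model couples dense Erdős–Rényi wiring inside communities ("cities",
mean intra-degree ``K``) with sparse links between lattice-adjacent
communities (``Q`` inter-links per community, split uniformly over its
four grid neighbours).  Discrete-time SIR dynamics with per-contact
infection probability ``beta`` and one-step recovery maps exactly onto
bond percolation, which yields two epidemic thresholds:

* a local one, ``beta_c_er = 1/K``, above which an outbreak fills a
  single city (the ER giant-component condition), and
* a global one, ``beta_c_2d``, above which infected cities percolate
  across the community lattice.  A city-to-city "bond" is open when the
  local outbreak (relative size ``S``, the positive root of
  ``S = 1 - exp(-K*beta*S)``) transmits through at least one of the
  ``k ~ Binomial(Q, 1/4)`` links joining the two cities, so the
  no-spread probability is ``[1 - S*beta/4]**Q``.  Setting it equal to
  the square-lattice bond-percolation threshold ``p_c = 1/2`` gives

      beta_c_2d = 4*(1 - 2**(-1/Q)) / (1 - exp(-4*K*(1 - 2**(-1/Q)))).

The module also provides the local outbreak size at the global
threshold, its large-``Q`` limit ``4*K*ln(2)/Q``, and the inversions of
the threshold formula used by quarantine strategies (critical ``K`` for
fixed ``Q`` and vice versa).

The derivation assumes ``k_inter`` is small enough that finite
non-infected clusters inside a supercritical city rarely carry more
than one inter-link (``s * k_inter << 1``); at the parameter values used
throughout the package this holds comfortably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import bisect

from .exceptions import ConsistencyError, InfeasibleError, ParameterError

__all__ = [
    "LatticeSpec",
    "SQUARE",
    "ThresholdResult",
    "er_outbreak_size",
    "inter_link_count_pmf",
    "no_spread_prob",
    "critical_beta_2d",
    "outbreak_size_at_threshold",
    "outbreak_size_limit",
    "critical_K",
    "critical_Q",
    "critical_beta_er",
    "threshold_summary",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the community lattice.

    ``p_c`` is the bond-percolation threshold of that lattice and
    ``neighbor_count`` the number of communities adjacent to each
    community.  The default (and the only case exercised by the
    simulator) is the square lattice with ``p_c = 1/2`` and 4
    neighbours; other geometries can be supplied by the caller, with
    ``p_c`` user-provided rather than hardcoded.
    """

    name: str = "square"
    p_c: float = 0.5
    neighbor_count: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.p_c < 1.0):
            raise ParameterError(f"bond threshold p_c must lie in (0,1), got {self.p_c}")
        if self.neighbor_count < 1:
            raise ParameterError("neighbor_count must be a positive integer")


SQUARE = LatticeSpec()


@dataclass(frozen=True)
class ThresholdResult:
    """The analytic threshold quantities for one (K, Q) point."""

    K: float
    Q: float
    beta_c_er: float
    beta_c_2d: float
    S_at_threshold: float
    S_limit: float

    def as_dict(self) -> dict:
        return {
            "K": self.K,
            "Q": self.Q,
            "beta_c_er": self.beta_c_er,
            "beta_c_2d": self.beta_c_2d,
            "S_at_threshold": self.S_at_threshold,
            "S_limit": self.S_limit,
        }


def er_outbreak_size(K: float, beta: float, tol: float = 1e-10) -> float:
    """Relative size S of the epidemic (giant) component of an ER city.

    Solves the self-consistency relation ``S = 1 - exp(-K*beta*S)`` and
    returns its largest root in [0, 1]: 0 when ``K*beta <= 1`` (the
    trivial root is the only one), otherwise the unique positive root,
    located by bisection to absolute tolerance ``tol``.
    """
    if K < 0:
        raise ParameterError("K must be non-negative")
    if not (0.0 <= beta <= 1.0):
        raise ParameterError("beta must lie in [0, 1]")
    if tol <= 0:
        raise ParameterError("tol must be positive")
    m = K * beta
    if m <= 1.0:
        return 0.0

    def f(s: float) -> float:
        return s - 1.0 + math.exp(-m * s)

    lo = tol
    if f(lo) >= 0.0:  # root indistinguishable from 0 at this tolerance
        return 0.0
    return float(bisect(f, lo, 1.0, xtol=tol))


def inter_link_count_pmf(Q: int, k: int) -> float:
    """P(k links join a community to one given neighbour | Q links total).

    Each of the community's ``Q`` inter-links attaches to one of its 4
    lattice neighbours uniformly, so the count toward a specific
    neighbour is Binomial(Q, 1/4):
    ``P_k = C(Q, k) * (1/4)**k * (3/4)**(Q-k)``.
    """
    if not isinstance(Q, (int,)) or isinstance(Q, bool):
        raise ParameterError("Q must be an integer for the pmf; use no_spread_prob for real Q")
    if Q < 0:
        raise ParameterError("Q must be non-negative")
    if not isinstance(k, (int,)) or isinstance(k, bool):
        raise ParameterError("k must be an integer")
    if k < 0 or k > Q:
        raise ParameterError(f"k must satisfy 0 <= k <= Q, got k={k}, Q={Q}")
    return math.comb(Q, k) * 0.25**k * 0.75 ** (Q - k)


def no_spread_prob(Q: float, S: float, beta: float, lattice: LatticeSpec = SQUARE) -> float:
    """Probability that a city's local outbreak spreads to none of the
    links toward one given neighbouring city.

    Summing the binomial pmf against per-link transmission probability
    ``S*beta`` collapses to the closed form ``(1 - S*beta/z)**Q`` with
    ``z`` the neighbour count (4 on the square lattice); the closed form
    is analytic in ``Q`` and therefore accepts real ``Q``.
    """
    if Q < 0:
        raise ParameterError("Q must be non-negative")
    if not (0.0 <= S <= 1.0) or not (0.0 <= beta <= 1.0):
        raise ParameterError("S and beta must lie in [0, 1]")
    return (1.0 - S * beta / lattice.neighbor_count) ** Q


def _a(Q: float, lattice: LatticeSpec) -> float:
    """Per-link transmission level S*beta/z required at criticality."""
    return 1.0 - lattice.p_c ** (1.0 / Q)


def critical_beta_2d(K: float, Q: float, lattice: LatticeSpec = SQUARE) -> float:
    """Global (lattice) epidemic threshold beta_c_2d.

    With ``a = 1 - p_c**(1/Q)`` and ``z`` neighbours,
    ``beta_c_2d = z*a / (1 - exp(-z*K*a))``.  For the square lattice at
    K=4, Q=10 this evaluates to 0.40740.  Note the value may exceed 1
    for small Q: the country then admits no global epidemic at any
    infection probability.
    """
    if K <= 0 or Q <= 0:
        raise ParameterError("K and Q must be positive")
    a = _a(Q, lattice)
    z = lattice.neighbor_count
    beta = z * a / (-math.expm1(-z * K * a))
    if beta < 1.0 / K - 1e-12:
        raise ConsistencyError(
            f"beta_c_2d={beta} fell below beta_c_er={1.0 / K}; "
            "the global threshold cannot precede the local one"
        )
    return beta


def outbreak_size_at_threshold(K: float, Q: float, lattice: LatticeSpec = SQUARE) -> float:
    """Local outbreak size S at the global threshold.

    ``S(beta_c_2d) = 1 - exp(-z*K*(1 - p_c**(1/Q)))``; the transition is
    discontinuous in this sense — cities are internally supercritical
    already at the lattice threshold, so S is finite there.
    """
    if K <= 0 or Q <= 0:
        raise ParameterError("K and Q must be positive")
    return -math.expm1(-lattice.neighbor_count * K * _a(Q, lattice))


def outbreak_size_limit(K: float, Q: float, lattice: LatticeSpec = SQUARE) -> float:
    """Large-Q asymptote of the outbreak size at threshold.

    Expanding ``1 - p_c**(1/Q)`` for large Q gives
    ``S(beta_c_2d) ~ z*K*ln(1/p_c)/Q`` (= ``4*K*ln(2)/Q`` on the square
    lattice).  Outside the asymptotic regime the formula can exceed 1
    and is then meaningless as a fraction; callers compare it to
    :func:`outbreak_size_at_threshold` to judge validity.
    """
    if K <= 0 or Q <= 0:
        raise ParameterError("K and Q must be positive")
    return lattice.neighbor_count * K * math.log(1.0 / lattice.p_c) / Q


def critical_K(beta: float, Q: float, lattice: LatticeSpec = SQUARE) -> float:
    """Critical intra-degree K_c below which an epidemic at infection
    probability ``beta`` cannot percolate across the lattice.

    Inverts the threshold formula at fixed Q:
    ``K_c = -log(1 - z*a/beta) / (z*a)`` with ``a = 1 - p_c**(1/Q)``.
    Infeasible when ``z*a/beta >= 1``: no intra-degree, however small,
    keeps the lattice threshold below ``beta`` — intra-city quarantine
    alone cannot succeed at this Q.
    """
    if not (0.0 < beta <= 1.0):
        raise ParameterError("beta must lie in (0, 1]")
    if Q <= 0:
        raise ParameterError("Q must be positive")
    za = lattice.neighbor_count * _a(Q, lattice)
    x = za / beta
    if x >= 1.0:
        raise InfeasibleError(
            f"z*a/beta = {x:.6g} >= 1 at Q={Q}: no K yields beta_c_2d = {beta}; "
            "intra-community quarantine alone cannot stop this epidemic"
        )
    return -math.log1p(-x) / za


def critical_Q(beta: float, K: float, lattice: LatticeSpec = SQUARE, tol: float = 1e-10) -> float:
    """Critical per-community inter-degree Q_c solving beta_c_2d(K, Q_c) = beta.

    beta_c_2d is monotone decreasing in Q (from ~z/(1-exp(-z*K)) as
    Q -> 0 down to 1/K as Q -> inf), so the root is bracketed and found
    by bisection.  Infeasible when ``beta <= 1/K``: the threshold sits
    above ``beta`` for every Q already, so no reduction is needed (nor
    does a finite Q_c exist).
    """
    if K <= 0:
        raise ParameterError("K must be positive")
    if not (0.0 < beta <= 1.0):
        raise ParameterError("beta must lie in (0, 1]")
    if beta <= 1.0 / K:
        raise InfeasibleError(
            f"beta={beta} <= 1/K={1.0 / K:.6g}: beta_c_2d(K, Q) > beta for every Q, "
            "so no finite critical Q exists"
        )

    def f(Q: float) -> float:
        return critical_beta_2d(K, Q, lattice) - beta

    lo = 1e-9
    if f(lo) <= 0.0:  # beta above the small-Q ceiling — cannot happen for beta <= 1
        raise InfeasibleError(f"beta={beta} exceeds the Q->0 threshold ceiling")
    hi = 1.0
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > 2**60:
            raise ConsistencyError("failed to bracket Q_c")
    return float(bisect(f, lo, hi, xtol=tol))


def critical_beta_er(K: float) -> float:
    """Local (within-city) epidemic threshold, beta_c_er = 1/K."""
    if K <= 0:
        raise ParameterError("K must be positive")
    return 1.0 / K


def threshold_summary(K: float, Q: float, lattice: LatticeSpec = SQUARE) -> ThresholdResult:
    """Bundle all closed-form threshold quantities for one (K, Q)."""
    return ThresholdResult(
        K=K,
        Q=Q,
        beta_c_er=critical_beta_er(K),
        beta_c_2d=critical_beta_2d(K, Q, lattice),
        S_at_threshold=outbreak_size_at_threshold(K, Q, lattice),
        S_limit=outbreak_size_limit(K, Q, lattice),
    )
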