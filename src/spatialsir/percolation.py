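"""Bond percolation on the periodic square lattice, plus the exhaustive
SIR <-> percolation equivalence oracle.

The square-lattice bond threshold ``p_c = 1/2`` anchors the analytic
theory; :func:`estimate_pc_square` re-derives it by Monte Carlo as an
end-to-end check.  Cluster wrapping around the torus is detected with a
union-find that tracks each node's displacement to its root: an open
bond closing a cycle whose accumulated displacement disagrees with the
bond's geometric offset (by a multiple of the lattice size) certifies a
cluster winding the torus along that axis.  The wrapping criterion
matches the model's periodic boundaries and is sharper near ``p_c``
than open-boundary spanning.

:func:`sir_reach_distribution_exhaustive` enumerates all ``2**E``
open/closed bond configurations of a small graph and accumulates the
exact distribution of the origin's reachable set — the independent
oracle against which the stochastic SIR simulator is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import child_seed
from .exceptions import ParameterError

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "PercolationTrial",
    "PcEstimate",
    "bond_percolation_trial",
    "estimate_pc_square",
    "sir_reach_distribution_exhaustive",
]


@dataclass(frozen=True)
class PercolationTrial:
    size: int
    p: float
    seed: int
    wrap_x: bool
    wrap_y: bool
    largest_fraction: float

    @property
    def wraps(self) -> bool:
        """Wrapping along either axis."""
        return self.wrap_x or self.wrap_y


@dataclass(frozen=True)
class PcEstimate:
    p_c: float
    stderr: float
    replicates: int
    size: int
    probes: tuple  # ((p, wrap frequency), ...) visited by the bisection


@njit(cache=False)
def _find(parent, dx, dy, i):
    """Root of i and i's displacement to it, with path compression."""
    root = i
    rx = 0
    ry = 0
    while parent[root] != root:
        rx += dx[root]
        ry += dy[root]
        root = parent[root]
    # second pass: point the whole path at the root
    node = i
    cx = 0
    cy = 0
    while parent[node] != node:
        nxt = parent[node]
        ox, oy = dx[node], dy[node]
        parent[node] = root
        dx[node] = rx - cx
        dy[node] = ry - cy
        cx += ox
        cy += oy
        node = nxt
    return root, rx, ry


@njit(cache=False)
def _bond_trial(size, open_right, open_down):
    """Union-find sweep over the open bonds of one configuration.

    ``open_right[i]`` opens the bond from node i to its +x neighbour,
    ``open_down[i]`` to its +y neighbour (periodic).  Returns
    (wrap_x, wrap_y, largest cluster fraction).
    """
    n = size * size
    parent = np.arange(n)
    dx = np.zeros(n, dtype=np.int64)
    dy = np.zeros(n, dtype=np.int64)
    csize = np.ones(n, dtype=np.int64)
    wrap_x = False
    wrap_y = False
    largest = 1
    for node in range(n):
        x = node % size
        y = node // size
        for axis in range(2):
            if axis == 0:
                if not open_right[node]:
                    continue
                nb = y * size + (x + 1) % size
                ex, ey = 1, 0
            else:
                if not open_down[node]:
                    continue
                nb = ((y + 1) % size) * size + x
                ex, ey = 0, 1
            ra, ax_, ay_ = _find(parent, dx, dy, node)
            rb, bx_, by_ = _find(parent, dx, dy, nb)
            if ra == rb:
                # cycle: positions must satisfy pos(nb) = pos(node)+e
                if bx_ - ax_ != ex:
                    wrap_x = True
                if by_ - ay_ != ey:
                    wrap_y = True
            else:
                # attach smaller tree; displacement of rb's root chosen so
                # that pos(nb) = pos(node) + e stays consistent
                if csize[ra] < csize[rb]:
                    parent[ra] = rb
                    dx[ra] = bx_ - ax_ - ex
                    dy[ra] = by_ - ay_ - ey
                    csize[rb] += csize[ra]
                    if csize[rb] > largest:
                        largest = csize[rb]
                else:
                    parent[rb] = ra
                    dx[rb] = ax_ - bx_ + ex
                    dy[rb] = ay_ - by_ + ey
                    csize[ra] += csize[rb]
                    if csize[ra] > largest:
                        largest = csize[ra]
    return wrap_x, wrap_y, largest / n


def bond_percolation_trial(size: int, p: float, seed: int) -> PercolationTrial:
    """One bond-percolation configuration on the size x size torus.

    Each of the 2*size**2 bonds opens independently with probability
    ``p``.  Bonds are realized as uniforms compared against ``p``, so
    for a fixed seed the open set is monotone in ``p`` (useful for
    coupling tests).  Deterministic given (size, p, seed).
    """
    if size < 2:
        raise ParameterError("size must be >= 2")
    if not (0.0 <= p <= 1.0):
        raise ParameterError("p must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF))
    u = rng.random(2 * size * size)
    n = size * size
    open_right = u[:n] < p
    open_down = u[n:] < p
    wrap_x, wrap_y, largest = _bond_trial(size, open_right, open_down)
    return PercolationTrial(
        size=size,
        p=float(p),
        seed=int(seed),
        wrap_x=bool(wrap_x),
        wrap_y=bool(wrap_y),
        largest_fraction=float(largest),
    )


def estimate_pc_square(
    size: int = 128,
    replicates: int = 200,
    seed: int = 0,
    n_iter: int = 10,
    p_lo: float = 0.25,
    p_hi: float = 0.75,
) -> PcEstimate:
    """Monte-Carlo estimate of the square-lattice bond threshold.

    Bisects on ``p`` the frequency of clusters wrapping the torus along
    a fixed axis against 1/2 (the frequency is monotone in ``p``); at
    criticality the single-axis wrapping probability is close to 1/2,
    so the crossing point estimates ``p_c`` with negligible bias at
    these sizes.  The standard error combines the binomial noise of the
    final probe (scaled by the empirical slope of the wrapping curve)
    with the bisection resolution.
    """
    if size < 32:
        raise ParameterError("size must be >= 32 for a meaningful estimate")
    if replicates < 50:
        raise ParameterError("need at least 50 replicates per probe")
    lo, hi = float(p_lo), float(p_hi)
    probes = []
    for it in range(n_iter):
        mid = 0.5 * (lo + hi)
        wraps = 0
        for r in range(replicates):
            trial = bond_percolation_trial(
                size, mid, child_seed(seed, "pc-bisect", it * replicates + r)
            )
            wraps += trial.wrap_x
        freq = wraps / replicates
        probes.append((mid, freq))
        if freq > 0.5:
            hi = mid
        else:
            lo = mid
    estimate = 0.5 * (lo + hi)
    ps = np.array([p for p, _ in probes])
    fs = np.array([f for _, f in probes])
    if np.ptp(ps) > 0 and np.ptp(fs) > 0:
        slope = abs(np.polyfit(ps, fs, 1)[0])
    else:
        slope = float("inf")
    binom_se = np.sqrt(0.25 / replicates) / max(slope, 1e-9)
    stderr = float(np.hypot(binom_se, (hi - lo) / 2.0))
    return PcEstimate(
        p_c=float(estimate),
        stderr=stderr,
        replicates=replicates,
        size=size,
        probes=tuple(probes),
    )


def sir_reach_distribution_exhaustive(
    edges: Sequence[tuple[int, int]], origin: int, beta: float, max_edges: int = 12
) -> dict[frozenset, float]:
    """Exact distribution of the final recovered set of an SIR epidemic
    started at ``origin``, by exhaustive bond enumeration.

    Every subset of open edges has probability
    ``beta**n_open * (1-beta)**n_closed``; the recovered set of the SIR
    process equals the origin's reachable set through open edges, so
    accumulating reachable sets over all ``2**E`` configurations gives
    the exact law.  Restricted to small graphs (``E <= max_edges``).
    """
    edges = [tuple(e) for e in edges]
    E = len(edges)
    if E > max_edges:
        raise ParameterError(f"{E} edges exceed the enumeration limit of {max_edges}")
    if not (0.0 <= beta <= 1.0):
        raise ParameterError("beta must lie in [0, 1]")
    nodes = {origin}
    for u, v in edges:
        if u == v:
            raise ParameterError("self-loops are not allowed")
        nodes.add(u)
        nodes.add(v)
    dist: dict[frozenset, float] = {}
    for mask in range(1 << E):
        n_open = bin(mask).count("1")
        w = beta**n_open * (1.0 - beta) ** (E - n_open)
        if w == 0.0:
            continue
        adj: dict[int, list[int]] = {u: [] for u in nodes}
        for b in range(E):
            if mask >> b & 1:
                u, v = edges[b]
                adj[u].append(v)
                adj[v].append(u)
        reached = {origin}
        stack = [origin]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in reached:
                    reached.add(v)
                    stack.append(v)
        key = frozenset(reached)
        dist[key] = dist.get(key, 0.0) + w
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-12:
        raise ParameterError(f"probabilities sum to {total}, not 1")
    return dist
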