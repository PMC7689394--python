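"""Discrete-time SIR dynamics with scheduled interventions.

Synchronous update: at each step every currently-infectious node
attempts each susceptible neighbour once, independently, with the
current infection probability ``beta``; newly infected nodes become
infectious at the next step; infectious nodes recover (permanently)
after exactly one infectious step.  This is the standard discrete-time
SIR that maps exactly onto bond percolation with bond probability
``beta`` — the final recovered set is distributed as the origin's
reachable set when each edge is open independently with probability
``beta``.

Interventions model control strategies:

* ``social`` — reduce the infection probability (beta -> beta').
* ``quarantine_intra`` — remove a uniform random subset of within-city
  edges so the mean intra-degree drops K -> K'.
* ``quarantine_inter`` — likewise for between-city edges
  (k_inter -> k_inter', i.e. Q -> Q' at fixed zeta).

A quarantine with a finite window ``t_q`` restores the removed edges
bit-exactly at step ``t_x + t_q``.  Network generation, epidemic
dynamics and quarantine edge selection draw from independently seeded
streams, so scheduling an intervention does not perturb the infection
trajectory before ``t_x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import ParameterError, SchedulingError
from .network import INTER, INTRA, SpatialModularNetwork, build_csr

__all__ = [
    "EpidemicParams",
    "InterventionSpec",
    "EpidemicRun",
    "run_sir",
    "periodic_distance",
    "apply_quarantine",
    "write_recovery_events",
]

SUSCEPTIBLE, INFECTED, RECOVERED = 0, 1, 2

STRATEGIES = ("social", "quarantine_intra", "quarantine_inter")


@dataclass(frozen=True)
class EpidemicParams:
    """Epidemic dynamics parameters.

    ``origin`` selects the index case: ``"random_community"`` (a uniform
    node in a uniform community), ``"central_community"`` (a uniform
    node in the community at the centre of the grid — statistically
    immaterial under periodic boundaries but convenient for
    reproducible spatial-propagation experiments), or an explicit node
    id.
    """

    beta: float
    origin: Union[str, int] = "random_community"
    max_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ParameterError("beta must lie in [0, 1]")
        if self.max_steps < 1:
            raise ParameterError("max_steps must be >= 1")
        if isinstance(self.origin, str) and self.origin not in (
            "random_community",
            "central_community",
        ):
            raise ParameterError(f"unknown origin rule {self.origin!r}")


@dataclass(frozen=True)
class InterventionSpec:
    """One scheduled control action.

    ``new_value`` is beta' for ``social``, K' for ``quarantine_intra``
    and k_inter' for ``quarantine_inter``.  A finite ``t_q`` makes a
    quarantine temporal: the removed edges return at ``t_x + t_q``.
    """

    strategy: str
    t_x: int
    new_value: float
    t_q: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ParameterError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if self.t_x < 0:
            raise ParameterError("t_x must be non-negative")
        if self.t_q is not None and self.t_q < 1:
            raise ParameterError("t_q must be a positive integer (or None for permanent)")
        if self.new_value < 0:
            raise ParameterError("new_value must be non-negative")
        if self.strategy == "social" and self.t_q is not None:
            raise ParameterError("temporal windows are defined for quarantines only")


@dataclass
class EpidemicRun:
    """One SIR realization.

    ``s/i/r_counts[t]`` are the compartment sizes at the *start* of step
    ``t`` (so ``i_counts[0] == 1``); a final row records the terminal
    state.  ``rmax_series[t]`` is the running maximum distance from the
    origin over all recoveries up to and including step ``t``.
    """

    origin: int
    s_counts: np.ndarray
    i_counts: np.ndarray
    r_counts: np.ndarray
    rmax_series: np.ndarray
    final_r: float
    final_extent: float
    extent_at_intervention: Optional[float]
    exhausted: bool
    duration: int  # number of steps with at least one infectious node
    beta_series: Optional[np.ndarray] = None
    recovery_steps: Optional[np.ndarray] = None
    recovery_nodes: Optional[np.ndarray] = None
    recovery_dists: Optional[np.ndarray] = None


def write_recovery_events(run: "EpidemicRun", path) -> None:
    """Stream a run's recovery events as TSV (step, node, distance).

    Requires the run to have been produced with ``record_events=True``.
    """
    if run.recovery_steps is None:
        raise ParameterError("run was simulated without record_events=True")
    with open(path, "w") as fh:
        fh.write("step\tnode\tdistance\n")
        for s, n, d in zip(run.recovery_steps, run.recovery_nodes, run.recovery_dists):
            fh.write(f"{s}\t{n}\t{d:.17g}\n")


def periodic_distance(delta_x: np.ndarray, delta_y: np.ndarray, L: Optional[int]) -> np.ndarray:
    """Minimal-image Euclidean distance on the periodic L x L lattice.

    Per axis the displacement is folded to ``min(|d|, L - |d|)``; with
    ``L=None`` (generic graphs) the plain Euclidean distance is used.
    """
    dx = np.abs(np.asarray(delta_x, dtype=np.float64))
    dy = np.abs(np.asarray(delta_y, dtype=np.float64))
    if L is not None:
        dx = np.minimum(dx, L - dx)
        dy = np.minimum(dy, L - dy)
    return np.sqrt(dx * dx + dy * dy)


def _origin_node(
    net: SpatialModularNetwork, rule: Union[str, int], rng: np.random.Generator
) -> int:
    if isinstance(rule, (int, np.integer)):
        if not (0 <= rule < net.n_nodes):
            raise ParameterError(f"origin node {rule} out of range")
        return int(rule)
    if net.params is None:
        return int(rng.integers(net.n_nodes))
    n = net.params.n_communities
    if rule == "random_community":
        comm = int(rng.integers(n))
    else:  # central_community
        g = net.params.grid_side
        comm = (g // 2) * g + g // 2
    members = np.flatnonzero(net.community == comm)
    return int(members[rng.integers(members.size)])


def _gather_neighbors(
    indptr: np.ndarray, indices: np.ndarray, nodes: np.ndarray
) -> np.ndarray:
    """Concatenate the CSR neighbour lists of ``nodes`` (with repeats)."""
    starts = indptr[nodes]
    counts = indptr[nodes + 1] - starts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=indices.dtype)
    cum = np.cumsum(counts)
    out_pos = np.arange(total, dtype=np.int64)
    offsets = np.repeat(starts - (cum - counts), counts)
    return indices[out_pos + offsets]


def _validate_schedule(interventions: Sequence[InterventionSpec]) -> None:
    times = [iv.t_x for iv in interventions]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise SchedulingError("interventions must be sorted by t_x")
    seen = {}
    for iv in interventions:
        if iv.strategy in seen:
            prev = seen[iv.strategy]
            if prev.t_q is None or prev.t_x + prev.t_q > iv.t_x:
                raise SchedulingError(
                    f"conflicting {iv.strategy} interventions overlap in time"
                )
        seen[iv.strategy] = iv


def _quarantine_removal(
    kind_mask: np.ndarray,
    active: np.ndarray,
    n_nodes: int,
    new_mean_degree: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of edges to remove so the expected mean degree of the
    given kind drops to ``new_mean_degree`` (each edge kept i.i.d.)."""
    candidates = np.flatnonzero(kind_mask & active)
    current = 2.0 * candidates.size / n_nodes
    if new_mean_degree > current + 1e-12:
        raise ParameterError(
            f"target mean degree {new_mean_degree} exceeds current {current:.6g}"
        )
    if current == 0.0:
        return np.empty(0, dtype=np.int64)
    keep_p = new_mean_degree / current
    drop = rng.random(candidates.size) >= keep_p
    return candidates[drop]


def apply_quarantine(
    net: SpatialModularNetwork, kind: str, new_mean_degree: float, seed: int
) -> tuple[SpatialModularNetwork, np.ndarray]:
    """Return (quarantined copy of the network, removed edge index set).

    Removes a uniform random subset of edges of the given kind
    (``"intra"`` or ``"inter"``) so the expected mean degree of that
    kind equals ``new_mean_degree``; the removed indices refer to the
    *original* edge arrays so a temporal quarantine can restore them
    exactly.
    """
    if kind not in ("intra", "inter"):
        raise ParameterError("kind must be 'intra' or 'inter'")
    code = INTRA if kind == "intra" else INTER
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF))
    active = np.ones(net.n_edges, dtype=bool)
    removed = _quarantine_removal(
        net.edge_kind == code, active, net.n_nodes, new_mean_degree, rng
    )
    keep = np.ones(net.n_edges, dtype=bool)
    keep[removed] = False
    new_net = net.replace_edges(net.edge_u[keep], net.edge_v[keep], net.edge_kind[keep])
    return new_net, removed


def run_sir(
    net: SpatialModularNetwork,
    epi: EpidemicParams,
    interventions: Sequence[InterventionSpec] = (),
    seed: Optional[int] = None,
    record_events: bool = False,
) -> EpidemicRun:
    """Simulate one epidemic realization.

    Deterministic given (net, epi, interventions, seed).  Interventions
    take effect at the start of step ``t_x``; temporal quarantines
    restore their removed edges at the start of step ``t_x + t_q``.
    Terminates when no infectious nodes remain, or flags ``exhausted``
    at ``max_steps``.
    """
    interventions = list(interventions)
    _validate_schedule(interventions)
    if seed is None:
        seed = epi.seed
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    origin_rng, dyn_rng, quar_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    N = net.n_nodes
    origin = _origin_node(net, epi.origin, origin_rng)

    dists = periodic_distance(
        net.coords[:, 0].astype(np.float64) - net.coords[origin, 0],
        net.coords[:, 1].astype(np.float64) - net.coords[origin, 1],
        net.L,
    )

    structural = any(iv.strategy != "social" for iv in interventions)
    if structural:
        active = np.ones(net.n_edges, dtype=bool)
        indptr, indices = build_csr(N, net.edge_u, net.edge_v)
    else:
        active = None
        indptr, indices = net.adjacency()

    pending = list(interventions)
    restores: list[tuple[int, np.ndarray]] = []  # (restore step, removed edge idx)

    beta = epi.beta
    status = np.zeros(N, dtype=np.uint8)
    status[origin] = INFECTED
    frontier = np.array([origin], dtype=np.int64)

    s_hist, i_hist, r_hist, rmax_hist, beta_hist = [], [], [], [], []
    ev_steps, ev_nodes, ev_dists = [], [], []
    rmax = 0.0
    extent_at_iv: Optional[float] = None
    n_s, n_i, n_r = N - 1, 1, 0
    t = 0
    exhausted = False

    while frontier.size:
        if t >= epi.max_steps:
            exhausted = True
            break
        rebuild = False
        for rt, ridx in [r for r in restores if r[0] == t]:
            active[ridx] = True
            rebuild = True
        restores = [r for r in restores if r[0] != t]
        while pending and pending[0].t_x == t:
            iv = pending.pop(0)
            if extent_at_iv is None:
                extent_at_iv = rmax
            if iv.strategy == "social":
                if iv.new_value > beta + 1e-12:
                    raise ParameterError("social strategy must not increase beta")
                beta = iv.new_value
            else:
                kind = INTRA if iv.strategy == "quarantine_intra" else INTER
                removed = _quarantine_removal(
                    net.edge_kind == kind, active, N, iv.new_value, quar_rng
                )
                active[removed] = False
                rebuild = True
                if iv.t_q is not None:
                    restores.append((t + iv.t_q, removed))
        if rebuild:
            keep = active
            indptr, indices = build_csr(N, net.edge_u[keep], net.edge_v[keep])

        s_hist.append(n_s)
        i_hist.append(n_i)
        r_hist.append(n_r)
        beta_hist.append(beta)

        targets = _gather_neighbors(indptr, indices, frontier)
        if targets.size:
            cand = targets[status[targets] == SUSCEPTIBLE]
            if cand.size and beta > 0.0:
                hit = cand[dyn_rng.random(cand.size) < beta]
                new_inf = np.unique(hit)
            else:
                new_inf = np.empty(0, dtype=np.int64)
        else:
            new_inf = np.empty(0, dtype=np.int64)

        # step-t infectious nodes recover at the end of step t
        status[frontier] = RECOVERED
        step_max = float(dists[frontier].max())
        if step_max > rmax:
            rmax = step_max
        rmax_hist.append(rmax)
        if record_events:
            ev_steps.append(np.full(frontier.size, t, dtype=np.int64))
            ev_nodes.append(frontier)
            ev_dists.append(dists[frontier])
        n_r += frontier.size
        n_i = new_inf.size
        n_s -= new_inf.size
        status[new_inf] = INFECTED
        frontier = new_inf
        t += 1

    # terminal state row
    s_hist.append(n_s)
    i_hist.append(n_i)
    r_hist.append(n_r)
    beta_hist.append(beta)
    rmax_hist.append(rmax)

    if pending and extent_at_iv is None and not exhausted:
        # scheduled interventions never fired (epidemic died first)
        extent_at_iv = rmax

    return EpidemicRun(
        origin=origin,
        s_counts=np.asarray(s_hist, dtype=np.int64),
        i_counts=np.asarray(i_hist, dtype=np.int64),
        r_counts=np.asarray(r_hist, dtype=np.int64),
        rmax_series=np.asarray(rmax_hist, dtype=np.float64),
        final_r=n_r / N,
        final_extent=rmax,
        extent_at_intervention=extent_at_iv,
        exhausted=exhausted,
        duration=t,
        beta_series=np.asarray(beta_hist, dtype=np.float64),
        recovery_steps=np.concatenate(ev_steps) if record_events and ev_steps else None,
        recovery_nodes=np.concatenate(ev_nodes) if record_events and ev_nodes else None,
        recovery_dists=np.concatenate(ev_dists) if record_events and ev_dists else None,
    )
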