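"""Aggregate simulation experiments.

Three families of experiments, mirroring how the model is interrogated:

* **beta sweeps** — the mean final recovered fraction R(beta) over a
  grid of infection probabilities; the two epidemic transitions show up
  as the two maxima of d log R / d beta.
* **propagation curves** — the mean maximal spatial extent of the
  epidemic <r_max>(t), which climbs the "circles" of cities around the
  origin at early times (timescales tau_0 > tau_1 > tau_2) and crosses
  over to critical spatial spreading <r_max> ~ t**(1/d_min) with
  d_min ≈ 1.13 in 2D.
* **intervention outcomes** — the extent at intervention time
  <r_max>_x versus the terminal extent <r_max>_f; a successful control
  freezes the epidemic's footprint (<r_max>_f ≈ <r_max>_x).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._rng import child_seed
from .exceptions import ParameterError
from .network import ModelParams, SpatialModularNetwork, build_network
from .sir import EpidemicParams, EpidemicRun, InterventionSpec, run_sir

__all__ = [
    "SweepResult",
    "ThresholdDetection",
    "PropagationCurve",
    "CircleTimescales",
    "InterventionOutcome",
    "beta_sweep",
    "log_derivative_thresholds",
    "propagation_curve",
    "circle_timescales",
    "default_fit_window",
    "fit_dmin",
    "fit_dmin_first_passage",
    "run_intervention_experiment",
    "intervention_outcome",
]


@dataclass
class SweepResult:
    """R(beta) over a grid, with per-replicate detail."""

    params: ModelParams
    betas: np.ndarray
    final_r: np.ndarray  # (replicates, n_beta)
    seed: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.betas) <= 0):
            raise ParameterError("beta grid must be strictly increasing")

    @property
    def mean_r(self) -> np.ndarray:
        return self.final_r.mean(axis=0)

    @property
    def replicates(self) -> int:
        return self.final_r.shape[0]


@dataclass(frozen=True)
class ThresholdDetection:
    """Locations of the (up to two) maxima of d log R / d beta."""

    beta_1: float
    beta_2: Optional[float]
    collided: bool  # only one maximum found (expected for zeta -> L)
    derivative: np.ndarray
    betas: np.ndarray


@dataclass
class PropagationCurve:
    """<r_max>(t) averaged over realizations.

    ``rmax_mean`` averages over all runs, with extinct runs contributing
    their final extent thereafter (monotone non-decreasing).
    ``rmax_mean_active`` conditions on runs still propagating at t — the
    cleaner observable for the critical-exponent fit, since runs that
    died early would otherwise flatten the late-time growth; it is NaN
    once no runs remain active.
    """

    t: np.ndarray
    rmax_mean: np.ndarray
    rmax_mean_active: np.ndarray
    n_active: np.ndarray
    zeta: int
    L: int
    beta: float
    replicates: int
    degenerate: bool  # every run died inside the origin city
    rmax_runs: Optional[np.ndarray] = None  # (replicates, T) padded per-run series
    durations: Optional[np.ndarray] = None


@dataclass(frozen=True)
class CircleTimescales:
    tau0: Optional[float]
    tau1: Optional[float]
    tau2: Optional[float]
    tau_x: Optional[float]


@dataclass(frozen=True)
class InterventionOutcome:
    extent_at_intervention: float  # <r_max>_x
    final_extent: float  # <r_max>_f
    stopped: bool
    band: float


def beta_sweep(
    params: ModelParams,
    betas: Sequence[float],
    replicates: int,
    seed: int,
    max_steps: int = 100_000,
    origin: str = "random_community",
    reuse_networks: bool = True,
) -> SweepResult:
    """Mean final recovered fraction over a beta grid.

    One network per replicate, shared across the grid by default (so the
    beta-dependence is not confounded with structural noise); with
    ``reuse_networks=False`` every (beta, replicate) cell gets a fresh
    network.
    """
    betas = np.asarray(sorted(set(float(b) for b in betas)), dtype=np.float64)
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    if betas.min() < 0 or betas.max() > 1:
        raise ParameterError("betas must lie within [0, 1]")
    out = np.empty((replicates, betas.size), dtype=np.float64)
    for rep in range(replicates):
        net = None
        if reuse_networks:
            net = build_network(params, child_seed(seed, "sweep-net", rep))
        for j, beta in enumerate(betas):
            if not reuse_networks:
                net = build_network(
                    params, child_seed(seed, "sweep-net", rep * betas.size + j)
                )
            epi = EpidemicParams(beta=float(beta), origin=origin, max_steps=max_steps)
            run = run_sir(net, epi, seed=child_seed(seed, "sweep-sir", rep * betas.size + j))
            out[rep, j] = run.final_r
    return SweepResult(params=params, betas=betas, final_r=out, seed=seed)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: x.size]


def log_derivative_thresholds(
    sweep: SweepResult, smoothing_window: int = 3, min_separation: int = 2
) -> ThresholdDetection:
    """Detect the two epidemic thresholds as the two dominant,
    well-separated local maxima of d log R / d beta.

    log R is floored at 1/N (a dead epidemic recovers exactly the index
    case), smoothed with a short moving average, and differentiated
    with central finite differences on the grid.  When only one maximum
    exists — the two transitions coalesce as the communities grow
    toward the system size — the single location is returned with
    ``collided=True``.
    """
    if sweep.betas.size < 7:
        raise ParameterError("need at least 7 grid points to locate two maxima")
    floor = 1.0 / sweep.params.n_nodes
    log_r = np.log(np.maximum(sweep.mean_r, floor))
    smooth = _moving_average(log_r, smoothing_window)
    deriv = np.gradient(smooth, sweep.betas)

    peaks = [
        i
        for i in range(1, deriv.size - 1)
        if deriv[i] >= deriv[i - 1] and deriv[i] >= deriv[i + 1]
    ]
    if not peaks:
        raise ParameterError("derivative has no interior local maximum")
    # discard flat-floor artifacts: a genuine transition peak rises well
    # above zero, spurious plateau "maxima" sit at ~0 height
    top = max(deriv[i] for i in peaks)
    peaks = [i for i in peaks if deriv[i] > 0.05 * top]
    peaks.sort(key=lambda i: deriv[i], reverse=True)
    chosen: list[int] = []
    for i in peaks:
        if all(abs(i - j) >= min_separation for j in chosen):
            chosen.append(i)
        if len(chosen) == 2:
            break
    if not chosen:
        raise ParameterError("derivative has no interior local maximum")
    chosen.sort()
    if len(chosen) == 1:
        return ThresholdDetection(
            beta_1=float(sweep.betas[chosen[0]]),
            beta_2=None,
            collided=True,
            derivative=deriv,
            betas=sweep.betas,
        )
    return ThresholdDetection(
        beta_1=float(sweep.betas[chosen[0]]),
        beta_2=float(sweep.betas[chosen[1]]),
        collided=False,
        derivative=deriv,
        betas=sweep.betas,
    )


def propagation_curve(
    params: ModelParams,
    beta: float,
    replicates: int,
    seed: int,
    max_steps: int,
    origin: str = "central_community",
    interventions: Sequence[InterventionSpec] = (),
) -> PropagationCurve:
    """Average the running-max recovery distance over realizations.

    Each replicate gets a fresh network and an origin in the central
    community.  Runs are padded with their final extent after
    extinction for the all-runs average; the survivor-conditioned
    average tracks only runs with infectious nodes left at t.
    """
    if beta <= 1.0 / max(params.k_intra, 1e-12):
        raise ParameterError(
            "beta must exceed the local threshold 1/K for spatial spread to exist"
        )
    series = []
    durations = []
    for rep in range(replicates):
        net = build_network(params, child_seed(seed, "prop-net", rep))
        epi = EpidemicParams(beta=beta, origin=origin, max_steps=max_steps)
        run = run_sir(
            net, epi, interventions=interventions, seed=child_seed(seed, "prop-sir", rep)
        )
        series.append(run.rmax_series)
        durations.append(run.duration)
    T = max_steps + 1
    padded = np.full((replicates, T), np.nan)
    active = np.zeros((replicates, T), dtype=bool)
    for r, s in enumerate(series):
        padded[r, : s.size] = s
        padded[r, s.size:] = s[-1]
        active[r, : durations[r]] = True
    t = np.arange(T)
    n_active = active.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_all = padded.mean(axis=0)
        sums = np.where(active, padded, 0.0).sum(axis=0)
        mean_active = np.where(n_active > 0, sums / np.maximum(n_active, 1), np.nan)
    degenerate = bool(np.nanmax(mean_all) < params.zeta / 2.0)
    return PropagationCurve(
        t=t,
        rmax_mean=mean_all,
        rmax_mean_active=mean_active,
        n_active=n_active,
        zeta=params.zeta,
        L=params.L,
        beta=beta,
        replicates=replicates,
        degenerate=degenerate,
        rmax_runs=padded,
        durations=np.asarray(durations, dtype=np.int64),
    )


def circle_timescales(
    curve: PropagationCurve, zeta: Optional[int] = None, min_plateau: int = 3
) -> CircleTimescales:
    """Durations the epidemic spends confined to successive circles of
    cities around the origin.

    The circle index is ``c(t) = floor(<r_max>(t)/zeta + 1/2)`` (circle
    boundaries at half-integer multiples of zeta, bands centred on the
    city rings).  ``tau_i`` is the residence time at index i before
    index i+1 is first reached, reported only when the plateau is
    identifiable (at least ``min_plateau`` steps — ballistic curves
    yield no identifiable circles).  ``tau_x`` is the mean duration of
    the crossings between identified consecutive circles, measured as
    the time <r_max> takes to climb the middle half-band around each
    circle boundary ((i+1/4)zeta to (i+3/4)zeta).
    """
    if curve.degenerate:
        return CircleTimescales(None, None, None, None)
    z = zeta if zeta is not None else curve.zeta
    r = curve.rmax_mean
    c = np.floor(r / z + 0.5).astype(np.int64)
    taus: list[Optional[float]] = []
    for i in range(3):
        at_i = np.flatnonzero(c == i)
        above = np.flatnonzero(c > i)
        if at_i.size >= min_plateau and above.size:
            taus.append(float(at_i[at_i < above[0]].size))
        else:
            taus.append(None)
    crossings = []
    for i in range(3):
        if taus[i] is None:
            continue
        lo_lvl, hi_lvl = (i + 0.25) * z, (i + 0.75) * z
        lo_idx = np.flatnonzero(r >= lo_lvl)
        hi_idx = np.flatnonzero(r >= hi_lvl)
        if lo_idx.size and hi_idx.size:
            crossings.append(float(hi_idx[0] - lo_idx[0]))
    tau_x = float(np.mean(crossings)) if crossings else None
    return CircleTimescales(tau0=taus[0], tau1=taus[1], tau2=taus[2], tau_x=tau_x)


def default_fit_window(curve: PropagationCurve, min_active: Optional[int] = None) -> tuple[int, int]:
    """Late-time window for the d_min fit: past the circle regime
    (<r_max> > 3*zeta), before torus saturation (<r_max> < L/2), and
    with enough surviving runs for the conditioned mean to be stable."""
    if min_active is None:
        min_active = max(3, curve.replicates // 10)
    r = curve.rmax_mean_active
    ok = (
        (r > 3 * curve.zeta)
        & (r < curve.L / 2.0)
        & (curve.n_active >= min_active)
        & (curve.t > 0)
    )
    idx = np.flatnonzero(ok & ~np.isnan(r))
    if idx.size == 0:
        raise ParameterError("no usable late-time window (epidemic never left the circle regime)")
    return int(curve.t[idx[0]]), int(curve.t[idx[-1]])


def fit_dmin(
    curve: PropagationCurve,
    window: Optional[tuple[float, float]] = None,
    use_active: bool = True,
    min_points: int = 5,
) -> float:
    """Chemical-distance exponent from the late-time growth of <r_max>.

    Least-squares slope s of log <r_max> versus log t over the window;
    returns 1/s (so a pure power law t**(1/1.13) gives 1.13).

    Note: on small community grids this direct curve fit carries a
    strong upward bias — averaging runs whose extent has saturated
    flattens the late growth.  :func:`fit_dmin_first_passage` is the
    preferred estimator on simulation output; this form is exact on an
    unsaturated power-law curve and is kept for analytic inputs and
    cross-checks.
    """
    if window is None:
        window = default_fit_window(curve)
    t_lo, t_hi = window
    if t_lo <= 0:
        raise ParameterError("window must start at t > 0 for the log fit")
    r = curve.rmax_mean_active if use_active else curve.rmax_mean
    mask = (curve.t >= t_lo) & (curve.t <= t_hi) & ~np.isnan(r) & (r > 0)
    if mask.sum() < min_points:
        raise ParameterError(
            f"window contains {int(mask.sum())} points; need at least {min_points}"
        )
    slope = np.polyfit(np.log(curve.t[mask]), np.log(r[mask]), 1)[0]
    if slope <= 0:
        raise ParameterError("non-increasing curve over the fit window")
    return float(1.0 / slope)


def fit_dmin_first_passage(
    curve: PropagationCurve,
    r_window: Optional[tuple[float, float]] = None,
    n_radii: int = 10,
    min_runs: int = 8,
) -> float:
    """Chemical-distance exponent from mean first-passage times.

    For each radius r in the window, the mean over runs (that ever
    reach r) of the first step at which r_max >= r estimates t(r); at
    criticality t(r) ~ r**d_min, so the least-squares slope of
    log t-bar versus log r is d_min directly.  This inverts the same
    r_max-t scaling law as :func:`fit_dmin` but sidesteps the
    saturation bias of averaging extents at fixed time: a run
    contributes to t(r) only while it is still advancing.

    The default window spans the late regime past the circle structure
    (r > 3*zeta) up to half the lattice (minimal-image distances are
    unambiguous below L/2).
    """
    if curve.rmax_runs is None:
        raise ParameterError("curve was built without per-run series")
    if r_window is None:
        r_window = (3.0 * curve.zeta, curve.L / 2.0)
    r_lo, r_hi = r_window
    if not (0 < r_lo < r_hi):
        raise ParameterError("need 0 < r_lo < r_hi")
    radii = np.linspace(r_lo, r_hi, n_radii)
    tbars = []
    for r in radii:
        reached = curve.rmax_runs[:, -1] >= r
        if reached.sum() < min_runs:
            tbars.append(np.nan)
            continue
        first = (curve.rmax_runs[reached] >= r).argmax(axis=1)
        tbars.append(float(first.mean()))
    tbars = np.asarray(tbars)
    ok = ~np.isnan(tbars) & (tbars > 0)
    if ok.sum() < 5:
        raise ParameterError(
            "fewer than 5 usable radii: too few runs spread far enough"
        )
    return float(np.polyfit(np.log(radii[ok]), np.log(tbars[ok]), 1)[0])


def run_intervention_experiment(
    params: ModelParams,
    beta: float,
    interventions: Sequence[InterventionSpec],
    replicates: int,
    seed: int,
    max_steps: int,
    origin: str = "central_community",
) -> list[EpidemicRun]:
    """Replicated SIR runs sharing one intervention schedule."""
    runs = []
    for rep in range(replicates):
        net = build_network(params, child_seed(seed, "iv-net", rep))
        epi = EpidemicParams(beta=beta, origin=origin, max_steps=max_steps)
        runs.append(
            run_sir(net, epi, interventions=interventions, seed=child_seed(seed, "iv-sir", rep))
        )
    return runs


def intervention_outcome(
    runs: Sequence[EpidemicRun], zeta: int, band: Optional[float] = None
) -> InterventionOutcome:
    """Mean extent at intervention vs terminal extent.

    ``stopped`` declares the intervention successful when the epidemic's
    footprint grew by no more than ``band`` (default 2*zeta) after the
    intervention fired.
    """
    if band is None:
        band = 2.0 * zeta
    ext_x = [r.extent_at_intervention for r in runs]
    if any(e is None for e in ext_x):
        raise ParameterError("every run must carry the intervention schedule")
    mean_x = float(np.mean(ext_x))
    mean_f = float(np.mean([r.final_extent for r in runs]))
    return InterventionOutcome(
        extent_at_intervention=mean_x,
        final_extent=mean_f,
        stopped=bool(mean_f - mean_x <= band),
        band=float(band),
    )
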