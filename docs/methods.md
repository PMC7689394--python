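# Methods

## Model

`spatialsir` simulates and analyses SIR epidemics on a *spatial modular
network*: N = L² nodes on a periodic square lattice, tiled by square
communities ("cities") of linear size ζ, so there are n = (L/ζ)² cities
of N_c = ζ² nodes each.  Infection channels inside a city are dense and
unstructured — each city is wired as an Erdős–Rényi graph G(N_c, p)
with p = K/(N_c − 1), mean intra-degree K.  Channels between cities are
sparse and spatial: inter-links join nodes in lattice-adjacent cities
only, with a mean total inter-degree of k_inter per node, i.e.
Q = k_inter·ζ² links per city, each attached uniformly to one of its 4
grid neighbours.  Periodic boundaries apply at both the node and the
community level (a torus), so all cities are statistically equivalent.

Because an inter-link contributes degree to both endpoints, the
generator draws Poisson(k_inter/2) link stubs per node (direction
uniform over 4, target node uniform in the neighbour city); drawn plus
received halves make the per-node inter-degree k_inter and the link
count between a fixed pair of adjacent cities Binomial-thinned with
mean Q/4 — the quantities the closed-form theory is stated in.  The
factor of two matters: drawing Poisson(k_inter) stubs per node doubles
the pair-link count, which shifts the measured global threshold from
0.407 to ≈0.33 at K=4, Q=10 and breaks every analytic identity below.
Duplicate edges are discarded (collision probability O(k_inter²) at the
parameter ranges of interest).  On the degenerate 1×1 community grid no
inter-links are generated at all, so the ζ = L limit is exactly one ER
graph.  Edges are stored canonically ((u < v), lexicographically
sorted); generation is bit-reproducible given (params, seed).

## Dynamics and the percolation mapping

The epidemic is discrete-time SIR with synchronous updates: a single
infected node starts in a chosen city; at each step every infectious
node attempts each susceptible neighbour once, independently, with
probability β; newly infected nodes become infectious the next step;
infectious nodes recover after exactly one step (recovery probability
1).  Under these rules the final recovered set is distributed exactly
as the origin's reachable set under bond percolation with bond
probability β.  The package exploits this twice: an exhaustive 2^E
enumeration over small graphs serves as the correctness oracle for the
simulator (4σ multinomial bands at 10⁵ Monte-Carlo replicates), and the
square-lattice bond threshold p_c = 1/2 anchors the analytic theory.

## Two epidemic thresholds

The structure produces two transitions:

* **Local**, β_c^ER = 1/K: above it an outbreak fills a finite fraction
  S of the origin city, where S solves S = 1 − exp(−KβS) (largest root,
  found by bisection; S = 0 iff Kβ ≤ 1).
* **Global**, β_c^2D: cities form a square lattice whose "bonds" open
  when a local outbreak transmits through at least one of the
  Binomial(Q, 1/4) links to a given neighbour; the no-spread
  probability is (1 − Sβ/4)^Q.  Setting it to p_c = 1/2 and eliminating
  S gives, with a = 1 − 2^(−1/Q),

      β_c^2D = 4a / (1 − exp(−4Ka)),

  equal to 0.40741 at K = 4, Q = 10.  The outbreak size at that
  threshold is S* = 1 − exp(−4Ka) (finite — cities are internally
  supercritical there), with large-Q asymptote 4K·ln2/Q.  Closed-form
  and root-found inversions give the critical intra-degree K_c(β, Q)
  and critical inter-budget Q_c(β, K) used by quarantine planning; both
  round-trip with the threshold formula to 10⁻⁶ over a wide (K, Q)
  grid.  Other community geometries enter through (p_c, neighbour
  count), user-supplied; the square lattice is the default and the only
  geometry the generator produces.

The derivation assumes k_inter is small enough that finite non-infected
clusters inside a supercritical city rarely carry an inter-link
(s·k_inter ≪ 1); all shipped parameter sets satisfy this comfortably.

## Threshold detection from sweeps

`beta_sweep` measures the mean final recovered fraction R(β) over a β
grid (one fresh network per replicate, shared across the grid so the β
dependence is not confounded with structural noise).
`log_derivative_thresholds` floors R at 1/N, smooths log R with a
3-point moving average, differentiates on the grid, and reports the two
dominant well-separated local maxima of d log R/dβ, which estimate the
two thresholds; peaks below 5 % of the top peak are treated as
flat-floor artifacts.  When only one maximum survives — as ζ → L, where
the transitions coalesce — the single location is returned with a flag.

At desk scale the first maximum sits slightly above 1/K because the ER
transition inside a ζ² city is finite-size-smeared by Δβ ≈ N_c^(−1/3)/K
(≈ 0.02 at ζ = 50); the acceptance experiment uses a 21-point grid over
[0.18, 0.50] (resolution 0.016, both analytic thresholds interior) and
300 replicates — subcritical R is a heavy-tailed mean and needs that
many realizations to stabilise its logarithm.

## Spatial propagation and d_min

`propagation_curve` starts epidemics in the central city and tracks
⟨r_max⟩(t), the mean over realizations of the maximal minimal-image
Euclidean distance from the origin among recovered nodes up to t.  Two
averages are reported: over all runs (extinct runs contribute their
final extent — monotone, used for intervention bookkeeping) and over
runs still active at t (used for growth analysis).  At early times the
curve climbs the discrete "circles" of cities around the origin;
`circle_timescales` reads the residence times τ₀ > τ₁ > τ₂ off the
staircase of the circle index c(t) = ⌊⟨r_max⟩/ζ + ½⌋ (boundaries at
half-integer multiples of ζ; plateaus shorter than 3 steps are treated
as unidentifiable, which is what a ballistic curve produces), and
reports the mean boundary-crossing duration τ_x as the time to climb
the middle half-band around each circle boundary.

At β = β_c^2D the late-time growth follows ⟨r_max⟩ ~ t^(1/d_min) with
the 2D chemical-distance exponent d_min ≈ 1.13.  Two estimators are
provided:

* `fit_dmin` — inverse least-squares slope of log⟨r_max⟩ vs log t over
  a window (default: past the circle regime, ⟨r_max⟩ > 3ζ, and below
  L/2 where minimal-image distances are unambiguous).  Exact on
  analytic power-law input; on simulated curves at desk scale it is
  biased high (≈ 1.4 at L = 400, ζ = 40) because averaging extents at
  fixed time mixes in runs whose clusters have stopped growing on the
  small community torus.
* `fit_dmin_first_passage` (preferred on simulation output) — for a
  grid of radii in the same window, the mean over runs of the first
  step at which r_max ≥ r estimates t(r) ~ r^d_min; the slope of
  log t̄ vs log r is d_min.  A run contributes only while it is still
  advancing, which removes the worst of the saturation bias; the
  residual finite-size excess on a 10×10-community torus remains
  sizeable — measured values across seeds and replicate counts
  (60–600) span ≈ 1.16–1.48 with a high-replicate centre near 1.27
  against the asymptotic 1.13 — and are insensitive to the upper
  window cutoff.  Precision critical exponents require larger L/ζ
  ratios than desk scale affords.

## Interventions

Three control strategies act at a scheduled step t_x: *social*
(β → β′), *intra-city quarantine* (K → K′: each within-city edge kept
independently with probability K′/K), and *inter-city quarantine*
(k_inter → k_inter′, i.e. Q → Q′ at fixed ζ).  A finite window t_q
makes a quarantine temporal: the removed edge set is restored
bit-exactly at t_x + t_q.  Network construction, epidemic dynamics and
quarantine edge selection use independently seeded streams, so adding
an intervention never perturbs the trajectory before t_x.  Outcomes are
summarised by the mean extent at intervention ⟨r_max⟩_x versus the
terminal extent ⟨r_max⟩_f; an intervention counts as having stopped the
spread when the footprint grew by at most 2ζ (configurable).  For
temporal-window experiments the package conditions on runs still active
at t_x — runs already extinct carry no information about the window.

Strategy *planning* happens in the (K, Q) parameter space: candidate
quarantine targets lie on the critical line β_c^2D(K, Q) = β(1 + ε)
(margin ε, default 10⁻³, keeps the target strictly below threshold),
restricted to K ≤ K₀, Q ≤ Q₀ since quarantines only remove channels.
`optimize_strategy` minimises a weight function over the discretized
line — Euclidean distance in raw (K, Q) units by default, a proxy for
minimal total link reduction; arbitrary user weights are accepted, as
any realistic cost (economic, social) is more complex.  Ties break
toward the smaller total relative reduction.  The result is labelled
local / global / mixed by which coordinates moved (relative tolerance
10⁻³, coarse enough to absorb line-grid resolution).

## Percolation machinery

`bond_percolation_trial` opens each of the 2·size² torus bonds with
probability p (uniforms thresholded, so open sets are nested in p for a
fixed seed) and runs a union-find that tracks each node's displacement
to its root; an open bond closing a cycle whose accumulated
displacement disagrees with the bond's geometric offset certifies a
cluster wrapping the torus along that axis.  The kernel is numba-jitted.
`estimate_pc_square` bisects on p the frequency of wrapping along a
fixed single axis against 1/2: at criticality that probability is
≈ 0.52 (vs ≈ 0.69 for either-axis wrapping), so the crossing point
estimates p_c with a bias well below the Monte-Carlo error at size 128;
the reported standard error combines binomial noise at the final probe
(scaled by the empirical slope of the wrapping curve) with the
bisection resolution.

## Problem sizes and reproducibility

Simulation experiments ship at desk scale: L = 400–500 with ζ = 40–50
(10×10 community grids, 1.6–2.5·10⁵ nodes) and 40–300 replicates per
measurement; the closed-form theory is exact at any size and covers the
full-scale regime.  What the scaled experiments demonstrate is the
existence and location of both transitions, the percolation mapping,
and the qualitative intervention phenomenology — not precision critical
exponents, which at 10 communities across carry finite-size corrections
of order +0.1 (documented above).

All randomness flows through a counter-based fan-out: every operation
derives its generator from (master seed, operation tag, replicate
index), so adding replicates or re-ordering experiments never shifts
existing streams, and every experiment is bit-reproducible from its
config file (the run manifest records a SHA-256 per output).  Numeric
outputs serialize at 17 significant digits.

## Known limitations

* All cities share one size ζ²; heterogeneous city sizes are out of
  scope.
* No long-range (small-world) links; only nearest-neighbour city
  coupling.
* Recovery probability is fixed at 1; slower recovery would lengthen
  the quarantine windows required.
* The generator produces square community tilings only; other
  geometries are supported analytically through (p_c, neighbour count).
* Critical-exponent measurements at desk scale carry the finite-size
  biases quantified above.
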