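# Methods

## Model structure and assumptions

The simulator couples three processes on a directed travel network of N
patches (recreational destinations plus their associated population centres):

1. **Forest dynamics.**  Susceptible trees S grow logistically to a shared
   carrying capacity K; infested trees I and infested firewood B transmit the
   pest within a patch at rate A, modulated by a sigmoid density dependence
   θ_k(I − I_a) so that transmission runs at half speed when I = I_a.
   Infested trees and firewood decay at the same rate γ (tree mortality is
   assumed to be entirely infestation-driven).
2. **Firewood transport.**  A fraction 1 − L_i of visitors transport firewood;
   infested wood leaves patch i at rate d, distributed over destinations by
   the trip-fraction matrix P and thinned by checkpoint interception
   (1 − C_e) on every route.  Every unit of wood that leaves a patch arrives
   as B somewhere else: with no quarantine active, total import equals total
   export identically, which the tests assert on random states.
3. **Social learning.**  L_i follows replicator dynamics with payoff
   difference U + s(2L_i − 1) + f I_i: net transport cost U, conformity
   pressure s, and aversion driven by visible local infestation f.  L = 0 and
   L = 1 are absorbing in exact arithmetic.

Quarantine replaces the transport terms with gated versions: routes touching
the quarantined set V are multiplied by an upside-down boxcar that is zero for
t ∈ [t0, t0 + Δt].  Both import into and export out of quarantined patches are
gated.  The model is fully deterministic; there is no demographic-noise
variant.

## Parameters

| name | default | units | meaning |
|------|---------|-------|---------|
| r | 0.02 | /yr | tree growth rate |
| A | 0.001 | /contact/yr | intra-patch transmission rate |
| γ | 1.4 | /yr | infested-tree death rate |
| K | 5000 | trees | carrying capacity per patch |
| U | 0 | utility | net social cost to transport firewood |
| C_e | 0 | — | interception fraction, in [0, 1] |
| f | 0.1 | utility/capita | impact of local infestation on strategy |
| s | 0.1 | utility/capita | strength of social norms |
| σ | 0.1 | /yr | social learning rate |
| d | 0.1 | logs/yr | inter-patch firewood transmission rate |
| I_a | 1 | trees | infestation level halving transmission |
| k | 1 | — | sigmoid steepness |

These are the baseline values; the ranges explored in the sweep experiments
are r ∈ [0.01, 0.06], A ∈ [0.00065, 0.0014], γ ∈ [0.8, 1.8], U ∈ [−5, 5],
C_e ∈ [0, 1], f ∈ [0.01, 0.13], d ∈ [0.05, 0.3], I_a ∈ [0.5, 5].

## Synthetic travel network

Reservation-derived travel data are proprietary, so experiments run on a
gravity-model surrogate: patches uniform in the unit square, log-normal
population weights (σ = 1), trips(i ← j) ∝ pop_i · pop_j / dist(i, j)², no
self-trips, columns normalized to trip fractions.  The largest patch's
population is multiplied by 50 and flagged focal, standing in for the dominant
urban centre (the seeding site).  The defaults reproduce the features that
matter for transport-driven spread — heavy-tailed trip volumes and a hub that
dominates incoming trip fractions — but not the geography, seasonality, or
multi-province structure of real reservation data, so passing tests support
the mechanisms and their relative ordering, not site-specific predictions.
The generator is a pure function of its arguments; the same seed yields a
bit-identical network.

Real data can be loaded from a CSV edge list (`origin,destination,trips`)
with an optional node table; origins with zero outgoing trips are dropped by
default (configurable: self-loop or error).  The k-core reduction used to
prune sparse travel networks computes degree on the undirected support of the
graph and keeps the largest connected component of the core; surviving nodes
whose out-trips were all pruned receive a unit self-loop so the core's node
set is preserved (self-loops never enter the transport sums, which skip
j = i).

## Calibration

The transmission pair (A, d) is calibrated so that the baseline outbreak on
the default 100-node network infests at least 95% of the host population
within 10–15 years, the timescale of major observed wood-borer invasions.
The baseline values above, tuned to a much larger network, spread too slowly
at this scale, so the calibrated scenario uses the midpoints of the explored
ranges — A = 0.0012, d = 0.2 — which reach 95% cumulative infestation at
t ≈ 11.4 years (`firewoodnet.scenarios`).

## Initial conditions

All patches start at carrying capacity with local-strategist fraction 0.5
(the neutral replicator point at U = 0, I = 0) and no firewood; the focal
patch starts fully infested (I = K, S = 0).  T is initialized to I(0) so the
seeded infestation counts toward cumulative damage.  All of these are
configurable; results that depend on them are treated as qualitative.

## Numerical choices

* Integration: LSODA (adaptive, stiffness-switching) with rtol 1e-6,
  atol 1e-8; default horizon 20 years sampled every 0.1 year.  Halving the
  tolerances changes the final network-averaged infestation by well under
  0.1% on the reference scenario.
* Quarantine discontinuities: the run is segmented at t0 and t0 + Δt and the
  gate held constant inside each segment, so the adaptive stepper never
  straddles the switch; with V covering the whole network the gated run
  matches a fully decoupled (d = 0) run to 1e-6.
* L is clamped to [0, 1] at segment boundaries; sampled components below
  −1e-6 abort the run, smaller float undershoots are clamped to zero.
* Betweenness selection rounds scores to 9 decimals before ranking so that
  mathematically equal centralities tie deterministically; ties break by
  ascending node id.  The edge-distance transform uses the global off-diagonal
  maximum of P.
* The halving-interception search brackets by bisection (tolerance 0.005 in
  C_e) with a monotonicity guard; damage is provably nonincreasing in C_e
  since every transport term scales by 1 − C_e.
* Sweep cells are cached by parameter hash; identical parameter sets are
  never re-integrated, and results are independent of evaluation order.

## Experiment sizes

The reference experiments run on 100-node (test suite) and 150-node
(acceptance script) synthetic networks, the U grid for the marginal-benefit
fit is 11 evenly spaced points on [−5, 5], and quarantine sweeps evaluate
horizons {5, 10, 15} years with sets chosen by betweenness.  These sizes keep
every experiment comfortably reproducible on a laptop while preserving the
network features (hub dominance, heavy tails) the mechanisms depend on.

## Known limitations

* Enlarging the quarantine set is not guaranteed to reduce damage when social
  feedback is active (f > 0): delaying infestation also delays the behavioural
  shift to local purchasing, and detrimental regimes exist.  The sweeps report
  raw surfaces and leave "effectiveness" thresholds to the user.
* C_e is a single scalar applied to every route; per-route interception would
  be a straightforward extension but is not implemented.
* No spatial targeting of outreach (per-patch U) and no cost-benefit layer
  beyond the utility abstraction.
* The synthetic generator does not model seasonality, multi-day itineraries,
  or origin/destination asymmetries in who carries firewood.
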