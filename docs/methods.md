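# Methods

This note describes, in the package's own terms, the models and analyses
implemented in `pursuitnet`: the pursuit task, the recurrent network
agent, its training procedure, the reactive control baseline, and the
behavioral and representational statistics.

## 1. Arena and target trajectories

All simulations take place in a square arena of side `side_length`
(default 1 m) with one of two boundary rules, simulated at a fixed time
step `dt` for `T` steps:

- **reflective** — positions are clipped to the walls; distances and
  displacements are ordinary Euclidean quantities;
- **periodic** — positions wrap modulo the side length; displacements and
  distances use the minimal image (the shortest of the nine wrapped
  copies), so "through the wall" can be the shortest route.

Target speed is capped at `v_max_target` (0.4 m/s) and the pursuing
agent's speed at `v_max_agent` (0.3 m/s): the pursuer is slower than the
target can be, so pure chasing cannot always catch it.

**Random trajectories (RT).** A smooth forager: the heading performs a
Gaussian random walk with standard deviation `heading_noise_sd * sqrt(dt)`
per step, and speed follows a first-order autoregressive process around
`speed_mean`. Within `wall_avoid_dist` of a wall the heading rotates
toward the arena center at a fixed angular rate and speed is reduced,
which keeps paths inside the arena without hard reflections. Every RT
trial is unique.

**Characteristic trajectories (CT).** Stereotyped routes from four fixed
start locations (wall midpoints offset toward one corner). Each route
crosses the arena to the opposite wall and then runs along that wall to
its midpoint; motion follows the waypoints with small heading and speed
jitter, and stops at the final waypoint. CTs are therefore highly
repeatable across trials — the property that makes route anticipation
possible. In the periodic arena the same routes are defined with
unwrapped waypoints so that crossing a wall is a valid continuation. A
feasibility check rejects routes longer than `speed_mean * T * dt`.

**Datasets.** `make_dataset` mixes RTs and CTs by a Bernoulli draw with
probability `ct_fraction` per trial, samples agent start positions at
least 0.1 m from the target's start, and optionally masks the target
velocity input: with `mask_fraction = f`, a regular subsampling keeps a
`1 - f` fraction of the steps (the first step is always kept), and masked
steps deliver zero velocity input.

## 2. Network model

The agent is a rate network of `N` units whose recurrent weights are
constrained to rank `r` by construction:

    W = M Q^T / N,        M, Q ∈ R^{N×r}

with state update (Euler leak `alpha`, default 0.5)

    h(t+1) = (1 - alpha) h(t) + alpha [ W tanh(h(t)) + B u(t) + b ]

Recorded unit activations are `tanh(h)`. Factor entries are initialized
i.i.d. Gaussian with variance chosen so that at full rank the top
singular value of `W` concentrates near the configured gain (the edge of
the singular-value distribution of a product of two Gaussian matrices,
`sqrt(27/4)`, divides the naive scale).

**Inputs (6 channels).** Channels 0–3 deliver the agent's and target's
initial positions as a single pulse at `t = 0`; channels 4–5 deliver the
target's allocentric velocity at every unmasked step. The agent's own
position is *never* fed back: the network must path-integrate its own
movement internally from the initial condition and its own motor output.

**Output.** A linear readout `z = W_out tanh(h)` is squashed to a
velocity with bounded speed,

    v = v_max_agent * z / (1 + |z|),

and the position integrates `p(t+1) = boundary(p(t) + v dt)`.

**Span invariant.** With `h(0) = 0` the state always lies in the column
span of `[M, B, b]`, because every update writes into that span and the
leak preserves it. Hidden-state dimensionality is therefore at most
`r + n_in + 1` regardless of `N` — the structural mechanism linking
recurrent rank to latent dimensionality. The dynamics apply `tanh` before
the recurrent product (rather than to the whole update) precisely so this
invariant is exact.

## 3. Training

The full closed loop — state update, readout, velocity squash, position
integration with the boundary rule, and geodesic distance loss — is
differentiated analytically (backpropagation through time implemented in
NumPy; gradients verified against central finite differences). Two losses:

- `final_distance` (default): geodesic inter-agent distance at the last
  step. Only the end matters, so waiting or cutting corners is free —
  this is the objective under which predictive strategies emerge.
- `mean_distance`: time-averaged distance, which penalizes any deviation
  from immediate chasing and induces reactive behavior.

At reflective walls the position clip has zero gradient in the clipped
coordinate (subgradient mask); periodic wrapping is gradient-transparent.
Optimization is Adam with global-norm gradient clipping (1.0), on freshly
sampled trials each epoch with a held-out evaluation set fixed at the
start. Training preserves the rank bound exactly because gradients act on
the factors `M` and `Q`, never on `W` directly.

## 4. Reactive control

The baseline pursuer moves straight toward the target's *current*
position each step, at the same instantaneous speed as the paired network
rollout (step length capped by the remaining distance so it never
overshoots). In periodic arenas it chases along the minimal image. The
control has perfect information and zero anticipation; any systematic
advantage of the network over it must come from prediction.

## 5. Behavioral metrics

- **Shortcut metric**: mean distance from the agent's trajectory to the
  chord connecting the agent's start to the target's *final* position —
  the path of a perfectly informed agent. Smaller is more direct. In
  periodic arenas the chord is the minimal-image segment and distances
  are minimized over wrapped copies.
- **Normalized deviation**: mean separation between the network and
  control trajectories, divided by the network's path length — how far
  behavior departs from pure reactivity, as a fraction of distance
  traveled.
- **Distribution comparisons**: two-sample Kolmogorov–Smirnov test
  (`scipy.stats.ks_2samp`, asymptotic p-values) and 1-D Wasserstein
  distance between shortcut-metric distributions of network vs control.
- **Waiting detection**: maximal runs of steps where the distance to the
  target's endpoint changes by less than `eps`, reported when at least
  `min_len` steps long — the "wait at the end of the route" signature in
  periodic arenas.

## 6. Representational analyses

**Egocentric coordinates.** At each step the target's position is
expressed relative to the agent as (distance, bearing), with bearing
measured counterclockwise from the agent's heading (direction of its last
movement; steps before first movement are excluded).

**MRL and egocentric target units (ETUs).** For each unit, activations
are averaged in 36 bearing bins (occupancy-normalized, distance
marginalized). Because `tanh` activations are signed, the tuning curve is
shifted by its minimum to make weights non-negative; the mean resultant
length is then

    MRL = | Σ_j w_j e^{iθ_j} | / Σ_j w_j

(0 = flat, 1 = delta; invariant to adding constants and positive
rescaling). A null distribution comes from time-shuffling each unit's
activations against fixed coordinates. A unit is an ETU when its MRL
exceeds the 99th percentile of its own null *and* each of two data
splits independently exceeds its split null — the consistency
requirement. Prospective/retrospective coding is probed by re-pairing
activity at `t` with the target's position at `t + k` and recomputing the
MRL profile over shifts `k`.

**Ablations.** Units are structurally silenced (their factor rows, input
rows, biases and readout columns zeroed) in decreasing-MRL,
increasing-MRL, or random order; pursuit performance at growing ablated
fractions is compared to random-ablation controls with a KS test.

**Dimensionality.** Two estimators over activation (or latent) covariance
eigenvalues λ: the number of principal components explaining 95% of
variance, and the participation ratio `(Σλ)² / Σλ²`. Latent coordinates
are `Q^T tanh(h) / N`, the `r`-dimensional projection that drives the
recurrent dynamics.

**Linear decoding.** Ridge regression (penalty selected by efficient
leave-one-out cross-validation on the training folds, via
`sklearn.linear_model.RidgeCV`) from population activations to task
features (egocentric distance, target position, self position), with
folds split by trial to avoid within-trial leakage, optional time shifts
applied within trials, and a chance baseline from permuting features
across whole trials. Reported error is the median absolute (Euclidean for
2-D features) held-out error.

## 7. Scale presets

The reference configuration of the original study trains networks of
N ≈ 1000 units for hundreds of epochs across many seeds, which is far
beyond a single-CPU budget. The package therefore defines three presets:

- `smoke`: N=32, 2 epochs — contract checks only;
- `desk`: N=256 (N=128 for multi-network sweeps), 6-second trials at
  `dt = 0.1` (half the steps of the reference `dt = 0.05` at equal
  duration), learning rate 5e-3, 40 epochs × 512 trials — reproduces the
  qualitative signatures in minutes per network;
- `full`: the reference configuration (documented, compute-heavy).

Desk-scale quantitative results are expected to approach but not exactly
match full-scale values; the acceptance suite encodes explicit slack
bands for this comparison.
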