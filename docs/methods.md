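# Methods

## Model and conventions

The package implements the three-variable Hindmarsh–Rose neuron at three
coupling levels: isolated (`rhs_single`), mean-field reduced
(`rhs_reduced`, drive `D (x₀ − x)` on the fast equation with `D = d₁ k`),
and fully networked (`rhs_network`, diffusive Laplacian coupling
`d₁ Σⱼ Lᵢⱼ xⱼ` with `L = A − diag(k)` static, unweighted and undirected).
The network coupling is evaluated in the pairwise form
`Σⱼ Aᵢⱼ (xⱼ − xᵢ)`, which is algebraically identical to the Laplacian
form but vanishes *exactly* (not merely to rounding) on the synchronized
manifold — this is what makes the `K = 0` decoupling and constant-state
identities bit-exact.

Two printed-form ambiguities are resolved as explicit switches rather than
silent choices:

* **Slow-current decay.** Expanding the slow equation gives
  `ż = r s x − r z − r s x_r`, i.e. decay coefficient `r = 0.01` on `z`;
  an alternative transcription with unit decay (`−z`) circulates.
  `HRParams.z_decay` selects the coefficient and defaults to `r`.  The
  choice is not cosmetic: with `z_decay = r` the reduced neuron at
  `I_ext = 1, x₀ = 1` rests at `D = 0.1`, fires periodically at `D = 1`
  and rests again at `D = 1.5` — the documented regime sequence — whereas
  unit decay produces periodic firing at all three spot values.
* **Resting offset.** `x_r = −1.6` is fixed by requiring the slow
  equation's constant term `r·s·(−x_r)` to equal 0.064.

## Helmholtz split and energy

For the reduced system, with `u = y − z + D (x₀ − x)`:

```
F₁ = (u, −d x², r s x)                             (conservative)
F₂ = (−a x³ + b x² + I_ext [− k x], c − y, −r s x_r − r z)   (dissipative)
H  = u² + (2/3) d x³ + r s x²
Ḣ  = ∇H · F₂
```

Two deliberate variant axes:

* **Gradient convention.** `partial` (default/canonical) treats the drive
  `q = D (x₀ − x)` as an external input when differentiating `H` with
  respect to `x`: `∇H = (2 d x² + 2 r s x, 2u, −2u)`.  This is the unique
  reading under which `∇H · F₁ = 0` holds identically (verified
  symbolically with sympy and at 10⁴ random states).  The `full`
  convention differentiates everything and yields the closed-form residual
  `∇H · F₁ = −2 D u²`, exposed for diagnosis.
* **F₂ variant.** `consistent` (default) uses `−a x³ + b x² + I_ext` for
  the fast component so that `F₁ + F₂` rebuilds the reduced vector field
  exactly.  `as_printed` additionally carries `−k x` (degree `k`, no `d₁`
  factor), reproducing the published component list and the published
  polynomial expansion of `Ḣ` term for term; its defect against the
  vector field is exactly `(−k x, 0, 0)` and the two `Ḣ` variants differ
  by exactly `−k x (2 d x² + 2 r s x)`.  Both variants are first-class
  because neither reading can be ruled out from the printed forms alone.

Along trajectories the chain rule takes the form
`dH/dt = Ḣ_consistent − 2 D u ẋ` (the correction stems from the partial
gradient convention); the test suite verifies it by centered differences
with O(dt) convergence under dt-halving.

Energies are computed raw internally; the `/100` reporting scale is
applied only at the series/summary level (`scaled=True`, the default for
experiment outputs) and, for dimensional consistency, to `Ḣ` as well.

`H1` is the trapezoidal time average of `H` over a window `[t₀, t₀+T]`
whose start `t₀` is the first upward mean-crossing of `x` after the
burn-in (`settle_window`); `H2` is the `(max, min)` pair of `Ḣ` and the
`deltaH`/`deltaHdot` ranges serve the max–min curves.  The trapezoidal
rule matches the O(dt) accuracy of the integrator; nothing finer is
warranted.

## Numerics

* **Integrator.** Explicit forward Euler with `dt = 0.01` is the headline
  scheme (the natural reading of a finite-difference solution at that
  step); classic RK4 is included only as a cross-check oracle.  Time grids
  are computed as `i·dt` by multiplication, never accumulation.  A guard
  aborts with the step index if any component exceeds 10⁶, and scans flag
  such grid points rather than dying.
* **Equilibria.** The fixed-point cubic
  `a x³ + (d−b) x² + (s+D) x − (c + I_ext + s x_r + D x₀)` is solved by
  the companion matrix with a bisection polish; real roots closer than
  1e−9 are merged when counting.  For the default parameters the
  derivative `3x² + 4x + 4 + D` is positive for every `D ≥ 0`, so the
  root census is 1 everywhere — confirmed against a discriminant oracle
  and a dense sign-change scan in the tests.
* **Batched scans.** `bifurcation_scan` integrates the whole parameter
  grid as one vectorized Euler run (per-grid-point equilibria + seeded
  perturbations as the initial batch), so a 41-point sweep costs a single
  trajectory.
* **Burn-in.** Default 2,000 time units before the analysis window: the
  slow variable's timescale is `1/r = 100`, so this sheds 20 slow
  timescales.  Shorter horizons shrink the default burn-in to 40 % of the
  run.

## Classification and detection

* **Spikes** (`spike_stats`): upward crossings of the absolute threshold
  `x = 1` with a 1-time-unit refractory gap.  HR action potentials
  overshoot 1 while subthreshold wobble stays below; used for the
  stimulus→frequency trend, where the neuron genuinely spikes.
* **Regimes** (`regime_classify`): `resting` if the post-transient
  amplitude of `x` is below 0.01; otherwise cycles are counted as upward
  crossings of the *amplitude midpoint* and the orbit is `periodic` when
  at least 3 cycles occur with inter-cycle-interval CV < 0.05, else
  `irregular`.  The midpoint (rather than the absolute spike threshold)
  matters: under mean-field coupling at `D = 1` the limit cycle lies
  entirely in `x ∈ [−1.23, −0.22]`, a perfectly periodic subthreshold
  oscillation that an absolute-threshold detector would miss.
* **Extrema**: strict interior local maxima/minima of `x` after burn-in;
  values within 1e−4 are merged when counting distinct branches (float
  noise on limit cycles).
* **Synchronization** (`sync_error`): time-averaged cross-node standard
  deviation of `x` after burn-in.  Labels: `synchronized` < 1e−3,
  `partial_sync` < 0.5, else `asynchronous` — scale-free relative to the
  HR attractor amplitude of 2–4.  A greedy single-linkage cluster count
  (RMS pairwise difference < 1e−2) reports simultaneous partial synchrony;
  it is a diagnostic, never an assertion.

## Synthetic scenarios

The `scenarios` module bundles the study conditions: coupling-strength and
degree pattern scans on `W(100, 8, 0.01)` at `I_ext = 4` (grids
`d₁ ∈ {0.01, 0.05, 0.3, 1}`, `K ∈ {0, 2, 4, 6}`), the reduced-neuron spot
values and scans at `I_ext = 1` (`D ∈ {0.1, 1, 1.5}`, `D ∈ [0, 2]` step
0.02, `x₀ ∈ {1, 5, 10, 20, 200}`, `x₀ ∈ [0, 30]` step 0.25), and a 3-node
toy ring for smoke runs.  Initial conditions are the relevant equilibrium
plus seeded uniform perturbations of amplitude 0.1 per component — small
against the attractor so basin selection is stable; one shared network
seed and one shared IC draw per scan, so the scanned parameter is the only
thing varying.

What the generator emulates — and what it does not: trajectories are
deterministic, neurons identical, graphs static and binary.  Real neural
tissue has heterogeneous parameters, channel noise, transmission delays
and plastic synapses; passing tests therefore demonstrate the internal
consistency of the model and its energy machinery, not quantitative
predictions for biological recordings.

## Problem sizes

Default analysis runs use 2,000 time units of burn-in plus a 3,000
time-unit window (5 × 10⁵ Euler steps) for reduced-system scans, at scan
resolution 0.05 in `D` and 2.0 in `x₀`; network runs use n = 100 for
2,000 time units with decimated (stride-10) recording.  These sizes give
fully converged regime labels and energy summaries (doubling them changes
`H1` values by < 10⁻⁴) while keeping a full scan in tens of seconds.

## Known limitations

* The energy function is derived for the *reduced* system only; no
  n-node network Hamiltonian is defined (the per-node `G₁/G₂` factor
  matrices are never constructed — only their products `F₁/F₂` are
  specified by the theory).
* On `W(100, 8, 0.01)` the algebraic connectivity is λ₂ ≈ 0.12, so
  `d₁·λ₂` stays below the master-stability threshold of x-coupled HR
  neurons across the scanned coupling range: the network reaches partial
  phase coherence, not complete synchronization, and the mean-dispersion
  sync error is a blunt instrument for "pattern clarity".  In particular
  the dispersion is *not* monotone in `d₁` — intermediate coupling
  (0.05–0.3) disperses the ensemble more than near-zero coupling.
* Forward Euler at `dt = 0.01` carries O(dt) bias; RK4 cross-checks bound
  the trajectory error at short horizons, but long chaotic runs are only
  statistically, not pathwise, faithful.
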