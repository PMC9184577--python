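# Methods

`empde` learns effective partial differential equations for ensembles of
heterogeneous coupled agents in *emergent* spatial coordinates discovered from
the data. This note describes the models, the algorithmic choices and their
rationale, the problem sizes the package runs at, and the known limits of
what its tests demonstrate.

## The problem and the method

Many interacting-agent systems (coupled oscillators, neural populations)
have no physical space in which to write a field equation, yet their
long-term dynamics collapse onto a low-dimensional slow manifold that *can*
be parametrized by one or two smooth coordinates. The package:

1. **simulates** an agent ensemble and samples its attractor plus nearby
   transients;
2. **embeds** the per-agent time series with diffusion maps: each agent's
   full observed history is one data point; a Gaussian kernel
   `k(x,y) = exp(-||x-y||^2 / eps)` is row-normalized into a Markov matrix
   whose leading independent eigenvectors `phi_1, phi_2, ...` become the
   emergent coordinates;
3. **regrids** the scattered per-agent values onto a uniform grid in the
   emergent coordinate(s);
4. **learns** a right-hand side `f` with a fully connected network so that
   `dW/dt ~ f(W, dW/dx, d2W/dx2, ...; gamma)`, the spatial derivatives taken
   in emergent space with maximal-accuracy centered finite differences and
   the time derivatives by forward differences;
5. **integrates** the learned PDE forward with ground-truth *boundary
   corridors* in place of analytic boundary conditions, and a truncated-SVD
   filter that projects every emitted snapshot back onto the subspace
   spanned by the training data.

## Benchmark systems and their study conditions

**Complex Ginzburg-Landau equation (CGLE)**,
`dW/dt = W + (1 + i c1) W_xx - (1 - i c2)|W|^2 W`.
Two regimes: spatiotemporal intermittency (`c1=0, c2=-3, L=80`, periodic
boundaries, pseudospectral ETD2 Runge-Kutta stepping) and a time-periodic
state (`c1=1, c2=2, L=200`, zero-flux boundaries, three-point Laplacian with
the LSODA stiff multistep integrator). The chaotic regime is used for the
scramble-and-recover protocol: the mesh label is deliberately discarded and
must be rediscovered as the angle on the circle spanned by `(phi_1, phi_2)`.

**Mean-coupled Stuart-Landau ensemble**,
`dW_k/dt = (1 + i w_k) W_k - |W_k|^2 W_k + K(<W> - W_k)`, with `w_k`
linearly spaced in `[omega0 - gamma, omega0 + gamma]` (endpoints included)
and `K = 1.2, omega0 = 0.2`. At `gamma = 1.7` the ensemble settles into a
rigid rotating wave: every oscillator rotates at exactly `omega0` with a
constant, `w_k`-dependent amplitude, so the collective period is
`T = 2 pi / omega0 = 10 pi`. Near `gamma_H ~ 1.74-1.75` the ensemble
undergoes a collective Hopf bifurcation into oscillator death (`W = 0`).
The emergent coordinate `phi_1` is one-to-one with the intrinsic frequency.

**Heterogeneous Hodgkin-Huxley-type network** (a pre-Boetzinger complex
caricature): per-neuron voltage/channel pair `(V_k, h_k)` with standard
sigmoid gates, coupled through a synaptic current on a symmetric Chung-Lu
random graph (`w_k = p N (k/N)^r`, `p=0.9, r=0.25`), applied currents
`I_app = 22 + 2 u`, `u ~ U[-1,1]`, `N = 1024`, constants
`C=0.21, eps=0.1, g_Na=2.8, g_l=2.4, g_syn=0.3, V_Na=50, V_l=-65, V_syn=0`.
Sampling: RK5(4) from `V=-60, h=0`, window `[120, 140]` at `dt = 2e-3`,
plus scaled-snapshot transients; observables are affinely rescaled
(`V -> (V+37)/30`, `h -> (h-0.42)/0.2`) so both channels share one scale.
Two emergent coordinates arise, tracking the kinetic (`I_app`) and the
structural (degree) heterogeneity.

## Floquet analysis

Limit cycles are detected from the ensemble-mean observable (zero-crossing
period estimate, then minimization of the recurrence residual
`||x(t+T) - x(t)||` over `T` on a cubic-spline interpolant). The monodromy
matrix integrates `dV/dt = J(x(t)) V` over one period from the identity with
fixed-step RK4; the analytic Jacobian is applied in structured form (2x2
local blocks plus the `K/N` mean-field coupling), keeping each product at
`O(N^2)`. Eigendirections at secondary anchor points are obtained by
transporting the anchor eigenvector with the same variational equation —
Floquet theory makes this exact up to scale — so one monodromy computation
per cycle suffices.

The implementation is verified against two independent oracles: the
single-oscillator cycle (`multipliers {1, e^{-4 pi/omega}}`, analytic) and a
brute-force finite-difference flow-map Jacobian of the full ODE at N=48,
which reproduces the package's leading multipliers to four decimals. For
the N=512 ensemble at `gamma=1.7` the spectrum found is a neutral
multiplier 1 and a slow complex pair `~ -0.056 +/- 0.129i` over the
rotating-wave period `10 pi`; the step-like tail of fast multipliers
(`|lambda| ~ 2e-3`) affects isolated extreme-frequency oscillators, giving
the characteristic two-time-scale relaxation.

## Slow-manifold sampling

Training transients start on the attractor and are pushed off it:

* chaotic CGLE: 22 independent runs (20 train / 2 validation), burn-in 1000
  time units, additive complex Gaussian noise (sigma = 0.1 per mesh point,
  also the random-initial-condition amplitude), then 20 units sampled at
  `dt = 0.02` — 20,000 training pairs;
* no-flux CGLE: 21 anchors spaced 100 units apart after `t_min = 2000`,
  snapshots scaled by 0.9 and 1.1, 20 units at `dt = 1e-3` —
  `2 x 20 x 20,000 = 8e5` training pairs (fields stored at 128 mesh points);
* Stuart-Landau: anchors along the cycle perturbed by `+/- 0.1 v_1` with
  `v_1` the leading stable Floquet direction (real part of the unit
  eigenvector; three initial states per anchor), 20 anchors, 200 units at
  `dt = 0.05` — 240,000 training points. In the oscillator-death regime the
  role of `v_1` is played by the slowest stable eigendirection of the
  analytic Jacobian at the origin, with seeded random phase;
* Hodgkin-Huxley: the attractor window plus snapshots scaled by 0.9/1.1 in
  the rescaled coordinates, integrated 20 units.

## Kernel scales

The absolute kernel scales of the full-size experiments (100 for the chaotic
CGLE, the median squared distance for the no-flux CGLE, 20/10 for the
Stuart-Landau runs, 4000 for the neuron network) are tied to the length of
the concatenated series. For reduced problem sizes the package provides two
data-driven rules, chosen once per geometry: `nn_median` (median per-point
nearest-neighbor squared distance) resolves uniform-density manifolds such
as the scrambled-CGLE circle, and `nn_max` (the largest per-point
nearest-neighbor squared distance — the smallest scale at which the kernel
graph stays connected) is required for heterogeneous oscillator ensembles
whose density varies by orders of magnitude along the `omega` curve.
Harmonic eigenvectors are rejected by a local-linear-regression residual
test (threshold 0.5) over the first ten nontrivial modes; the number of
retained modes per experiment can also be fixed manually.

## Regridding

1D: spline interpolation of the sorted per-agent values, evaluated at
uniform grid points (periodic closure on circular coordinates, not-a-knot
ends otherwise). Agents cluster very tightly along `phi_1` where the
ensemble is dense; an interpolating cubic spline can oscillate by orders of
magnitude between near-duplicate knots, so the scaled Stuart-Landau runs use
the shape-preserving monotone cubic (PCHIP) variant, selectable per
experiment. 2D: local weighted least-squares polynomials of total degree 2
(Gaussian weights, bandwidth two grid spacings) evaluated on a 64x64
rectangle covering the central 70% of the embedding's bounding box; because
the fit is linear in the data it is assembled once as a sparse
scatter-to-grid matrix and reused across all snapshots. A global quadratic
fit remains available.

## Network and training

The right-hand side is a fully connected network (4x96 with swish
activation for the chaotic CGLE; 4x96 tanh for the no-flux CGLE and the
Stuart-Landau runs; 3x64 tanh for the neuron network), taking per point the
field channels and their first `n_derivs` emergent-space derivatives (2 for
the chaotic CGLE, otherwise 3; per axis, no mixed terms, stencil length 5
or 9 at the maximal attainable accuracy order), plus `gamma` when the
parameter sweep is learned. Weights are initialized uniformly in
`+/- 1/sqrt(fan_in)` from the seed. Training minimizes the mean-squared
error against forward-difference time derivatives with Adam (learning rates
2e-3 / 1e-3, batch 128 / 1024 as per experiment) and halves the learning
rate when the validation loss stalls for `patience` epochs (relative
improvement tolerance 1e-4). The network, backpropagation and optimizer are
implemented directly on numpy arrays; training is bit-reproducible for a
fixed seed, dataset and configuration on one device. No feature
standardization is applied by default (a z-scoring flag exists).

## Inference

Forward Euler (or an embedded RK5(4) for the periodic chaotic CGLE) steps
the interior of the emergent domain; boundary corridors of width 4 grid
cells per side (a frame in 2D) are overwritten from aligned ground-truth
data after every step, and the truncated-SVD filter (2 modes for the
no-flux CGLE, 3 for the Stuart-Landau sweep, 10 for the neuron network;
snapshots-as-rows, no centering) projects each snapshot back onto the
training subspace. The corridor must be at least as wide as the stencil
half-width; this is validated. A norm cap aborts diverged rollouts with the
last stable time.

## Desk-scale problem sizes

The reference experiments (`empde.experiments`, exercised by
`scripts/acceptance.py` and the test suite) run the full method at sizes
chosen for a single CPU; quantities that are invariant to the reduction are
measured at the canonical protocol:

* dataset counts: exact canonical protocols; spatial resolution reduced to
  64 mesh points / 64 oscillators (the pair counts depend only on the
  temporal protocol);
* scramble-and-recover: 128 agents, four independent 20-unit runs
  concatenated (the multi-run embedding protocol), kernel scale half the
  median nearest-neighbor squared distance — the locality needed to resolve
  a uniform-density closed curve, stable across realizations;
* Floquet spectrum and true-ODE Hopf scan: full `N = 512`, scan horizon
  2000 time units (transition location is horizon-stable well below this);
* learned Hopf scan: `N = 256`, five training gammas `{1.7 ... 1.8}`, two
  anchors per gamma, horizon 20 at `dt = 0.1`, 64 grid points, 40 epochs,
  SVD truncation 3; rollouts of 2000 time units at `dt = 0.1` with
  corridors from the paired true simulation;
* neuron network: full `N = 1024` per seed; snapshots strided by 5 in time
  before the Gram-matrix SVD (the variance fraction is insensitive to the
  stride);
* heat-equation benchmark: 64 mesh points, band limit 4, `dt = 0.002` (the
  forward-difference bias `~ dt k^2 / 2` stays below 2%).

## What the synthetic benchmarks do and do not show

The generators emulate the published study conditions: deterministic
dynamics observed without measurement noise, on fixed agent sets, with
seeded randomness only in initial conditions and network topology. Passing
tests therefore demonstrate the machinery (embedding, regridding, learning,
rollout, bifurcation capture) under clean conditions; they do not speak to
observation noise, missing agents, non-autonomous forcing, or attractors
outside the sampled slow manifold — the learned `f` is only trustworthy
where data existed, which is exactly why corridors and SVD filtering are
part of inference.

## Numerical choices and degenerate inputs

* ETD2RK phi-functions switch to Taylor series for `|z| < 1e-5`; the
  scheme's second-order convergence is asserted in the tests.
* Limit-cycle detection requires the sampled tail to cover about two
  periods and raises a "no cycle" error on fixed points (amplitude below
  1e-4) or non-recurrent dynamics; the relative recurrence tolerance is
  1e-6 with a hard sanity bound at 1e-3.
* `eps = 0` kernels, zero row sums, constant eigenvectors, duplicate
  emergent coordinates, rank-deficient local fits, corridors narrower than
  the stencil half-width, and non-finite losses all raise immediately
  rather than propagate.
* Eigenvector sign is fixed by making the largest-|loading| entry positive;
  mode scaling to `[-1, 1]` records the affine map and is idempotent.
* Bifurcation transitions are reported as the midpoint of the bracketing
  grid cell (threshold 0.01 on the mean limit amplitude); initial
  conditions "close to the limit set" are the settled state plus a 0.05
  perturbation along the slow stable direction, which is computed once per
  scan and reused across gammas (it varies slowly with gamma).

## Known limitations

* The learned models are surrogates for the slow dynamics only; they are
  not expected to extrapolate beyond the sampled transients, and rollouts
  without corridors/filtering can diverge.
* One- and two-dimensional emergent spaces are supported; nothing beyond.
* The no-flux CGLE state at reduced mesh resolution is only approximately
  periodic; anchors are placed by time rather than by phase.
* Diffusion-map kernel scales remain the method's most sensitive
  hyperparameter; the two provided heuristics cover the geometries
  encountered here but are not universal.
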