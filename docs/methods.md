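# Methods

## Model and sampler

The sampler targets densities defined with respect to the Hausdorff
(surface-area) measure of an embedded manifold. Working against the
Hausdorff measure, rather than a Lebesgue density in some chart, has two
consequences that shape the whole design: reparametrizations (such as the
square-root map between the simplex and the sphere) require no Jacobian
bookkeeping inside the sampler, and no coordinate chart — none of which
covers a sphere globally — is ever needed. Points and velocities are plain
ambient vectors; matrices are column-stacked (Fortran order) throughout.

The Hamiltonian `H(x, v) = -log pi_H(x) + ||v||^2 / 2` is split into its
potential and kinetic terms, each solved exactly: the potential part moves
only the velocity (a linear kick by the tangent-projected gradient), and the
kinetic part is exact geodesic flow. A symmetric kick–flow–kick composition
is reversible and symplectic, so a Metropolis correction on the energy error
yields an exact MCMC method. Velocities are refreshed each transition from
the degenerate Gaussian on the tangent space, obtained by projecting an
ambient standard normal (the projector is idempotent, so no factorization
is needed).

Geodesic flows per back-end:

- **Sphere** `x(t) = x cos(at) + (v/a) sin(at)`, `a = ||v||`; zero velocity
  is returned unchanged to avoid the 0/0 limit.
- **Stiefel** with `A = X'V` (skew, conserved) and `S = V'V`:
  `[X(t) V(t)] = [X V] exp(t[[A, -S], [I, A]]) diag(e^{-tA}, e^{-tA})`.
  The matrix exponential is scipy's scaling-and-squaring Padé routine; the
  largest exponential is `2p x 2p`. Because this closed form is easy to get
  wrong, the test suite certifies it against an independent RATTLE oracle —
  leapfrog with symmetric Lagrange multipliers enforcing `X'X = I` and
  tangency, at step `1e-5` — to `1e-6`, and separately checks that the
  `p = 1` case reproduces the sphere formula to `1e-10`. The orthogonal-group
  shortcut `X exp(tA)` (Rodrigues-type evaluations) is deliberately not a
  separate code path: one tested path only.
- **Euclidean / simplex plane**: straight lines. On flat space the whole
  scheme collapses to standard leapfrog HMC, which the tests verify
  trajectory-for-trajectory at shared random draws.
- **Simplex positivity** is handled by billiard reflections: the straight
  flow advances to the first coordinate hitting zero (exact linear root
  finding; simultaneous hits within `1e-12` resolve in index order), the
  velocity reflects in the in-plane face normal (exactly negating that
  coordinate's velocity component and preserving speed and the plane
  constraint), and the remaining time continues. More than 10,000
  reflections in one call raises a divergence error — the signature of a
  step size too large near a vertex. Note the *manifold* is the affine
  plane `1'theta = 1`; positivity is the domain of the reflecting flow, not
  part of the plane's constraint residual (the plain straight-line geodesic
  legitimately exits the positive region).
- **Products** flow componentwise. Per-component step sizes are implemented
  as componentwise time dilation of both kick and flow, which is exactly
  leapfrog with a diagonal mass matrix, so reversibility and the Metropolis
  correction are unaffected.

Floating-point drift control: sphere endpoints are renormalized after every
flow and the velocity re-projected; Stiefel endpoints are polar-retracted
only when the orthonormality residual exceeds `1e-10`; the reflecting flow
recentres the plane constraint on exit. These corrections act far below the
resolution of the Metropolis step (chains of 10^4 flows keep residuals
under `1e-8`).

Non-finite gradients or states mid-trajectory (e.g. the sphere-Dirichlet
gradient on a coordinate hyperplane) abort the trajectory and count as a
rejection, preserving the invariant distribution. Random draws occur in a
fixed order (momentum, then the acceptance uniform), so chains are
bit-reproducible from the seed.

## Targets

All log-densities are unnormalized; normalization constants (Bessel ratios
and the like) appear only in test oracles. The sphere-Dirichlet family
`log pi(x) = sum_i (2 alpha_i - 1) log|x_i|` is the pushforward of
Dirichlet(alpha) through the square-root map, extended to the whole sphere
by reflection symmetry (the `2^d` multiplicity is an irrelevant constant);
`alpha = 1/2` is uniform on the sphere, `alpha = 1` pushes to uniform on
the simplex. Its gradient is discontinuous across coordinate hyperplanes
for `alpha_i != 1/2`, the known failure mode of Hamiltonian paths at small
concentrations; `grad_check` reports it loudly rather than hiding it.

The team-competition model gives a team the win with probability equal to
its share of the total strength of the players on the field, with strengths
`p = x^2` on the simplex and a Dirichlet prior composed through the sphere
map. This ratio form follows the convention of the hyperdirichlet R package;
the package's own match generator uses the same law, so recovery tests are
internally consistent. It is a reconstruction: the authoritative display of
the win-probability formula was not available when this package was written.

The network eigenmodel places `P(Y_ij = 1) = Phi(c + u_i' Lambda u_j)` on
symmetric binary graphs, with `U` uniform on the Stiefel manifold (no
density term against the Hausdorff measure), `lambda_k ~ N(0, m)`,
`c ~ N(0, 100)`. Probit terms use `log_ndtr`, and the gradient factor
`s phi(eta) / Phi(s eta)` is evaluated on the log scale, so tail pairs
(`|eta| > 8`) neither underflow nor overflow — with hundreds of nodes the
likelihood sums tens of thousands of pair terms and a single saturated pair
would otherwise poison the sum. All closed-form gradients (including the
`G U Lambda` frame gradient) are validated against central finite
differences in the tests. The posterior is invariant to column sign flips
and permutations of `(U, Lambda)`; recovery checks therefore compare sorted
`|lambda|` and the invariant reconstruction `U Lambda U'`, and no
order-fixing term is added to the likelihood.

## Tempering

A tempered target is the log-density and gradient scaled by
`rho in (0, 1]`. Parallel tempering advances one chain per rung of an
ascending ladder ending at 1 (sequentially, for reproducibility), then
proposes `n_exchanges` swaps of uniformly random adjacent pairs, accepted
with `min(1, exp[(rho_i - rho_j)(log pi(x_j) - log pi(x_i))])`. The
`rho = 1` rung is the primary output. With a single rung the driver consumes
the identical random stream as the plain chain runner, a property the tests
pin down exactly. Replica exchange is what lets the bimodal Bingham target
(`A = diag(-20,-10,0,10,20)`, `c = 0`) cross between its `+/- e_5` modes:
a single chain at `eps = 0.01, T = 20` shows zero sign flips of `x_5` in
200 iterations, while the ten-rung ladder (`rho = 0.1, ..., 1.0`, ten
exchanges per sweep) typically shows tens of flips in 200 sweeps. The flip
count at a given seed is genuinely stochastic; roughly one seed in ten
produces none in a 200-sweep window.

## Diagnostics

Effective sample size uses Geyer's initial monotone positive-sequence
truncation: autocorrelations are summed in consecutive pairs, the leading
run of positive pairs is kept, monotonicity is enforced, and
`ESS = n / (2 sum Gamma - 1)`. Antithetic chains can report ESS above `n`;
such values are reported as computed, not clipped (HMC genuinely produces
them). The estimator is cross-checked in the tests against arviz's
non-rank-normalized (`method="mean"`) estimator within 15% and against the
`(1-phi)/(1+phi)` closed form for AR(1). A constant series returns 0 with a
warning. Mode occupancy counts sign changes of a designated coordinate
(zeros inherit the previous sign), the proxy used for mode switching on
axially bimodal targets.

## Synthetic data and what the tests show

The workbench generates eigenmodel networks (Haar frame via sign-fixed QR,
then independent Bernoulli edges through the probit link) and team matches
(disjoint uniform teams, team-sum-ratio winner). Default recovery
conditions: networks at `m = 30, p = 2, Lambda = (10, -6), c = -0.5`;
matches with 6 players, 500 matches, strengths
`(0.30, 0.22, 0.18, 0.13, 0.10, 0.07)`.

What passing tests do and do not show: the generators draw from the same
parametric families the targets model, so recovery tests validate the
sampler and posterior code, not robustness to misspecification — real
protein-interaction networks have degree heterogeneity and transitivity the
eigenmodel only partially captures, and real match data have form and
context effects absent from the strength-ratio law. At the default network
size the latent signal is weak: orthonormal columns make `u_i' Lambda u_j`
of typical size `|Lambda|/m`, so a 30-node binary adjacency carries only a
faint imprint of `U Lambda U'` (the adjacency correlates with the true
reconstruction at roughly 0.2–0.3 across generator draws). The posterior
honestly reflects that: sorted `|lambda|` credible intervals cover the
truth, posterior-mean reconstruction correlations land far below 1, and
chains started at the generating parameters drift to the same diffuse
region. Recovering the reconstruction sharply would require larger networks
or stronger eigenvalues, which is a property of the experimental design,
not of the sampler.

Eigenmodel chains are initialized with a Haar-random frame, `Lambda = 0`
and the offset at the probit of the observed edge density
(`workbench.eigenmodel_init`). Initializing with sizeable eigenvalues
instead puts many pairs deep in the wrong probit tail, where the gradient
factor grows linearly in `eta` and the log-posterior curvature scales like
its square summed over a node's pairs — step sizes that are stable near the
posterior bulk then diverge during warm-up. The neutral start keeps every
linear predictor small so this stiff transient never forms.

## Parameters and presets

- `eps` (step size) and `T` (steps per trajectory): fixed per run, no
  adaptation. The bundled Bingham presets use `eps = 0.01, T = 20`, 200
  iterations. The eigenmodel preset uses per-component steps
  `(0.004, 0.04, 0.04)` for (frame, eigenvalues, offset) with `T = 10`,
  5,000 sweeps and ladder `(0.25, 0.5, 1.0)` with 10 exchanges per sweep —
  step sizes chosen once for ~95% acceptance at the posterior bulk; a
  three-rung ladder suffices because, after sign/permutation alignment,
  this posterior is not multimodal the way the cold Bingham target is.
- Stationarity checks run chains of 20,000 iterations; the integrator-order
  measurement uses 300–500 paired trajectories at `eps in {0.05, 0.025}`,
  where the mean-|dH| ratio estimator concentrates (at larger steps its
  heavy tail makes a 200-trajectory mean swing across seeds).
- Tolerances: manifold constraint `1e-8` (spec default), flow reversibility
  `1e-9`, closed-form-vs-oracle agreement `1e-6`, finite-difference gradient
  checks `1e-5`–`1e-8` depending on the smoothness of the family.

## Known limitations

- No dynamic trajectory lengths (NUTS), no mass-matrix adaptation, no
  Riemannian (position-dependent metric) variant; preconditioning is
  available only as a constant linear re-embedding.
- Manifolds without closed-form geodesics (ellipsoids, general metric
  manifolds) are out of scope by design.
- The spherical random-walk baseline uses a symmetric geodesic-step kernel;
  it is a reconstruction of the standard construction, not a transcription
  of a published proposal density.
- Rung updates in parallel tempering run sequentially; the API is
  deliberately deterministic-first, and no concurrent execution is provided.
- ESS above `n` is reported as computed; consumers comparing estimators
  should note rank-normalized references (arviz default) will disagree on
  skewed bounded series.
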