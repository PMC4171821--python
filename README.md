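# geomc — geodesic Hamiltonian Monte Carlo on embedded manifolds

`geomc` samples from probability distributions whose support is a constraint
surface embedded in Euclidean space: the unit hypersphere `S^{d-1}`, Stiefel
manifolds `V_p(R^d)` of orthonormal `d x p` frames, the probability simplex,
and Cartesian products of these. Such distributions are the bread and butter
of directional statistics (von Mises–Fisher, Bingham), of Bayesian inference
for compositional/discrete data (Dirichlet-type posteriors on the simplex),
and of latent-factor models for networks (orthonormal-frame posteriors).
It is written for statisticians and computational biologists who need a
general-purpose, gradient-based MCMC sampler on these spaces without
conjugacy assumptions or coordinate charts.

## The algorithm

A target is specified by its unnormalized log-density `log pi_H(x)` with
respect to the **Hausdorff (surface-area) measure** of the manifold, plus its
ambient gradient. The sampler is Hamiltonian Monte Carlo with energy

    H(x, v) = -log pi_H(x) + (1/2) v'v,

where the velocity `v` lives in the tangent space at `x`. The integrator
**splits** the Hamiltonian and alternates exact solutions of its two parts:

1. half kick: `v <- v + (eps/2) P_x(grad log pi_H(x))`, with `P_x = I - NN'`
   the orthogonal projection onto the tangent space (`N` = normal basis);
2. exact geodesic flow for time `eps` — great-circle rotation on the sphere,
   the Edelman–Arias–Smith matrix-exponential curve on Stiefel manifolds,
   a straight line (with billiard reflections off the faces) on the simplex;
3. second half kick.

Both sub-flows are Hamiltonian, so the composition is reversible and
symplectic; a Metropolis accept/reject step on `exp(-dH)` makes the chain
exact. Velocities are refreshed from the tangent-space Gaussian
`(I - NN') z`, `z ~ N(0, I)`. On flat Euclidean space the scheme reduces
algebraically to textbook leapfrog HMC (verified to 1e-12 in the tests).
Product manifolds flow componentwise and admit per-component step sizes.
Power-tempered targets (`pi^rho`) and a parallel-tempering driver with
random adjacent exchanges handle multimodal cases such as the bimodal
Bingham distribution.

Shipped target families: von Mises–Fisher (`c'x`), Bingham–von Mises–Fisher
(`c'x + x'Ax`), the sphere pushforward of the Dirichlet family via the
square-root map `theta -> sqrt(theta)`, a team-competition posterior on the
simplex (team-sum-ratio win probabilities), and the probit low-rank network
eigenmodel `P(Y_ij = 1) = Phi(c + u_i' Lambda u_j)` on
`V_p(R^m) x R^p x R`.

## Worked example

Sample a von Mises distribution with concentration `kappa = 2` on the circle
(`c = (0, 2)`), then summarize:

```sh
$ cat manifold.json
{"kind": "sphere", "d": 2}
$ cat target.json
{"family": "vmf", "c": [0.0, 2.0]}
$ gmc sample --manifold manifold.json --target target.json \
      --eps 0.3 --steps 5 --iters 20000 --seed 42 --out samples.csv
{"acceptance_rate": 0.98935, "mean_abs_delta_h": 0.02286..., "n_iters": 20000, ...}
$ gmc ess samples.csv
{
  "n": 20000,
  "mean_ess": 24023.6,
  "ess_per_100": 120.1,
  ...
}
```

The acceptance rate near 1 reflects the small energy error of the splitting
integrator at this step size. The effective sample size above `n` (120 per
100 samples) indicates slight antithetic behaviour, which genuinely occurs
for well-tuned HMC. The mean resultant length of these 20,000 samples is
0.6987, against the closed-form value `I_1(2)/I_0(2) = 0.6978` for this
distribution — the kind of closed-form check the test suite applies
throughout (uniform-sphere moments, Dirichlet pushforward moments, uniform
Stiefel frame moments).

Other entry points: `gmc pt` (parallel tempering), `gmc preset` (the bundled
experiment configurations, e.g. `fig4-bimodal`, `fig5-pt`,
`eigenmodel-small`), `gmc gen eigenmodel` / `gmc gen matches` (synthetic
data), or the library API (`geomc.sampler.run_chain`,
`geomc.tempering.run_pt`).

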