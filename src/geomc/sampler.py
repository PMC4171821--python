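"""Geodesic Hamiltonian Monte Carlo transition kernel and chain driver.

The integrator splits the Hamiltonian ``H(x, v) = -log pi_H(x) + v'v / 2``
into its potential and kinetic parts and alternates their *exact* solutions:
a half momentum kick by the tangent-projected gradient, the exact geodesic
flow for a full step, and a second half kick. Both sub-flows are Hamiltonian,
so their symmetric composition is reversible and symplectic, and a standard
Metropolis correction on the energy error makes the chain exact.

On flat Euclidean space the geodesic is a straight line and the scheme is
algebraically identical to the textbook leapfrog, so plain HMC is recovered
as a special case. Two random-walk baselines used in the simplex comparison
are provided as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .manifolds import (
    DivergenceError,
    ManifoldSpec,
    check_point,
    component_slices,
    geodesic_flow,
    reflect_flow_simplex,
    sample_tangent,
    simplex_plane,
    tangent_project,
)
from .targets import TargetDensity

__all__ = [
    "HMCConfig",
    "ChainOutput",
    "hamiltonian",
    "half_kick",
    "integrator_step",
    "hmc_transition",
    "run_chain",
    "rw_sphere_transition",
    "rw_simplex_transition",
]


@dataclass(frozen=True)
class HMCConfig:
    """Sampler settings.

    ``epsilon`` may be a scalar or, for a product manifold, one step size per
    component: per-component steps are realized by dilating each component's
    kick and flow time, which leaves reversibility intact.
    """

    epsilon: float | tuple[float, ...]
    n_steps: int
    n_iters: int
    seed: int = 0
    renormalize: bool = True

    def epsilons(self, spec: ManifoldSpec) -> np.ndarray:
        """Per-component step-size array (length = number of components)."""
        ncomp = len(spec.components) if spec.kind == "product" else 1
        eps = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        if eps.size == 1:
            eps = np.full(ncomp, eps[0])
        if eps.size != ncomp:
            raise ValueError(
                f"epsilon list length {eps.size} != component count {ncomp}"
            )
        if np.any(eps <= 0):
            raise ValueError("step sizes must be positive")
        return eps


@dataclass
class ChainOutput:
    """Stored samples and per-iteration diagnostics of one chain."""

    samples: np.ndarray  # n_iters x n
    accepted: np.ndarray  # bool per iteration
    delta_h: np.ndarray  # energy error per iteration
    n_reflections: np.ndarray  # reflection count per iteration (simplex only)
    config: HMCConfig
    seed: int

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted)) if self.accepted.size else float("nan")


def hamiltonian(target: TargetDensity, x: np.ndarray, v: np.ndarray) -> float:
    """Total energy ``-log pi_H(x) + ||v||^2 / 2`` (infinite off support)."""
    lp = target.logpdf_h(x)
    k = 0.5 * float(v @ v)
    if lp == -np.inf:
        return np.inf
    return -lp + k


def _eps_ambient(spec: ManifoldSpec, eps: np.ndarray) -> np.ndarray:
    """Expand per-component step sizes to ambient-coordinate length."""
    if spec.kind != "product":
        return np.full(spec.ambient_dim, eps[0])
    out = np.empty(spec.ambient_dim)
    for e, s in zip(eps, component_slices(spec)):
        out[s] = e
    return out


def half_kick(
    target: TargetDensity,
    spec: ManifoldSpec,
    x: np.ndarray,
    v: np.ndarray,
    eps: np.ndarray,
) -> np.ndarray:
    """Half momentum kick ``v + (eps/2) P_x grad log pi_H(x)``.

    The ambient gradient is projected onto the tangent space at ``x``; the
    position is unchanged and the output remains tangent. Raises on
    non-finite gradients so the caller can reject the trajectory.
    """
    g = np.asarray(target.grad_logpdf(x), dtype=float)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient in momentum kick")
    pg = tangent_project(spec, x, g)
    return v + 0.5 * _eps_ambient(spec, eps) * pg


def _flow(spec, x, v, eps, renormalize):
    if spec.kind == "simplex_plane":
        return reflect_flow_simplex(spec, x, v, float(eps[0]))
    t = eps if spec.kind == "product" else float(eps[0])
    return geodesic_flow(spec, x, v, t, renormalize=renormalize)


def integrator_step(
    target: TargetDensity,
    spec: ManifoldSpec,
    x: np.ndarray,
    v: np.ndarray,
    eps: np.ndarray,
    renormalize: bool = True,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One symmetric splitting step: half kick, geodesic flow, half kick.

    On the simplex plane the flow step is the reflecting (billiard) flow so
    the positivity constraints are respected. Returns the new state and the
    number of reflections taken.
    """
    v = half_kick(target, spec, x, v, eps)
    res = _flow(spec, x, v, eps, renormalize)
    v = half_kick(target, spec, res.x_end, res.v_end, eps)
    return res.x_end, v, res.n_reflections


def hmc_transition(
    target: TargetDensity,
    spec: ManifoldSpec,
    x0: np.ndarray,
    config: HMCConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool, float, int]:
    """One geodesic-HMC transition from ``x0``.

    Draws a tangent-Gaussian momentum, integrates ``n_steps`` splitting
    steps, and accepts the endpoint with probability
    ``min(1, exp(H0 - H_T))``. Trajectories that produce non-finite states
    or energies are treated as divergences and rejected. The random draws
    are consumed in a fixed order (momentum first, then the acceptance
    uniform) so chains are reproducible from the seed alone.

    Returns ``(x, accepted, delta_H, n_reflections)``.
    """
    eps = config.epsilons(spec)
    v0 = sample_tangent(spec, x0, rng)
    h0 = hamiltonian(target, x0, v0)
    x, v = x0, v0
    n_refl = 0
    ok = np.isfinite(h0)
    if ok:
        try:
            for _ in range(config.n_steps):
                x, v, r = integrator_step(
                    target, spec, x, v, eps, renormalize=config.renormalize
                )
                n_refl += r
                if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
                    ok = False
                    break
        except (FloatingPointError, DivergenceError):
            ok = False
    u = rng.uniform()
    if not ok:
        return x0, False, np.inf, n_refl
    h1 = hamiltonian(target, x, v)
    dh = h1 - h0
    if np.isfinite(dh) and np.log(u) < -dh:
        return x, True, dh, n_refl
    return x0, False, dh, n_refl


def run_chain(
    target: TargetDensity,
    spec: ManifoldSpec,
    x0: np.ndarray,
    config: HMCConfig,
    rng: np.random.Generator | None = None,
) -> ChainOutput:
    """Run ``config.n_iters`` geodesic-HMC transitions from ``x0``.

    Deterministic given ``config.seed`` (or an explicitly supplied generator).
    """
    x0 = check_point(spec, np.asarray(x0, dtype=float))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = spec.ambient_dim
    samples = np.empty((config.n_iters, n))
    accepted = np.zeros(config.n_iters, dtype=bool)
    delta_h = np.empty(config.n_iters)
    refl = np.zeros(config.n_iters, dtype=int)
    x = x0
    for i in range(config.n_iters):
        x, acc, dh, nr = hmc_transition(target, spec, x, config, rng)
        samples[i] = x
        accepted[i] = acc
        delta_h[i] = dh
        refl[i] = nr
    return ChainOutput(samples, accepted, delta_h, refl, config, config.seed)


# ---------------------------------------------------------------------------
# Random-walk baseline kernels


def rw_sphere_transition(
    target: TargetDensity,
    spec: ManifoldSpec,
    x: np.ndarray,
    eps: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Geodesic random walk on the sphere with Metropolis correction.

    Proposes the geodesic endpoint from an isotropic tangent velocity scaled
    by ``eps``; the kernel is symmetric (isotropy of the velocity plus
    reversibility of the geodesic), so the acceptance ratio is the plain
    density ratio.
    """
    v = eps * sample_tangent(spec, x, rng)
    prop = geodesic_flow(spec, x, v, 1.0).x_end
    u = rng.uniform()
    log_ratio = target.logpdf_h(prop) - target.logpdf_h(x)
    if np.log(u) < log_ratio:
        return prop, True
    return x, False


def rw_simplex_transition(
    logpdf_theta,
    theta: np.ndarray,
    eps: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Random-walk Metropolis on the simplex plane.

    Proposals are degenerate Gaussian ``N(theta, eps^2 (I - nn'))`` with
    ``n = 1/sqrt(d)`` so the planar constraint holds exactly; a proposal with
    any negative coordinate has zero target density and is rejected.
    ``logpdf_theta`` is the target log-density in simplex coordinates with
    respect to Lebesgue measure on the hyperplane.
    """
    d = theta.size
    z = rng.standard_normal(d)
    step = z - np.full(d, np.sum(z) / d)
    prop = theta + eps * step
    u = rng.uniform()
    if np.min(prop) < 0.0:
        return theta, False
    log_ratio = logpdf_theta(prop) - logpdf_theta(theta)
    if np.log(u) < log_ratio:
        return prop, True
    return theta, False
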