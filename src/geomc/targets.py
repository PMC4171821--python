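"""Target densities with respect to the Hausdorff measure.

All densities are unnormalized log-densities against the surface-area
(Hausdorff) measure of the manifold they live on, together with ambient
gradients (pre-projection). Using the Hausdorff measure as reference means
reparametrizations such as the square-root simplex-to-sphere map need no
extra Jacobian bookkeeping inside the sampler; Jacobians appear only when
converting to and from Lebesgue densities.

Families implemented:

* von Mises--Fisher ``exp(c'x)`` and Bingham--von Mises--Fisher
  ``exp(c'x + x'Ax)`` on the sphere,
* the sphere-pushforward of the Dirichlet family (``alpha = 1/2`` is uniform
  on the sphere, ``alpha = 1`` pushes to uniform on the simplex),
* a team-competition (Bradley--Terry-style, team-sum ratio) posterior on the
  sphere via the square-root map,
* the probit low-rank network eigenmodel posterior on
  ``V_p(R^m) x R^p x R``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import log_ndtr
from scipy.stats import norm as _norm

from .manifolds import (
    ManifoldSpec,
    component_slices,
    euclidean,
    product,
    sphere,
    stiefel,
    tangent_project,
)

__all__ = [
    "TargetDensity",
    "BVMFParams",
    "SphereDirichletParams",
    "MatchData",
    "EigenmodelData",
    "EigenmodelState",
    "vmf",
    "bvmf",
    "uniform_target",
    "gaussian_target",
    "sphere_dirichlet",
    "simplex_sqrt_map",
    "simplex_sqrt_inverse",
    "sqrt_map_log_jacobian",
    "team_model",
    "dirichlet_logpdf_theta",
    "eigenmodel_spec",
    "eigenmodel_pack",
    "eigenmodel_unpack",
    "eigenmodel_posterior",
    "grad_check",
]


@dataclass
class TargetDensity:
    """Unnormalized log-density w.r.t. the Hausdorff measure plus gradient.

    ``grad_logpdf`` returns the *ambient* gradient; the sampler projects it
    onto the tangent space before use.
    """

    logpdf_h: Callable[[np.ndarray], float]
    grad_logpdf: Callable[[np.ndarray], np.ndarray]
    spec: ManifoldSpec
    name: str = "target"


# ---------------------------------------------------------------------------
# Sphere families


@dataclass(frozen=True)
class BVMFParams:
    """Natural parameters of the Bingham--von Mises--Fisher family.

    ``c`` is the linear (von Mises--Fisher) term, ``A`` the symmetric
    quadratic (Bingham) term; either may be zero.
    """

    c: np.ndarray
    A: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "A", A)
        if A.shape != (c.size, c.size):
            raise ValueError("A must be d x d with d = len(c)")
        if np.max(np.abs(A - A.T)) > 1e-12:
            raise ValueError("A must be symmetric")


def vmf(c: Sequence[float]) -> TargetDensity:
    """von Mises--Fisher target ``log pi(x) = c'x`` on the sphere.

    On the circle, ``c = (kappa sin mu, kappa cos mu)`` recovers the von
    Mises distribution with concentration ``kappa`` and mean direction ``mu``.
    """
    c = np.asarray(c, dtype=float)
    spec = sphere(c.size)
    return TargetDensity(
        logpdf_h=lambda x: float(c @ x),
        grad_logpdf=lambda x: c.copy(),
        spec=spec,
        name="vmf",
    )


def bvmf(c: Sequence[float], A: np.ndarray) -> TargetDensity:
    """Bingham--von Mises--Fisher target ``log pi(x) = c'x + x'Ax``.

    The pure Bingham case (``c = 0``) is axially symmetric and bimodal, with
    modes along the top eigenvector of ``A``; the gradient is ``c + 2Ax``.
    """
    params = BVMFParams(np.asarray(c, dtype=float), np.asarray(A, dtype=float))
    spec = sphere(params.c.size)
    return TargetDensity(
        logpdf_h=lambda x: float(params.c @ x + x @ params.A @ x),
        grad_logpdf=lambda x: params.c + 2.0 * params.A @ x,
        spec=spec,
        name="bvmf",
    )


def uniform_target(spec: ManifoldSpec) -> TargetDensity:
    """Uniform distribution (w.r.t. Hausdorff measure) on a compact manifold."""
    n = spec.ambient_dim
    return TargetDensity(
        logpdf_h=lambda x: 0.0,
        grad_logpdf=lambda x: np.zeros(n),
        spec=spec,
        name="uniform",
    )


def gaussian_target(mean: Sequence[float], cov_diag: Sequence[float] | None = None
                    ) -> TargetDensity:
    """Diagonal Gaussian on Euclidean space (used for leapfrog-equivalence checks)."""
    mean = np.asarray(mean, dtype=float)
    var = np.ones_like(mean) if cov_diag is None else np.asarray(cov_diag, float)
    spec = euclidean(mean.size)
    return TargetDensity(
        logpdf_h=lambda x: float(-0.5 * np.sum((x - mean) ** 2 / var)),
        grad_logpdf=lambda x: -(x - mean) / var,
        spec=spec,
        name="gaussian",
    )


# ---------------------------------------------------------------------------
# Simplex <-> sphere


def simplex_sqrt_map(theta: np.ndarray) -> np.ndarray:
    """Element-wise square root: simplex point -> positive-orthant sphere point."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("simplex point has negative coordinates")
    return np.sqrt(theta)


def simplex_sqrt_inverse(x: np.ndarray) -> np.ndarray:
    """Inverse map: sphere point -> simplex point ``theta_i = x_i^2``."""
    x = np.asarray(x, dtype=float)
    return x * x


def sqrt_map_log_jacobian(x: np.ndarray) -> float:
    """Log of the (d-1)-dimensional Jacobian of the square-root map at ``x``.

    ``J = 2^{-(d-1)} prod_i x_i^{-1}`` on the positive orthant, so a Lebesgue
    density ``f(theta)`` on the simplex corresponds to the Hausdorff density
    ``f(x^2) / J(x)`` on the sphere.
    """
    x = np.asarray(x, dtype=float)
    d = x.size
    return float(-(d - 1) * np.log(2.0) - np.sum(np.log(np.abs(x))))


@dataclass(frozen=True)
class SphereDirichletParams:
    """Concentration vector of the sphere-pushforward Dirichlet family."""

    alpha: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", a)
        if np.any(a <= 0):
            raise ValueError("all alpha_i must be positive")


def sphere_dirichlet(alpha: Sequence[float]) -> TargetDensity:
    """Dirichlet(alpha) pushed onto the sphere by the square-root map.

    ``log pi(x) = sum_i (2 alpha_i - 1) log|x_i|`` w.r.t. the Hausdorff
    measure, extended from the positive orthant to the whole sphere by
    reflection symmetry (the 2^d normalization factor is irrelevant since
    densities are unnormalized). ``alpha = 1/2`` gives the uniform
    distribution on the sphere; ``alpha = 1`` pushes forward to the uniform
    distribution on the simplex. For ``alpha_i < 1/2`` the density diverges
    on the hyperplane ``x_i = 0`` and the gradient is discontinuous there,
    which is exactly the boundary pathology that degrades Hamiltonian paths
    for small concentrations.
    """
    params = SphereDirichletParams(np.asarray(alpha, dtype=float))
    a = params.alpha
    spec = sphere(a.size)
    w = 2.0 * a - 1.0

    def logpdf(x: np.ndarray) -> float:
        ax = np.abs(x)
        mask = ax == 0.0
        if np.any(mask & (w != 0.0)):
            return -np.inf
        with np.errstate(divide="ignore"):
            terms = np.where(mask, 0.0, w * np.log(np.where(mask, 1.0, ax)))
        return float(np.sum(terms))

    def grad(x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            g = w / x
        return g

    return TargetDensity(logpdf, grad, spec, name="sphere_dirichlet")


def dirichlet_logpdf_theta(alpha: Sequence[float], theta: np.ndarray) -> float:
    """Unnormalized Dirichlet log-density in simplex coordinates (Lebesgue ref.)."""
    alpha = np.asarray(alpha, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        return -np.inf
    mask = theta == 0.0
    if np.any(mask & (alpha != 1.0)):
        return -np.inf if np.any(mask & (alpha < 1.0)) else 0.0
    with np.errstate(divide="ignore"):
        terms = np.where(mask, 0.0, (alpha - 1.0) * np.log(np.where(mask, 1.0, theta)))
    return float(np.sum(terms))


# ---------------------------------------------------------------------------
# Team-competition posterior on the sphere


@dataclass(frozen=True)
class MatchData:
    """Records of team matches: two disjoint player sets and a winner flag.

    Each record is ``(team_a, team_b, winner)`` with ``winner`` in
    ``{"a", "b"}`` and player indices below ``n_players``.
    """

    records: tuple[tuple[tuple[int, ...], tuple[int, ...], str], ...]
    n_players: int

    def __post_init__(self):
        for ta, tb, win in self.records:
            if not ta or not tb:
                raise ValueError("teams must be nonempty")
            if set(ta) & set(tb):
                raise ValueError("teams must be disjoint")
            if max(max(ta), max(tb)) >= self.n_players:
                raise ValueError("player index out of range")
            if win not in ("a", "b"):
                raise ValueError("winner must be 'a' or 'b'")


def team_model(matches: MatchData, alpha: Sequence[float]) -> TargetDensity:
    """Posterior for team-competition strengths, on the sphere.

    Player strengths ``p`` live on the simplex; a team's win probability is
    the ratio of the winning team's total strength to the total strength of
    all players in the match. The posterior under a Dirichlet(alpha) prior is
    expressed on the sphere via ``p = x^2``, giving per-match terms
    ``log sum_{winner} x_i^2 - log sum_{both} x_i^2`` plus the
    sphere-Dirichlet prior.
    """
    prior = sphere_dirichlet(alpha)
    n = matches.n_players
    n_match = len(matches.records)
    # 0/1 membership matrices: winners-only and all participants, per match
    W = np.zeros((n_match, n))
    B = np.zeros((n_match, n))
    for k, (ta, tb, winner) in enumerate(matches.records):
        w = ta if winner == "a" else tb
        W[k, list(w)] = 1.0
        B[k, list(ta) + list(tb)] = 1.0

    def logpdf(x: np.ndarray) -> float:
        total = prior.logpdf_h(x)
        if not np.isfinite(total):
            return -np.inf
        p = x * x
        sw = W @ p
        sa = B @ p
        if np.any(sw <= 0.0) or np.any(sa <= 0.0):
            return -np.inf
        return float(total + np.sum(np.log(sw)) - np.sum(np.log(sa)))

    def grad(x: np.ndarray) -> np.ndarray:
        g = prior.grad_logpdf(x).copy()
        p = x * x
        sw = W @ p
        sa = B @ p
        g += 2.0 * x * (W.T @ (1.0 / sw) - B.T @ (1.0 / sa))
        return g

    return TargetDensity(logpdf, grad, sphere(n), name="team_model")


# ---------------------------------------------------------------------------
# Network eigenmodel


@dataclass(frozen=True)
class EigenmodelData:
    """Symmetric binary network without self-loops on ``m`` nodes."""

    m: int
    y: np.ndarray  # dense m x m symmetric 0/1, zero diagonal

    def __post_init__(self):
        y = np.asarray(self.y)
        if y.shape != (self.m, self.m):
            raise ValueError("adjacency must be m x m")
        if not np.array_equal(y, y.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(y) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        object.__setattr__(self, "y", y.astype(float))

    @classmethod
    def from_edges(cls, m: int, edges: Sequence[tuple[int, int]]) -> "EigenmodelData":
        y = np.zeros((m, m))
        for i, j in edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            y[i, j] = y[j, i] = 1.0
        return cls(m, y)

    def edges(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.y, 1))
        return list(zip(ii.tolist(), jj.tolist()))


@dataclass
class EigenmodelState:
    """Latent state (U, Lambda, offset) of the network eigenmodel."""

    U: np.ndarray
    lambda_diag: np.ndarray
    offset: float


def eigenmodel_spec(m: int, p: int) -> ManifoldSpec:
    """Product manifold V_p(R^m) x R^p x R the eigenmodel posterior lives on."""
    return product(stiefel(m, p), euclidean(p), euclidean(1))


def eigenmodel_pack(state: EigenmodelState) -> np.ndarray:
    """Flatten a state into a single column-stacked ambient vector."""
    return np.concatenate(
        [np.ravel(state.U, order="F"), np.asarray(state.lambda_diag, float),
         [float(state.offset)]]
    )


def eigenmodel_unpack(x: np.ndarray, m: int, p: int) -> EigenmodelState:
    """Inverse of :func:`eigenmodel_pack`."""
    U = np.asarray(x[: m * p]).reshape(m, p, order="F")
    lam = np.asarray(x[m * p : m * p + p], dtype=float)
    return EigenmodelState(U, lam, float(x[m * p + p]))


def eigenmodel_posterior(data: EigenmodelData, p: int) -> TargetDensity:
    """Posterior of the probit low-rank eigenmodel for a binary network.

    Edge probabilities are ``P(Y_ij = 1) = Phi(offset + u_i' Lambda u_j)``
    with ``U`` uniform on the Stiefel manifold (no density term w.r.t. the
    Hausdorff measure), ``lambda_k ~ N(0, m)`` and ``offset ~ N(0, 10^2)``.
    Probit terms use ``log_ndtr`` so tail pairs (|eta| > 8) do not underflow;
    the gradient factor ``g_ij = s_ij phi(eta_ij) / Phi(s_ij eta_ij)`` with
    ``s_ij = 2 y_ij - 1`` is evaluated on the log scale for the same reason.
    """
    m = data.m
    y = data.y
    s = 2.0 * y - 1.0
    np.fill_diagonal(s, 0.0)
    iu = np.triu_indices(m, 1)
    spec = eigenmodel_spec(m, p)

    def _eta(U, lam, c):
        return c + (U * lam) @ U.T

    def logpdf(x: np.ndarray) -> float:
        st = eigenmodel_unpack(x, m, p)
        eta = _eta(st.U, st.lambda_diag, st.offset)
        ll = float(np.sum(log_ndtr(s[iu] * eta[iu])))
        lp = -float(np.sum(st.lambda_diag**2)) / (2.0 * m) - st.offset**2 / 200.0
        return ll + lp

    def grad(x: np.ndarray) -> np.ndarray:
        st = eigenmodel_unpack(x, m, p)
        U, lam, c = st.U, st.lambda_diag, st.offset
        eta = _eta(U, lam, c)
        # g_ij = s_ij * phi(eta_ij) / Phi(s_ij eta_ij), symmetric, zero diag
        log_phi = _norm.logpdf(eta)
        g = s * np.exp(log_phi - log_ndtr(s * eta))
        np.fill_diagonal(g, 0.0)
        grad_U = g @ (U * lam)
        grad_lam = 0.5 * np.einsum("ik,ij,jk->k", U, g, U) - lam / m
        grad_c = 0.5 * float(np.sum(g)) - c / 100.0
        return np.concatenate([np.ravel(grad_U, order="F"), grad_lam, [grad_c]])

    return TargetDensity(logpdf, grad, spec, name="eigenmodel")


# ---------------------------------------------------------------------------
# Gradient checking


def grad_check(target: TargetDensity, x: np.ndarray, h: float = 1e-6) -> float:
    """Worst relative error of the analytic gradient vs central differences.

    Both the analytic and the finite-difference gradients are projected onto
    the tangent space at ``x`` before comparison, since only the tangential
    component enters the dynamics.
    """
    x = np.asarray(x, dtype=float)
    f0 = target.logpdf_h(x)
    if not np.isfinite(f0):
        raise ValueError("logpdf not finite at the evaluation point")
    n = x.size
    num = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        fp, fm = target.logpdf_h(x + e), target.logpdf_h(x - e)
        if not (np.isfinite(fp) and np.isfinite(fm)):
            raise ValueError("logpdf not finite at a finite-difference stencil point")
        num[i] = (fp - fm) / (2.0 * h)
    pa = tangent_project(target.spec, x, target.grad_logpdf(x))
    pn = tangent_project(target.spec, x, num)
    denom = max(1.0, float(np.linalg.norm(pa)))
    return float(np.linalg.norm(pa - pn) / denom)
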