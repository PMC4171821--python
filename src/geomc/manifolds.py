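"""Embedded-manifold back-ends for geodesic Monte Carlo.

Every manifold here lives in ambient Euclidean coordinates: a point is a
flat length-``n`` vector (matrices are column-stacked), and the manifold is
the zero set of an explicit constraint (``x'x = 1`` for the sphere,
``X'X = I`` for a Stiefel manifold, ``1'theta = 1`` for the simplex plane).
Each back-end supplies the three primitives the sampler needs:

* an orthogonal projection onto the tangent space at a point,
* the exact geodesic flow from a point/velocity pair,
* a Gaussian velocity sampler on the tangent space.

Working in ambient coordinates avoids coordinate charts entirely: no chart
covers the whole sphere, and the chart-based formulation needs metric
inverses and Christoffel symbols that the embedded formulation never touches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ManifoldSpec",
    "FlowResult",
    "ManifoldError",
    "InvalidPointError",
    "InvalidTangentError",
    "DivergenceError",
    "euclidean",
    "sphere",
    "stiefel",
    "simplex_plane",
    "product",
    "component_slices",
    "constraint_residual",
    "check_point",
    "tangent_project",
    "normal_basis",
    "geodesic_flow",
    "reflect_flow_simplex",
    "sample_tangent",
    "spec_to_json",
    "spec_from_json",
]


class ManifoldError(ValueError):
    """Base class for manifold-related errors."""


class InvalidPointError(ManifoldError):
    """Point violates the manifold constraint beyond tolerance."""


class InvalidTangentError(ManifoldError):
    """Vector is not in the tangent space at the given point."""


class DivergenceError(ManifoldError):
    """Trajectory diverged (e.g. unbounded reflection count)."""


@dataclass(frozen=True)
class ManifoldSpec:
    """Descriptor of an embedded manifold.

    Attributes
    ----------
    kind
        One of ``euclidean``, ``sphere``, ``stiefel``, ``simplex_plane``,
        ``product``.
    ambient_dim
        Dimension ``n`` of the ambient Euclidean space.
    intrinsic_dim
        Dimension ``m`` of the manifold itself.
    matrix_shape
        ``(d, p)`` for Stiefel manifolds (points are d x p matrices with
        orthonormal columns, column-stacked into length d*p vectors).
    components
        Component specs, for ``product`` manifolds.
    constraint_tol
        Tolerance used when validating points.
    """

    kind: str
    ambient_dim: int
    intrinsic_dim: int
    matrix_shape: tuple[int, int] | None = None
    components: tuple["ManifoldSpec", ...] = ()
    constraint_tol: float = 1e-8


def euclidean(n: int, tol: float = 1e-8) -> ManifoldSpec:
    """Flat Euclidean space R^n (geodesics are straight lines)."""
    if n < 1:
        raise ValueError("euclidean manifold needs n >= 1")
    return ManifoldSpec("euclidean", n, n, constraint_tol=tol)


def sphere(d: int, tol: float = 1e-8) -> ManifoldSpec:
    """Unit (d-1)-sphere embedded in R^d."""
    if d < 2:
        raise ValueError("sphere needs ambient dimension d >= 2")
    return ManifoldSpec("sphere", d, d - 1, constraint_tol=tol)


def stiefel(d: int, p: int, tol: float = 1e-8) -> ManifoldSpec:
    """Stiefel manifold V_p(R^d) of d x p matrices with orthonormal columns."""
    if not (1 <= p <= d):
        raise ValueError("stiefel requires 1 <= p <= d")
    m = d * p - p * (p + 1) // 2
    return ManifoldSpec("stiefel", d * p, m, matrix_shape=(d, p), constraint_tol=tol)


def simplex_plane(d: int, tol: float = 1e-8) -> ManifoldSpec:
    """The affine hyperplane {theta : 1'theta = 1} containing the simplex.

    The plane is the manifold; the positivity constraints of the simplex
    itself are enforced by billiard reflections in :func:`reflect_flow_simplex`.
    """
    if d < 2:
        raise ValueError("simplex plane needs d >= 2")
    return ManifoldSpec("simplex_plane", d, d - 1, constraint_tol=tol)


def product(*components: ManifoldSpec, tol: float = 1e-8) -> ManifoldSpec:
    """Cartesian product of manifolds; coordinates are concatenated."""
    if not components:
        raise ValueError("product needs at least one component")
    n = sum(c.ambient_dim for c in components)
    m = sum(c.intrinsic_dim for c in components)
    return ManifoldSpec("product", n, m, components=tuple(components), constraint_tol=tol)


def component_slices(spec: ManifoldSpec) -> list[slice]:
    """Ambient-coordinate slices of each component of a product manifold."""
    if spec.kind != "product":
        return [slice(0, spec.ambient_dim)]
    out, off = [], 0
    for c in spec.components:
        out.append(slice(off, off + c.ambient_dim))
        off += c.ambient_dim
    return out


def _as_matrix(spec: ManifoldSpec, x: np.ndarray) -> np.ndarray:
    d, p = spec.matrix_shape
    return np.asarray(x, dtype=float).reshape(d, p, order="F")


def _vec(X: np.ndarray) -> np.ndarray:
    return np.ravel(X, order="F")


def _check_len(spec: ManifoldSpec, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (spec.ambient_dim,):
        raise ManifoldError(
            f"expected vector of length {spec.ambient_dim}, got shape {x.shape}"
        )
    return x


def constraint_residual(spec: ManifoldSpec, x: np.ndarray) -> float:
    """Scalar measure of constraint violation; zero iff ``x`` is on the manifold."""
    x = _check_len(spec, x)
    if spec.kind == "euclidean":
        return 0.0
    if spec.kind == "sphere":
        return abs(float(x @ x) - 1.0)
    if spec.kind == "stiefel":
        X = _as_matrix(spec, x)
        p = spec.matrix_shape[1]
        return float(np.linalg.norm(X.T @ X - np.eye(p)))
    if spec.kind == "simplex_plane":
        # the manifold is the affine plane; positivity is the billiard domain
        # and is enforced by reflect_flow_simplex, not by the plane constraint
        return abs(float(np.sum(x)) - 1.0)
    if spec.kind == "product":
        return max(
            constraint_residual(c, x[s])
            for c, s in zip(spec.components, component_slices(spec))
        )
    raise ManifoldError(f"unknown manifold kind {spec.kind!r}")


def check_point(spec: ManifoldSpec, x: np.ndarray) -> np.ndarray:
    """Validate that ``x`` lies on the manifold within ``constraint_tol``."""
    x = _check_len(spec, x)
    r = constraint_residual(spec, x)
    if r > spec.constraint_tol:
        raise InvalidPointError(
            f"point violates {spec.kind} constraint: residual {r:.3e} "
            f"> tol {spec.constraint_tol:.3e}"
        )
    return x


def tangent_project(spec: ManifoldSpec, x: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Orthogonal projection of an ambient vector onto the tangent space at ``x``.

    Closed forms: sphere ``(I - xx')u``; Stiefel ``U - X sym(X'U)``;
    simplex plane ``(I - nn')u`` with ``n = 1/sqrt(d)``; Euclidean identity.
    The projection is idempotent and self-adjoint.
    """
    x = check_point(spec, x)
    u = _check_len(spec, u)
    if spec.kind == "euclidean":
        return u.copy()
    if spec.kind == "sphere":
        return u - (x @ u) * x
    if spec.kind == "stiefel":
        X = _as_matrix(spec, x)
        U = _as_matrix(spec, u)
        sym = (X.T @ U + U.T @ X) / 2.0
        return _vec(U - X @ sym)
    if spec.kind == "simplex_plane":
        d = spec.ambient_dim
        return u - np.full(d, np.sum(u) / d)
    if spec.kind == "product":
        out = np.empty_like(u)
        for c, s in zip(spec.components, component_slices(spec)):
            out[s] = tangent_project(c, x[s], u[s])
        return out
    raise ManifoldError(f"unknown manifold kind {spec.kind!r}")


def normal_basis(spec: ManifoldSpec, x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the normal space at ``x``.

    Returns an ``(n, n - m)`` array whose columns span the orthogonal
    complement of the tangent space. For the Stiefel manifold the basis
    consists of the ``p`` vectors ``vec(X e_i e_i')`` and the ``p(p-1)/2``
    vectors ``vec(X (e_i e_j' + e_j e_i') / sqrt(2))`` for ``i < j``.
    Euclidean space has an empty basis.
    """
    x = check_point(spec, x)
    n = spec.ambient_dim
    if spec.kind == "euclidean":
        return np.zeros((n, 0))
    if spec.kind == "sphere":
        return x.reshape(-1, 1).copy()
    if spec.kind == "simplex_plane":
        return np.full((n, 1), 1.0 / np.sqrt(n))
    if spec.kind == "stiefel":
        d, p = spec.matrix_shape
        cols = []
        for i in range(p):
            E = np.zeros((p, p))
            E[i, i] = 1.0
            cols.append(_vec(_as_matrix(spec, x) @ E))
        X = _as_matrix(spec, x)
        for i in range(p):
            for j in range(i + 1, p):
                E = np.zeros((p, p))
                E[i, j] = E[j, i] = 1.0
                cols.append(_vec(X @ E) / np.sqrt(2.0))
        return np.column_stack(cols)
    if spec.kind == "product":
        blocks = [
            normal_basis(c, x[s]) for c, s in zip(spec.components, component_slices(spec))
        ]
        k = sum(b.shape[1] for b in blocks)
        out = np.zeros((n, k))
        col = 0
        for b, s in zip(blocks, component_slices(spec)):
            out[s, col : col + b.shape[1]] = b
            col += b.shape[1]
        return out
    raise ManifoldError(f"unknown manifold kind {spec.kind!r}")


@dataclass
class FlowResult:
    """Endpoint of a geodesic (or reflected) flow."""

    x_end: np.ndarray
    v_end: np.ndarray
    elapsed: float
    n_reflections: int = 0


def _check_tangent(spec: ManifoldSpec, x: np.ndarray, v: np.ndarray) -> np.ndarray:
    v = _check_len(spec, v)
    pv = tangent_project(spec, x, v)
    scale = 1.0 + float(np.linalg.norm(v))
    if np.linalg.norm(pv - v) > 1e-6 * scale:
        raise InvalidTangentError("velocity is not tangent at the given point")
    return v


def _sphere_flow(x: np.ndarray, v: np.ndarray, t: float, renormalize: bool):
    alpha = float(np.linalg.norm(v))
    if alpha == 0.0:
        return x.copy(), v.copy()
    c, s = np.cos(alpha * t), np.sin(alpha * t)
    x_t = x * c + (v / alpha) * s
    v_t = -alpha * x * s + v * c
    if renormalize:
        x_t = x_t / np.linalg.norm(x_t)
        v_t = v_t - (x_t @ v_t) * x_t
    return x_t, v_t


def _stiefel_flow(spec: ManifoldSpec, x: np.ndarray, v: np.ndarray, t: float,
                  renormalize: bool):
    d, p = spec.matrix_shape
    X = _as_matrix(spec, x)
    V = _as_matrix(spec, v)
    A = X.T @ V  # skew-symmetric, constant along the geodesic
    S = V.T @ V
    B = np.block([[A, -S], [np.eye(p), A]])
    E = expm(t * B)
    eA = expm(-t * A)
    W = np.hstack([X, V]) @ E
    Xt = W[:, :p] @ eA
    Vt = W[:, p:] @ eA
    if renormalize and np.linalg.norm(Xt.T @ Xt - np.eye(p)) > 1e-10:
        # polar retraction: nearest orthonormal frame
        uu, _, vv = np.linalg.svd(Xt, full_matrices=False)
        Xt = uu @ vv
    # keep the velocity exactly tangent at the (possibly retracted) endpoint
    sym = (Xt.T @ Vt + Vt.T @ Xt) / 2.0
    Vt = Vt - Xt @ sym
    return _vec(Xt), _vec(Vt)


def geodesic_flow(
    spec: ManifoldSpec,
    x: np.ndarray,
    v: np.ndarray,
    t: float | np.ndarray,
    renormalize: bool = True,
) -> FlowResult:
    """Exact geodesic flow from ``(x, v)`` for time ``t``.

    Sphere: great-circle rotation ``x(t) = x cos(at) + (v/a) sin(at)`` with
    angular speed ``a = ||v||``. Stiefel: the matrix-exponential form with
    ``A = X'V`` and ``S = V'V``,
    ``[X(t) V(t)] = [X V] exp(t [[A, -S], [I, A]]) diag(e^{-tA}, e^{-tA})``.
    Euclidean and simplex-plane geodesics are straight lines. Products flow
    componentwise; there ``t`` may be a per-component array (used by the
    sampler to realize per-component step sizes).

    Kinetic energy ``||v||`` is conserved exactly. With ``renormalize`` the
    endpoint is nudged back onto the constraint set (sphere: rescale;
    Stiefel: polar retraction only when the residual exceeds 1e-10) so that
    float drift does not accumulate over long chains.
    """
    x = check_point(spec, x)
    v = _check_tangent(spec, x, v)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("flow time must be finite")
    if spec.kind == "product":
        if t_arr.size == 1:
            t_arr = np.full(len(spec.components), t_arr[0])
        if t_arr.size != len(spec.components):
            raise ValueError("per-component time must match component count")
        x_end = np.empty_like(x)
        v_end = np.empty_like(v)
        refl = 0
        for (c, s), tc in zip(
            zip(spec.components, component_slices(spec)), t_arr
        ):
            sub = geodesic_flow(c, x[s], v[s], tc, renormalize=renormalize)
            x_end[s], v_end[s] = sub.x_end, sub.v_end
            refl += sub.n_reflections
        return FlowResult(x_end, v_end, float(np.max(t_arr)), refl)
    if t_arr.size != 1:
        raise ValueError("per-component time is only meaningful for products")
    tf = float(t_arr[0])
    if spec.kind in ("euclidean", "simplex_plane"):
        return FlowResult(x + tf * v, v.copy(), tf, 0)
    if spec.kind == "sphere":
        x_t, v_t = _sphere_flow(x, v, tf, renormalize)
        return FlowResult(x_t, v_t, tf, 0)
    if spec.kind == "stiefel":
        x_t, v_t = _stiefel_flow(spec, x, v, tf, renormalize)
        return FlowResult(x_t, v_t, tf, 0)
    raise ManifoldError(f"unknown manifold kind {spec.kind!r}")


_MAX_REFLECTIONS = 10_000


def reflect_flow_simplex(
    spec: ManifoldSpec, theta: np.ndarray, v: np.ndarray, t: float
) -> FlowResult:
    """Straight-line flow on the simplex plane with billiard reflections.

    The path advances ``theta + s v`` until a coordinate first reaches zero,
    then reflects the velocity in the face ``theta_i = 0`` (within the plane):
    ``v <- v - 2 (w'v) w`` with ``w`` the unit in-plane normal of the face,
    which exactly negates ``v_i`` while preserving ``||v||`` and ``1'v = 0``.
    Simultaneous hits (within 1e-12 in time) are resolved in index order.
    """
    theta = check_point(spec, theta)
    v = _check_tangent(spec, theta, v)
    if np.min(theta) < -spec.constraint_tol:
        raise InvalidPointError("point has negative coordinates")
    if not np.isfinite(t):
        raise ValueError("flow time must be finite")
    d = spec.ambient_dim
    th = np.maximum(theta.copy(), 0.0)
    vv = v.copy()
    remaining = float(t)
    n_refl = 0
    w_norm = np.sqrt(1.0 - 1.0 / d)
    while remaining > 0.0:
        hit_idx = -1
        hit_s = np.inf
        for i in range(d):
            if vv[i] < 0.0:
                s = -th[i] / vv[i]
                if s < -1e-15:
                    continue
                s = max(s, 0.0)
                if s < hit_s - 1e-12 or (abs(s - hit_s) <= 1e-12 and i < hit_idx):
                    hit_s, hit_idx = s, i
        if hit_idx < 0 or hit_s >= remaining:
            th = th + remaining * vv
            break
        th = th + hit_s * vv
        th[hit_idx] = 0.0
        w = np.full(d, -1.0 / d)
        w[hit_idx] += 1.0
        w /= w_norm
        vv = vv - 2.0 * (w @ vv) * w
        remaining -= hit_s
        n_refl += 1
        if n_refl > _MAX_REFLECTIONS:
            raise DivergenceError(
                "more than 10000 reflections in one flow call; "
                "step size too large near a simplex vertex"
            )
    th = np.where((th < 0.0) & (th > -1e-12), 0.0, th)
    # recentre onto the plane: roundoff in the sum accumulates over chains
    th = th + (1.0 - np.sum(th)) / d
    vv = vv - np.sum(vv) / d
    return FlowResult(th, vv, float(t), n_refl)


def sample_tangent(
    spec: ManifoldSpec, x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw a standard tangent-Gaussian velocity at ``x``.

    Draws ``z ~ N(0, I_n)`` in ambient space and projects: because the
    tangent projector is idempotent, ``(I - NN')z`` has exactly the
    degenerate Gaussian law on the tangent space; no Cholesky factor of the
    metric is ever needed.
    """
    z = rng.standard_normal(spec.ambient_dim)
    return tangent_project(spec, x, z)


# ---------------------------------------------------------------------------
# JSON (de)serialization of specs


def spec_to_json(spec: ManifoldSpec) -> dict:
    """Spec as a plain JSON-ready dict."""
    if spec.kind == "product":
        return {
            "kind": "product",
            "components": [spec_to_json(c) for c in spec.components],
            "tol": spec.constraint_tol,
        }
    if spec.kind == "stiefel":
        d, p = spec.matrix_shape
        return {"kind": "stiefel", "d": d, "p": p, "tol": spec.constraint_tol}
    return {"kind": spec.kind, "d": spec.ambient_dim, "tol": spec.constraint_tol}


def spec_from_json(obj: dict | str) -> ManifoldSpec:
    """Inverse of :func:`spec_to_json`; accepts a dict or a JSON string."""
    if isinstance(obj, str):
        obj = json.loads(obj)
    kind = obj["kind"]
    tol = float(obj.get("tol", 1e-8))
    if kind == "product":
        return product(*[spec_from_json(c) for c in obj["components"]], tol=tol)
    if kind == "stiefel":
        return stiefel(int(obj["d"]), int(obj["p"]), tol=tol)
    if kind == "sphere":
        return sphere(int(obj["d"]), tol=tol)
    if kind == "simplex_plane":
        return simplex_plane(int(obj["d"]), tol=tol)
    if kind == "euclidean":
        return euclidean(int(obj["d"]), tol=tol)
    raise ManifoldError(f"unknown manifold kind {kind!r}")
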