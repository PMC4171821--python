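"""Manifold back-ends: projections, normal bases, geodesic flows, reflections."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from geomc import manifolds as mf


def random_on_manifold(spec, rng):
    if spec.kind == "sphere":
        z = rng.standard_normal(spec.ambient_dim)
        return z / np.linalg.norm(z)
    if spec.kind == "stiefel":
        d, p = spec.matrix_shape
        q, r = np.linalg.qr(rng.standard_normal((d, p)))
        return np.ravel(q * np.sign(np.diag(r)), order="F")
    if spec.kind == "euclidean":
        return rng.standard_normal(spec.ambient_dim)
    if spec.kind == "simplex_plane":
        th = rng.dirichlet(np.ones(spec.ambient_dim))
        return th
    if spec.kind == "product":
        return np.concatenate([random_on_manifold(c, rng) for c in spec.components])
    raise AssertionError(spec.kind)


SPECS = [
    mf.sphere(3),
    mf.sphere(7),
    mf.stiefel(4, 2),
    mf.stiefel(6, 3),
    mf.simplex_plane(4),
    mf.euclidean(5),
    mf.product(mf.sphere(3), mf.stiefel(4, 2), mf.euclidean(2)),
]


# ---------------------------------------------------------------------------
# constraint_residual / tangent_project / normal_basis


def test_constraint_residual_sphere_examples():
    s3 = mf.sphere(3)
    assert mf.constraint_residual(s3, np.array([1.0, 0, 0])) == 0.0
    assert mf.constraint_residual(s3, np.array([2.0, 0, 0])) == pytest.approx(3.0)
    st32 = mf.stiefel(3, 2)
    x = np.ravel(np.eye(3)[:, :2], order="F")
    assert mf.constraint_residual(st32, x) == 0.0


def test_constraint_residual_dimension_error():
    with pytest.raises(mf.ManifoldError):
        mf.constraint_residual(mf.sphere(3), np.zeros(4))


def test_tangent_project_sphere_example():
    s3 = mf.sphere(3)
    out = mf.tangent_project(s3, np.array([1.0, 0, 0]), np.array([0.3, 1.0, 2.0]))
    np.testing.assert_allclose(out, [0.0, 1.0, 2.0], atol=1e-15)


@pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.kind + str(s.ambient_dim))
def test_projection_idempotent_and_self_adjoint(spec, rng):
    for _ in range(10):
        x = random_on_manifold(spec, rng)
        u = rng.standard_normal(spec.ambient_dim)
        w = rng.standard_normal(spec.ambient_dim)
        pu = mf.tangent_project(spec, x, u)
        np.testing.assert_allclose(mf.tangent_project(spec, x, pu), pu, atol=1e-12)
        # self-adjointness u'P(w) = P(u)'w
        assert abs(u @ mf.tangent_project(spec, x, w) - pu @ w) < 1e-12 * (
            1 + np.linalg.norm(u) * np.linalg.norm(w)
        )


def test_projection_rejects_off_manifold_point():
    with pytest.raises(mf.InvalidPointError):
        mf.tangent_project(mf.sphere(3), np.array([1.0, 1.0, 0.0]), np.zeros(3))


def test_normal_basis_examples(rng):
    np.testing.assert_allclose(
        mf.normal_basis(mf.sphere(3), np.array([0.0, 0, 1.0])).ravel(), [0, 0, 1.0]
    )
    spl = mf.simplex_plane(3)
    nb = mf.normal_basis(spl, np.full(3, 1 / 3))
    np.testing.assert_allclose(nb.ravel(), np.full(3, 1 / np.sqrt(3)))
    assert mf.normal_basis(mf.euclidean(4), np.zeros(4)).shape == (4, 0)


@pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.kind + str(s.ambient_dim))
def test_normal_basis_orthonormal_and_orthogonal_to_tangent(spec, rng):
    x = random_on_manifold(spec, rng)
    nb = mf.normal_basis(spec, x)
    k = spec.ambient_dim - spec.intrinsic_dim
    assert nb.shape == (spec.ambient_dim, k)
    np.testing.assert_allclose(nb.T @ nb, np.eye(k), atol=1e-10)
    for _ in range(5):
        u = rng.standard_normal(spec.ambient_dim)
        pu = mf.tangent_project(spec, x, u)
        np.testing.assert_allclose(nb.T @ pu, np.zeros(k), atol=1e-9)


def test_stiefel_projection_matches_bruteforce_normal_removal(rng):
    """Closed-form Stiefel projection equals u minus its normal-space component."""
    spec = mf.stiefel(4, 2)
    for _ in range(5):
        x = random_on_manifold(spec, rng)
        u = rng.standard_normal(8)
        nb = mf.normal_basis(spec, x)
        brute = u - nb @ (nb.T @ u)
        np.testing.assert_allclose(mf.tangent_project(spec, x, u), brute, atol=1e-10)


# ---------------------------------------------------------------------------
# geodesic flows


def test_sphere_quarter_great_circle():
    r = mf.geodesic_flow(
        mf.sphere(2), np.array([1.0, 0.0]), np.array([0.0, np.pi / 2]), 1.0
    )
    np.testing.assert_allclose(r.x_end, [0.0, 1.0], atol=1e-12)
    np.testing.assert_allclose(r.v_end, [-np.pi / 2, 0.0], atol=1e-12)


@pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.kind + str(s.ambient_dim))
def test_zero_velocity_is_stationary(spec, rng):
    x = random_on_manifold(spec, rng)
    r = mf.geodesic_flow(spec, x, np.zeros(spec.ambient_dim), 2.5)
    np.testing.assert_allclose(r.x_end, x, atol=1e-14)
    np.testing.assert_allclose(r.v_end, 0.0, atol=1e-14)


def test_stiefel_p1_equals_sphere_flow(rng):
    d = 5
    ssp, tsp = mf.sphere(d), mf.stiefel(d, 1)
    for _ in range(10):
        x = random_on_manifold(ssp, rng)
        v = mf.tangent_project(ssp, x, rng.standard_normal(d))
        rs = mf.geodesic_flow(ssp, x, v, 0.8)
        rt = mf.geodesic_flow(tsp, x, v, 0.8)
        np.testing.assert_allclose(rs.x_end, rt.x_end, atol=1e-10)
        np.testing.assert_allclose(rs.v_end, rt.v_end, atol=1e-10)


@pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.kind + str(s.ambient_dim))
def test_flow_invariants(spec, rng):
    """Energy conservation, reversibility and the group property of the flow."""
    for _ in range(12):
        x = random_on_manifold(spec, rng)
        v = mf.tangent_project(spec, x, rng.standard_normal(spec.ambient_dim))
        t = float(rng.uniform(0.1, 1.5))
        fwd = mf.geodesic_flow(spec, x, v, t)
        assert abs(np.linalg.norm(fwd.v_end) - np.linalg.norm(v)) <= 1e-9 * (
            1 + np.linalg.norm(v)
        )
        assert mf.constraint_residual(spec, fwd.x_end) <= 1e-9
        back = mf.geodesic_flow(spec, fwd.x_end, -fwd.v_end, t)
        np.testing.assert_allclose(back.x_end, x, atol=1e-9)
        np.testing.assert_allclose(back.v_end, -v, atol=1e-9)
        s = 0.4 * t
        two_leg = mf.geodesic_flow(spec, x, v, s)
        two_leg = mf.geodesic_flow(spec, two_leg.x_end, two_leg.v_end, t - s)
        np.testing.assert_allclose(two_leg.x_end, fwd.x_end, atol=1e-8)
        np.testing.assert_allclose(two_leg.v_end, fwd.v_end, atol=1e-8)


def test_flow_rejects_bad_inputs(rng):
    spec = mf.sphere(3)
    x = np.array([1.0, 0, 0])
    with pytest.raises(mf.InvalidTangentError):
        mf.geodesic_flow(spec, x, np.array([1.0, 1.0, 0.0]), 0.5)
    with pytest.raises(ValueError):
        mf.geodesic_flow(spec, x, np.array([0.0, 1.0, 0.0]), np.inf)


@pytest.mark.parametrize(
    "spec,n_flows",
    [(mf.sphere(10), 10_000), (mf.stiefel(6, 3), 10_000)],
    ids=["sphere10", "stiefel6x3"],
)
def test_constraint_preserved_over_chained_flows(spec, n_flows, rng):
    x = random_on_manifold(spec, rng)
    v = mf.tangent_project(spec, x, rng.standard_normal(spec.ambient_dim))
    for _ in range(n_flows):
        r = mf.geodesic_flow(spec, x, v, 0.01)
        x, v = r.x_end, r.v_end
    assert mf.constraint_residual(spec, x) <= 1e-8


# ---------------------------------------------------------------------------
# RATTLE oracle for the Stiefel matrix-exponential flow


def rattle_free_flow(X, V, t, h=1e-5):
    """Constrained symplectic integration of free motion on the Stiefel manifold.

    Independent check of the closed-form geodesic: leapfrog with symmetric
    Lagrange multipliers enforcing X'X = I (position) and tangency (velocity).
    """
    p = X.shape[1]
    eye = np.eye(p)
    n_steps = int(round(t / h))
    for _ in range(n_steps):
        M = np.zeros((p, p))
        for _ in range(60):
            Vh = V + X @ M
            X1 = X + h * Vh
            R = X1.T @ X1 - eye
            if np.max(np.abs(R)) < 1e-15:
                break
            M = M - R / (2.0 * h)
        Vh = V + X @ M
        X1 = X + h * Vh
        sym = (X1.T @ Vh + Vh.T @ X1) / 2.0
        V = Vh - X1 @ sym
        X = X1
    return X, V


@pytest.mark.parametrize("d,p", [(3, 1), (3, 2), (4, 2), (5, 2)])
def test_stiefel_flow_matches_rattle_oracle(d, p, rng):
    spec = mf.stiefel(d, p)
    x = random_on_manifold(spec, rng)
    v = mf.tangent_project(spec, x, rng.standard_normal(d * p))
    t = 0.2
    closed = mf.geodesic_flow(spec, x, v, t)
    Xr, Vr = rattle_free_flow(
        x.reshape(d, p, order="F"), v.reshape(d, p, order="F"), t
    )
    np.testing.assert_allclose(
        closed.x_end, np.ravel(Xr, order="F"), atol=1e-6
    )
    np.testing.assert_allclose(
        closed.v_end, np.ravel(Vr, order="F"), atol=1e-6
    )


# ---------------------------------------------------------------------------
# reflecting simplex flow


def test_reflect_flow_interior_straight_line():
    spec = mf.simplex_plane(3)
    th = np.array([0.3, 0.3, 0.4])
    v = np.array([0.1, -0.05, -0.05])
    r = mf.reflect_flow_simplex(spec, th, v, 0.5)
    np.testing.assert_allclose(r.x_end, th + 0.5 * v, atol=1e-14)
    assert r.n_reflections == 0


def test_reflect_flow_single_bounce_segment():
    """1-D billiard on the d=2 simplex: one wall hit reverses the velocity."""
    spec = mf.simplex_plane(2)
    th = np.array([0.1, 0.9])
    v = np.array([-0.2, 0.2])
    r = mf.reflect_flow_simplex(spec, th, v, 1.0)
    assert r.n_reflections == 1
    np.testing.assert_allclose(r.v_end, [0.2, -0.2], atol=1e-12)
    assert abs(np.linalg.norm(r.v_end) - np.linalg.norm(v)) < 1e-12
    # 0.5 time units to the wall, 0.5 back
    np.testing.assert_allclose(r.x_end, [0.1, 0.9], atol=1e-12)


@given(st.integers(0, 2**31 - 1))
def test_reflect_flow_preserves_invariants(seed):
    """Long reflected paths keep speed, the plane constraint, and positivity."""
    rng = np.random.default_rng(seed)
    d = int(rng.integers(2, 6))
    spec = mf.simplex_plane(d)
    th = rng.dirichlet(np.ones(d))
    v = rng.standard_normal(d)
    v -= v.mean()
    r = mf.reflect_flow_simplex(spec, th, v, float(rng.uniform(0.5, 5.0)))
    assert abs(np.linalg.norm(r.v_end) - np.linalg.norm(v)) <= 1e-9 * (
        1 + np.linalg.norm(v)
    )
    assert abs(np.sum(r.x_end) - 1.0) < 1e-10
    assert np.min(r.x_end) >= 0.0
    assert abs(np.sum(r.v_end)) < 1e-9


# ---------------------------------------------------------------------------
# tangent sampling


def test_sample_tangent_orthogonal_at_basis_point(rng):
    spec = mf.sphere(4)
    x = np.array([1.0, 0, 0, 0])
    for _ in range(20):
        v = mf.sample_tangent(spec, x, rng)
        assert abs(v[0]) < 1e-14


@pytest.mark.parametrize(
    "spec", [mf.sphere(5), mf.stiefel(6, 3), mf.simplex_plane(4)],
    ids=lambda s: s.kind,
)
def test_sample_tangent_moments(spec, rng):
    """Mean zero; E||v||^2 equals the intrinsic dimension (projector trace)."""
    n = 20_000
    x = random_on_manifold(spec, rng)
    draws = np.array([mf.sample_tangent(spec, x, rng) for _ in range(n)])
    se = 1.0 / np.sqrt(n)
    assert np.max(np.abs(draws.mean(axis=0))) < 3.5 * se
    sq = np.sum(draws**2, axis=1)
    se_sq = sq.std(ddof=1) / np.sqrt(n)
    assert abs(sq.mean() - spec.intrinsic_dim) < 3 * se_sq


# ---------------------------------------------------------------------------
# spec JSON round-trip


@pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.kind + str(s.ambient_dim))
def test_spec_json_roundtrip(spec):
    assert mf.spec_from_json(mf.spec_to_json(spec)) == spec
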