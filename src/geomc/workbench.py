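"""Synthetic data generators, experiment presets, and file I/O.

Everything needed to exercise the sampler end to end without external data:
a generative network eigenmodel (draw an orthonormal frame uniformly, then
Bernoulli edges through the probit link), a team-competition match
generator, named presets for the illustrative experiments (bimodal
Bingham--von Mises--Fisher chains with and without parallel tempering, and
a small-network eigenmodel recovery run), and plain-text round-trip I/O for
samples, configs, edge lists and match tables.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from . import manifolds as mf
from .manifolds import ManifoldSpec, spec_from_json, spec_to_json
from .sampler import HMCConfig
from .targets import EigenmodelData, EigenmodelState, MatchData
from .tempering import TemperLadder

__all__ = [
    "ExperimentPreset",
    "gen_eigenmodel_network",
    "gen_matches",
    "random_point",
    "preset",
    "preset_names",
    "write_samples",
    "read_samples",
    "write_config",
    "read_config",
    "write_edges",
    "read_edges",
    "write_matches",
    "read_matches",
]


# ---------------------------------------------------------------------------
# Generators


def random_point(spec: ManifoldSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw a point uniformly (Hausdorff measure) on sphere/Stiefel manifolds.

    Sphere: normalized Gaussian. Stiefel: QR of a Gaussian matrix with the
    sign of the R diagonal fixed, which makes the Q factor Haar-uniform.
    Euclidean components get standard-normal draws; the simplex plane gets
    the barycentre plus a tangent Gaussian perturbation clipped to stay
    nonnegative (a convenient interior starting point, not a uniform draw).
    """
    if spec.kind == "sphere":
        z = rng.standard_normal(spec.ambient_dim)
        return z / np.linalg.norm(z)
    if spec.kind == "stiefel":
        d, p = spec.matrix_shape
        Z = rng.standard_normal((d, p))
        Q, R = np.linalg.qr(Z)
        Q = Q * np.sign(np.diag(R))
        return np.ravel(Q, order="F")
    if spec.kind == "euclidean":
        return rng.standard_normal(spec.ambient_dim)
    if spec.kind == "simplex_plane":
        d = spec.ambient_dim
        theta = np.full(d, 1.0 / d)
        z = rng.standard_normal(d)
        z -= z.mean()
        theta = theta + 0.1 / d * z
        theta = np.maximum(theta, 1e-6)
        return theta / theta.sum()
    if spec.kind == "product":
        return np.concatenate(
            [random_point(c, rng) for c in spec.components]
        )
    raise ValueError(f"unknown manifold kind {spec.kind!r}")


def gen_eigenmodel_network(
    m: int,
    p: int,
    lambda_diag: Sequence[float],
    offset: float,
    seed: int,
) -> tuple[EigenmodelData, EigenmodelState]:
    """Generate a binary network from the probit eigenmodel.

    ``U`` is drawn uniformly on the Stiefel manifold, then each unordered
    pair gets an edge with probability ``Phi(offset + u_i' Lambda u_j)``.
    Returns the network together with the generating state.
    """
    lam = np.asarray(lambda_diag, dtype=float)
    if not (1 <= p < m) or lam.size != p:
        raise ValueError("need m > p >= 1 and len(lambda_diag) == p")
    rng = np.random.default_rng(seed)
    U = random_point(mf.stiefel(m, p), rng).reshape(m, p, order="F")
    eta = offset + (U * lam) @ U.T
    probs = ndtr(eta)
    upper = rng.uniform(size=(m, m))
    y = np.zeros((m, m))
    iu = np.triu_indices(m, 1)
    y[iu] = (upper[iu] < probs[iu]).astype(float)
    y = y + y.T
    return EigenmodelData(m, y), EigenmodelState(U, lam, float(offset))


def eigenmodel_init(data: EigenmodelData, p: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """Neutral starting point for the eigenmodel posterior.

    A Haar-random frame with ``Lambda = 0`` and the offset at the probit of
    the observed edge density. Starting with zero eigenvalues keeps every
    linear predictor small, so no pair begins deep in the wrong probit tail;
    such mismatched pairs make the log-posterior extremely stiff and stall
    the integrator during warm-up.
    """
    from scipy.special import ndtri

    m = data.m
    dens = float(data.y.sum()) / (m * (m - 1))
    dens = min(max(dens, 1.0 / (m * m)), 1.0 - 1.0 / (m * m))
    U0 = random_point(mf.stiefel(m, p), rng)
    return np.concatenate([U0, np.zeros(p), [ndtri(dens)]])


def gen_matches(
    n_players: int,
    n_matches: int,
    p_true: Sequence[float],
    team_size: int,
    seed: int,
) -> MatchData:
    """Generate team matches with the team-sum-ratio win probability.

    Teams are disjoint uniform draws of ``team_size`` players each; team A
    wins with probability ``sum_A p / (sum_A p + sum_B p)``.
    """
    p = np.asarray(p_true, dtype=float)
    if p.size != n_players or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p_true must be a simplex point of length n_players")
    if 2 * team_size > n_players:
        raise ValueError("2 * team_size must not exceed n_players")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_matches):
        players = rng.choice(n_players, size=2 * team_size, replace=False)
        ta = tuple(int(i) for i in players[:team_size])
        tb = tuple(int(i) for i in players[team_size:])
        sa, sb = float(np.sum(p[list(ta)])), float(np.sum(p[list(tb)]))
        win = "a" if rng.uniform() < sa / (sa + sb) else "b"
        records.append((ta, tb, win))
    return MatchData(tuple(records), n_players)


# ---------------------------------------------------------------------------
# Presets


@dataclass
class ExperimentPreset:
    """A named, fully specified experiment configuration."""

    name: str
    spec: ManifoldSpec
    target_params: dict
    config: HMCConfig
    ladder: TemperLadder | None = None
    designated_coordinate: int | None = None
    expected_properties: tuple[str, ...] = ()

    def to_json(self) -> dict:
        obj = {
            "name": self.name,
            "manifold": spec_to_json(self.spec),
            "target": self.target_params,
            "config": {
                "epsilon": list(np.atleast_1d(self.config.epsilon).astype(float)),
                "n_steps": self.config.n_steps,
                "n_iters": self.config.n_iters,
                "seed": self.config.seed,
                "renormalize": self.config.renormalize,
            },
            "expected_properties": list(self.expected_properties),
        }
        if self.ladder is not None:
            obj["ladder"] = {
                "rhos": list(self.ladder.rhos),
                "n_exchanges": self.ladder.n_exchanges,
            }
        if self.designated_coordinate is not None:
            obj["designated_coordinate"] = self.designated_coordinate
        return obj

    @classmethod
    def from_json(cls, obj: dict | str) -> "ExperimentPreset":
        if isinstance(obj, str):
            obj = json.loads(obj)
        cfg = obj["config"]
        eps = cfg["epsilon"]
        epsilon = float(eps[0]) if len(eps) == 1 else tuple(float(e) for e in eps)
        ladder = None
        if "ladder" in obj:
            ladder = TemperLadder(
                tuple(obj["ladder"]["rhos"]), int(obj["ladder"]["n_exchanges"])
            )
        return cls(
            name=obj["name"],
            spec=spec_from_json(obj["manifold"]),
            target_params=obj["target"],
            config=HMCConfig(
                epsilon=epsilon,
                n_steps=int(cfg["n_steps"]),
                n_iters=int(cfg["n_iters"]),
                seed=int(cfg["seed"]),
                renormalize=bool(cfg["renormalize"]),
            ),
            ladder=ladder,
            designated_coordinate=obj.get("designated_coordinate"),
            expected_properties=tuple(obj.get("expected_properties", ())),
        )


_BIMODAL_A = [-20.0, -10.0, 0.0, 10.0, 20.0]


def _bvmf_preset(name: str, c1: float, with_pt: bool, n_iters: int) -> ExperimentPreset:
    target = {
        "family": "bvmf",
        "c": [c1, 0.0, 0.0, 0.0, 0.0],
        "A": np.diag(_BIMODAL_A).tolist(),
    }
    ladder = TemperLadder(tuple(np.round(np.arange(1, 11) * 0.1, 10)), 10) if with_pt else None
    props = ("x5_sign_flips>=1",) if with_pt else ("x5_sign_flips==0",)
    return ExperimentPreset(
        name=name,
        spec=mf.sphere(5),
        target_params=target,
        config=HMCConfig(epsilon=0.01, n_steps=20, n_iters=n_iters, seed=7),
        ladder=ladder,
        designated_coordinate=4,
        expected_properties=props,
    )


def _eigenmodel_preset() -> ExperimentPreset:
    m, p = 30, 2
    target = {
        "family": "eigenmodel",
        "m": m,
        "p": p,
        "true_lambda": [10.0, -6.0],
        "true_offset": -0.5,
        "gen_seed": 20,
    }
    return ExperimentPreset(
        name="eigenmodel-small",
        spec=mf.product(mf.stiefel(m, p), mf.euclidean(p), mf.euclidean(1)),
        target_params=target,
        # per-component step sizes: frame, eigenvalues, offset
        config=HMCConfig(epsilon=(0.004, 0.04, 0.04), n_steps=10, n_iters=5000, seed=11),
        ladder=TemperLadder((0.25, 0.5, 1.0), 10),
        expected_properties=(
            "abs_lambda_in_95ci",
            "reconstruction_correlation>=0.8",
        ),
    )


_PRESETS = {
    "fig4-bimodal": lambda: _bvmf_preset("fig4-bimodal", 0.0, False, 200),
    "fig4-c20": lambda: _bvmf_preset("fig4-c20", 20.0, False, 200),
    "fig4-c40": lambda: _bvmf_preset("fig4-c40", 40.0, False, 200),
    "fig5-pt": lambda: _bvmf_preset("fig5-pt", 0.0, True, 200),
    "eigenmodel-small": _eigenmodel_preset,
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> ExperimentPreset:
    """Look up a named experiment preset.

    ``fig4-*``: 5-sphere Bingham--von Mises--Fisher chains,
    ``A = diag(-20, -10, 0, 10, 20)``, ``c = (c1, 0, 0, 0, 0)``,
    ``eps = 0.01``, ``T = 20``, 200 iterations; at ``c1 = 0`` the target is
    bimodal along the fifth axis and a single chain stays in one mode.
    ``fig5-pt`` adds the tempering ladder ``rho = 0.1, ..., 1.0`` with 10
    random adjacent exchanges per sweep. ``eigenmodel-small`` is a
    parameter-recovery run of the network eigenmodel at ``m = 30, p = 2``.
    """
    if name not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        )
    return _PRESETS[name]()


# ---------------------------------------------------------------------------
# I/O (plain-text, full double precision)


def write_samples(path: str | Path, samples: np.ndarray) -> None:
    """Write a sample matrix as CSV, one row per sample, 17 significant digits."""
    np.savetxt(path, np.atleast_2d(samples), delimiter=",", fmt="%.17g")


def read_samples(path: str | Path) -> np.ndarray:
    try:
        return np.atleast_2d(np.loadtxt(path, delimiter=",", ndmin=2))
    except ValueError as e:
        raise ValueError(f"malformed sample CSV {path}: {e}") from e


def write_config(path: str | Path, obj: dict) -> None:
    """Write a config dict as JSON (or YAML if the suffix says so)."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=2))


def read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    try:
        return json.loads(text)
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed config {path} at line {e.lineno}: {e.msg}") from e


def write_edges(path: str | Path, data: EigenmodelData) -> None:
    """Write a network as a 2-column edge-list CSV with a node-count header."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# nodes", data.m])
        w.writerow(["i", "j"])
        for i, j in data.edges():
            w.writerow([i, j])


def read_edges(path: str | Path) -> EigenmodelData:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    try:
        m = int(rows[0][1])
        edges = [(int(r[0]), int(r[1])) for r in rows[2:] if r]
    except (IndexError, ValueError) as e:
        bad = len(rows)
        raise ValueError(f"malformed edge list {path} near line {bad}: {e}") from e
    return EigenmodelData.from_edges(m, edges)


def write_matches(path: str | Path, data: MatchData) -> None:
    """Write matches as CSV: semicolon-joined team indices plus the winner."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# players", data.n_players])
        w.writerow(["team_a", "team_b", "winner"])
        for ta, tb, win in data.records:
            w.writerow([";".join(map(str, ta)), ";".join(map(str, tb)), win])


def read_matches(path: str | Path) -> MatchData:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    try:
        n_players = int(rows[0][1])
        records = []
        for lineno, r in enumerate(rows[2:], start=3):
            if not r:
                continue
            ta = tuple(int(i) for i in r[0].split(";"))
            tb = tuple(int(i) for i in r[1].split(";"))
            records.append((ta, tb, r[2]))
    except (IndexError, ValueError) as e:
        raise ValueError(f"malformed match table {path}: {e}") from e
    return MatchData(tuple(records), n_players)
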