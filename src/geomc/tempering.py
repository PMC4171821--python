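"""Power tempering and parallel tempering around the geodesic HMC kernel.

A tempered target raises the density to a power ``rho`` in ``(0, 1]`` —
a linear scaling of the log-density and its gradient, so the geodesic
sampler applies unchanged. Parallel tempering runs one chain per rung of a
temperature ladder and stochastically exchanges states of adjacent rungs
with a Metropolis correction; the flattened rungs cross between modes that
trap the cold chain, and successful exchanges carry those crossings down to
the ``rho = 1`` rung, whose samples are the primary output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .manifolds import ManifoldSpec, check_point
from .sampler import ChainOutput, HMCConfig, hmc_transition
from .targets import TargetDensity

__all__ = ["TemperLadder", "tempered", "pt_sweep", "run_pt", "PTOutput"]


@dataclass(frozen=True)
class TemperLadder:
    """Ascending inverse temperatures ending at 1, plus exchanges per sweep."""

    rhos: tuple[float, ...]
    n_exchanges: int = 10

    def __post_init__(self):
        rhos = tuple(float(r) for r in self.rhos)
        object.__setattr__(self, "rhos", rhos)
        if not rhos or rhos[-1] != 1.0:
            raise ValueError("ladder must end at rho = 1.0")
        if any(r <= 0 for r in rhos):
            raise ValueError("all rhos must be positive")
        if any(b <= a for a, b in zip(rhos, rhos[1:])):
            raise ValueError("rhos must be strictly ascending")
        if self.n_exchanges < 0:
            raise ValueError("n_exchanges must be nonnegative")


def tempered(target: TargetDensity, rho: float) -> TargetDensity:
    """Target raised to the power ``rho``: log-density and gradient scaled."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    if rho == 1.0:
        return target
    return TargetDensity(
        logpdf_h=lambda x: rho * target.logpdf_h(x),
        grad_logpdf=lambda x: rho * np.asarray(target.grad_logpdf(x)),
        spec=target.spec,
        name=f"{target.name}^{rho:g}",
    )


def pt_sweep(
    states: list[np.ndarray],
    target: TargetDensity,
    spec: ManifoldSpec,
    config: HMCConfig,
    ladder: TemperLadder,
    rng: np.random.Generator,
    tempered_targets: Sequence[TargetDensity] | None = None,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One parallel-tempering sweep.

    Each rung advances by one geodesic-HMC transition against its tempered
    target (sequentially, for bit reproducibility), then ``n_exchanges``
    uniformly random adjacent pairs are proposed for a state swap, accepted
    with probability
    ``min(1, exp[(rho_i - rho_{i+1}) (log pi(x_{i+1}) - log pi(x_i))])``.

    Returns ``(states, accepted, delta_h, swap_attempts, swap_accepts)``
    where the swap tallies are per adjacent pair.
    """
    rhos = ladder.rhos
    if len(states) != len(rhos):
        raise ValueError("one state per ladder rung required")
    if tempered_targets is None:
        tempered_targets = [tempered(target, r) for r in rhos]
    accepted = np.zeros(len(rhos), dtype=bool)
    delta_h = np.full(len(rhos), np.nan)
    new_states = list(states)
    for i, tt in enumerate(tempered_targets):
        new_states[i], accepted[i], delta_h[i], _ = hmc_transition(
            tt, spec, new_states[i], config, rng
        )
    n_pairs = len(rhos) - 1
    attempts = np.zeros(max(n_pairs, 1), dtype=int)[:n_pairs]
    accepts = np.zeros(max(n_pairs, 1), dtype=int)[:n_pairs]
    if n_pairs > 0 and ladder.n_exchanges > 0:
        base_lp = [target.logpdf_h(s) for s in new_states]
        for _ in range(ladder.n_exchanges):
            i = int(rng.integers(n_pairs))
            attempts[i] += 1
            log_alpha = (rhos[i] - rhos[i + 1]) * (base_lp[i + 1] - base_lp[i])
            if np.log(rng.uniform()) < log_alpha:
                new_states[i], new_states[i + 1] = new_states[i + 1], new_states[i]
                base_lp[i], base_lp[i + 1] = base_lp[i + 1], base_lp[i]
                accepts[i] += 1
    return new_states, accepted, delta_h, attempts, accepts


@dataclass
class PTOutput:
    """Per-rung chain outputs plus exchange statistics."""

    rungs: list[ChainOutput]
    ladder: TemperLadder
    swap_attempts: np.ndarray  # per adjacent pair
    swap_accepts: np.ndarray

    @property
    def primary(self) -> ChainOutput:
        """The ``rho = 1`` rung (the actual target's chain)."""
        return self.rungs[-1]

    @property
    def swap_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.swap_attempts > 0, self.swap_accepts / self.swap_attempts, np.nan
            )


def run_pt(
    target: TargetDensity,
    spec: ManifoldSpec,
    initial_states: Sequence[np.ndarray],
    config: HMCConfig,
    ladder: TemperLadder,
    rng: np.random.Generator | None = None,
) -> PTOutput:
    """Run ``config.n_iters`` parallel-tempering sweeps.

    With a single-rung ladder and zero pairs to exchange, the random-draw
    sequence is identical to :func:`geomc.sampler.run_chain`, so the two are
    seed-for-seed equivalent in that degenerate case.
    """
    rhos = ladder.rhos
    states = [check_point(spec, np.asarray(s, dtype=float)) for s in initial_states]
    if len(states) != len(rhos):
        raise ValueError("one initial state per ladder rung required")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tempered_targets = [tempered(target, r) for r in rhos]
    n = spec.ambient_dim
    n_iters = config.n_iters
    samples = [np.empty((n_iters, n)) for _ in rhos]
    accepted = np.zeros((n_iters, len(rhos)), dtype=bool)
    delta_h = np.empty((n_iters, len(rhos)))
    n_pairs = max(len(rhos) - 1, 0)
    attempts = np.zeros(n_pairs, dtype=int)
    accepts = np.zeros(n_pairs, dtype=int)
    for it in range(n_iters):
        states, acc, dh, att, sw = pt_sweep(
            states, target, spec, config, ladder, rng, tempered_targets
        )
        for k, s in enumerate(states):
            samples[k][it] = s
        accepted[it] = acc
        delta_h[it] = dh
        attempts += att
        accepts += sw
    rungs = [
        ChainOutput(
            samples[k], accepted[:, k], delta_h[:, k],
            np.zeros(n_iters, dtype=int), config, config.seed,
        )
        for k in range(len(rhos))
    ]
    return PTOutput(rungs, ladder, attempts, accepts)
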