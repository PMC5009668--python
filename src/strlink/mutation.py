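"""Stepwise STR mutation: exact per-generation simulator and the clipped
normal (Brownian) approximation used as belief-propagation edge potentials.

Branch times are expressed in units of Ne generations throughout the
package, so a branch of time ``t`` corresponds to ``Ne * t`` generations and
the Brownian variance ``Ne * mu_s * t`` equals the exact stepwise-model
displacement variance ``mu_s * generations``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MutationParams",
    "TransitionMatrix",
    "transition_prob",
    "build_transition_matrix",
    "transition_kernel",
    "stepwise_simulate",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class MutationParams:
    """STR mutation rate (per generation) and diploid effective size."""

    mu_s: float
    Ne: float = 10400.0
    #: multiplier converting stored branch times into generations / Ne;
    #: 1.0 means times are in Ne-generation units.
    time_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_s <= 1.0):
            raise ValueError(f"mu_s must be in [0, 1], got {self.mu_s}")
        if self.Ne <= 0:
            raise ValueError(f"Ne must be positive, got {self.Ne}")

    def variance(self, t: float) -> float:
        """Brownian displacement variance accumulated over branch time ``t``."""
        return self.Ne * self.mu_s * t * self.time_scale


def transition_kernel(variance: float, max_delta: int) -> np.ndarray:
    """Vector ``k[d] = min(1, N(d; 0, variance))`` for ``d = 0..max_delta``.

    The edge potential depends only on ``|n_child - n_parent|``, so a full
    transition matrix is this kernel expanded over the state grid.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    d = np.arange(max_delta + 1, dtype=float)
    if variance == 0.0:
        k = np.zeros(max_delta + 1)
        k[0] = 1.0
        return k
    dens = np.exp(-0.5 * d * d / variance) / (_SQRT_2PI * np.sqrt(variance))
    return np.minimum(1.0, dens)


def transition_prob(n_u: int, n_v: int, t: float, params: MutationParams) -> float:
    """Potential for a repeat changing from ``n_v`` to ``n_u`` over branch
    time ``t`` (Ne-generation units).

    ``min(1, N(n_u; n_v, Ne * mu_s * t))``; the degenerate ``t = 0`` (or
    ``mu_s = 0``) limit is the identity indicator.  Not normalized over
    ``n_u`` by design — message renormalization absorbs the scale.
    """
    if t < 0:
        raise ValueError(f"branch time must be non-negative, got {t}")
    var = params.variance(t)
    if var == 0.0:
        return 1.0 if n_u == n_v else 0.0
    dens = np.exp(-0.5 * (n_u - n_v) ** 2 / var) / (_SQRT_2PI * np.sqrt(var))
    return float(min(1.0, dens))


class TransitionMatrix:
    """Dense edge-potential matrix over a repeat-count grid.

    ``entries[i, j] = transition_prob(n_min + i, n_min + j, t)`` — rows index
    the child state, columns the parent state.  Symmetric Toeplitz, so it is
    stored via its first column (the |delta| kernel).
    """

    def __init__(self, t: float, params: MutationParams, n_min: int, n_max: int):
        if n_min > n_max:
            raise ValueError("n_min must be <= n_max")
        self.t = float(t)
        self.n_min = int(n_min)
        self.n_max = int(n_max)
        size = self.n_max - self.n_min + 1
        self.kernel = transition_kernel(params.variance(t), size - 1)
        idx = np.abs(np.arange(size)[:, None] - np.arange(size)[None, :])
        self.entries = self.kernel[idx]

    def __call__(self, n_u: int, n_v: int) -> float:
        return float(self.entries[n_u - self.n_min, n_v - self.n_min])


_matrix_cache: dict[tuple, TransitionMatrix] = {}


def build_transition_matrix(t: float, params: MutationParams,
                            n_min: int, n_max: int) -> TransitionMatrix:
    """Build (or fetch from cache) the transition matrix for a branch.

    Matrices are shared between branch times equal within 1e-12.
    """
    if t < 0:
        raise ValueError(f"branch time must be non-negative, got {t}")
    key = (round(t / 1e-12), params.mu_s, params.Ne, params.time_scale, n_min, n_max)
    cached = _matrix_cache.get(key)
    if cached is None:
        cached = TransitionMatrix(t, params, n_min, n_max)
        if len(_matrix_cache) > 4096:
            _matrix_cache.clear()
        _matrix_cache[key] = cached
    return cached


def stepwise_simulate(n0: int, generations: int, mu_s: float,
                      rng: np.random.Generator, floor: int = 1) -> int:
    """Exact stepwise-model evolution of a repeat count.

    Each generation mutates independently with probability ``mu_s``; a
    mutation moves the count by +/-1 with equal probability.  The walk is
    reflected at ``floor`` so the locus is never erased.
    """
    if generations < 0:
        raise ValueError("generations must be non-negative")
    if not (0.0 <= mu_s <= 1.0):
        raise ValueError("mu_s must be in [0, 1]")
    n_events = rng.binomial(generations, mu_s) if mu_s > 0 else 0
    if n_events == 0:
        return int(n0)
    n = int(n0)
    if n > floor + n_events:
        # the walk cannot reach the floor: skip the per-event loop
        k_up = int(rng.binomial(n_events, 0.5))
        return n + 2 * k_up - n_events
    steps = rng.integers(0, 2, size=n_events) * 2 - 1
    for step in steps:
        n += int(step)
        if n < floor:
            n = 2 * floor - n
    return n
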