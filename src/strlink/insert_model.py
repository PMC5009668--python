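"""Per-individual insert-size likelihood model for STR repeat numbers.

An aligned read pair spanning an STR locus yields an inferred insert size
``l = e - s`` (reverse-read end minus forward-read start, reference
coordinates).  If the sample carries ``n`` repeat units where the reference
carries ``n_r``, the true fragment length is ``l + u*(n - n_r)``, so the
likelihood of an observation under repeat count ``n`` is the insert-size
distribution evaluated at the shifted length, normalized over the lengths
that would have produced a usable (spanning) pair from the same start
position.  A diploid genotype is scored by an equal-weight two-component
mixture over the two haplotypes, and estimated by exhaustive grid search.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "STRRegion",
    "InsertObservation",
    "InsertSizeDistribution",
    "NormalizationTable",
    "DiploidCall",
    "insert_likelihood",
    "normalization_naive",
    "build_normalization_table",
    "diploid_likelihood",
    "observation_likelihood_matrix",
    "basic_model_estimate",
]

#: floor applied to per-observation mixture likelihoods before taking logs,
#: so a single impossible observation does not poison the whole grid.
LIKELIHOOD_FLOOR = 1e-300


class InvalidObservationError(ValueError):
    """Raised when an observation cannot have been a spanning pair."""


class InconsistentNormalizationError(ArithmeticError):
    """Raised when a nonzero numerator meets a zero normalization factor."""


class NoSpanningPairsError(ValueError):
    """Raised when an estimate is requested with no observations."""


@dataclass(frozen=True)
class STRRegion:
    """A short-tandem-repeat locus on the reference genome.

    Coordinates are 1-based inclusive: the repeat tract occupies
    ``[start, end]``, the unit is ``unit`` bp long and the reference carries
    ``ref_repeat`` copies.
    """

    chrom: str
    start: int  # s_m
    end: int  # e_m, inclusive
    unit: int  # u
    ref_repeat: int  # n_r
    id: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region end {self.end} < start {self.start}")
        if self.unit < 1:
            raise ValueError(f"repeat unit length must be >= 1, got {self.unit}")
        span = self.end - self.start + 1
        if abs(self.unit * self.ref_repeat - span) > self.unit:
            warnings.warn(
                f"region {self.id or self.chrom}: unit*ref_repeat = "
                f"{self.unit * self.ref_repeat} differs from span {span} by more "
                f"than one unit",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class InsertObservation:
    """One spanning read pair: forward-read start and reverse-read end."""

    s: int
    e: int

    def __post_init__(self) -> None:
        if self.e <= self.s:
            raise ValueError(f"reverse end {self.e} must exceed forward start {self.s}")

    @property
    def l(self) -> int:
        """Inferred insert size in reference coordinates."""
        return self.e - self.s


class InsertSizeDistribution:
    """Discrete insert-size pmf over lengths ``1..K`` (zero elsewhere)."""

    def __init__(self, pmf: dict[int, float] | np.ndarray, K: int = 2000):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K = int(K)
        p = np.zeros(self.K + 1)  # index = length in bp; p[0] unused
        if isinstance(pmf, dict):
            for length, prob in pmf.items():
                if prob < 0:
                    raise ValueError(f"negative probability at length {length}")
                if 1 <= length <= self.K:
                    p[length] = prob
                elif prob > 0:
                    raise ValueError(f"nonzero probability at out-of-range length {length}")
        else:
            arr = np.asarray(pmf, dtype=float)
            if arr.ndim != 1 or arr.shape[0] != self.K + 1:
                raise ValueError("array pmf must have length K+1 (index = length)")
            if (arr < 0).any():
                raise ValueError("negative probability in pmf")
            p = arr.copy()
            p[0] = 0.0
        total = p.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pmf sums to {total}, expected 1 within 1e-9")
        self.p = p

    def __call__(self, l: int | np.ndarray) -> float | np.ndarray:
        """pmf at length ``l``; 0 outside ``1..K``."""
        l = np.asarray(l)
        inside = (l >= 1) & (l <= self.K)
        out = np.where(inside, self.p[np.clip(l, 0, self.K)], 0.0)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_lengths(cls, lengths: Iterable[int], K: int = 2000) -> "InsertSizeDistribution":
        """Empirical pmf from observed lengths (lengths > K are dropped)."""
        counts = np.zeros(K + 1)
        n_kept = 0
        for l in lengths:
            if 1 <= l <= K:
                counts[l] += 1
                n_kept += 1
        if n_kept == 0:
            raise ValueError("no usable lengths in 1..K")
        return cls(counts / counts.sum(), K=K)

    @classmethod
    def normal(cls, mean: float = 350.0, sd: float = 50.0, K: int = 2000) -> "InsertSizeDistribution":
        """Discretized normal pmf truncated to ``1..K``."""
        lengths = np.arange(K + 1)
        p = np.exp(-0.5 * ((lengths - mean) / sd) ** 2)
        p[0] = 0.0
        return cls(p / p.sum(), K=K)

    @classmethod
    def uniform(cls, low: int, high: int, K: int) -> "InsertSizeDistribution":
        """Uniform pmf on ``low..high`` inclusive (handy for toy examples)."""
        p = np.zeros(K + 1)
        p[low : high + 1] = 1.0 / (high - low + 1)
        return cls(p, K=K)


class NormalizationTable:
    """Cached normalization factors ``N(s, n)`` for the insert likelihood.

    ``N(s, n)`` sums the insert pmf over the fragment lengths that would have
    produced a spanning pair starting at ``s`` under repeat count ``n``.  The
    table covers ``s in [s_m - K, s_m - 1]`` and ``n in [n_min, n_max]``.
    """

    def __init__(self, region: STRRegion, F: InsertSizeDistribution,
                 n_min: int, n_max: int, values: np.ndarray):
        self.region = region
        self.F = F
        self.n_min = int(n_min)
        self.n_max = int(n_max)
        self.s_lo = region.start - F.K
        self.s_hi = region.start - 1
        self.values = values  # shape (K, n_max - n_min + 1)

    def __call__(self, s: int, n: int) -> float:
        if not (self.s_lo <= s <= self.s_hi):
            raise KeyError(f"s={s} outside table range [{self.s_lo}, {self.s_hi}]")
        if not (self.n_min <= n <= self.n_max):
            raise KeyError(f"n={n} outside table range [{self.n_min}, {self.n_max}]")
        return float(self.values[s - self.s_lo, n - self.n_min])

    def column(self, s: int) -> np.ndarray:
        """All ``N(s, n)`` for ``n_min..n_max`` as a vector."""
        if not (self.s_lo <= s <= self.s_hi):
            raise KeyError(f"s={s} outside table range [{self.s_lo}, {self.s_hi}]")
        return self.values[s - self.s_lo]


@dataclass(frozen=True)
class DiploidCall:
    """Repeat-number call for one individual, canonicalized ``n1 <= n2``."""

    n1: int
    n2: int
    loglik: float = field(default=float("nan"), compare=False)


def normalization_naive(s: int, n: int, region: STRRegion,
                        F: InsertSizeDistribution) -> float:
    """Direct summation oracle for ``N(s, n)``.

    Sums ``F(l + u*(n - n_r))`` for ``l`` from ``e_m - s + 1`` to
    ``K - u*(n - n_r)``; 0 when the range is empty.
    """
    shift = region.unit * (n - region.ref_repeat)
    lo = region.end - s + 1
    hi = F.K - shift
    if lo > hi:
        return 0.0
    total = 0.0
    for l in range(lo, hi + 1):
        total += F(l + shift)
    return total


def build_normalization_table(region: STRRegion, F: InsertSizeDistribution,
                              n_min: int, n_max: int) -> NormalizationTable:
    """Fill the whole ``N(s, n)`` table in O((n_max - n_min + 1) * K).

    Each column in ``s`` is a running prefix accumulation of pmf values:
    ``N(s+1, n) = N(s, n) + F(e_m - s + u*(n - n_r))``, anchored at the
    smallest ``s``.  Equivalently every cell is a suffix sum of the shifted
    pmf, which is what the vectorized cumulative sum below computes.
    """
    if n_min > n_max:
        raise ValueError("n_min must be <= n_max")
    K = F.K
    s_vals = np.arange(region.start - K, region.start)  # s_m - K .. s_m - 1
    n_vals = np.arange(n_min, n_max + 1)
    values = np.zeros((K, n_vals.size))
    # suffix sums of the pmf: S[a] = sum_{l' >= a} F(l'), a in 0..K+1
    suffix = np.zeros(K + 2)
    suffix[1 : K + 1] = np.cumsum(F.p[1:][::-1])[::-1]
    suffix[0] = suffix[1]
    for j, n in enumerate(n_vals):
        shift = region.unit * (n - region.ref_repeat)
        # N(s, n) = sum_{l' = e_m - s + 1 + shift}^{K} F(l')
        start_idx = region.end - s_vals + 1 + shift
        inside = start_idx <= K
        idx = np.clip(start_idx, 0, K + 1)
        values[inside, j] = suffix[idx[inside]]
    np.clip(values, 0.0, None, out=values)
    return NormalizationTable(region, F, n_min, n_max, values)


def insert_likelihood(l: int, s: int, n: int, region: STRRegion,
                      F: InsertSizeDistribution, table: NormalizationTable) -> float:
    """Probability of observing inferred insert size ``l`` from start ``s``
    under repeat count ``n``.

    Zero outside ``e_m - s < l <= K - u*(n - n_r)``; otherwise the shifted
    pmf value divided by ``N(s, n)``.
    """
    if s >= region.start:
        raise InvalidObservationError(
            f"forward-read start {s} is not before the region start {region.start}"
        )
    shift = region.unit * (n - region.ref_repeat)
    if not (l > region.end - s and l <= F.K - shift):
        return 0.0
    numerator = F(l + shift)
    denom = table(s, n)
    if denom == 0.0:
        if numerator > 0.0:
            raise InconsistentNormalizationError(
                f"N({s}, {n}) = 0 but F({l + shift}) = {numerator}"
            )
        return 0.0
    return float(numerator) / denom


def observation_likelihood_matrix(obs: Sequence[InsertObservation], region: STRRegion,
                                  F: InsertSizeDistribution,
                                  table: NormalizationTable) -> np.ndarray:
    """Matrix ``P[d, j] = P(l_d | n_j)`` over the table's repeat grid."""
    n_vals = np.arange(table.n_min, table.n_max + 1)
    shifts = region.unit * (n_vals - region.ref_repeat)
    P = np.zeros((len(obs), n_vals.size))
    for d, ob in enumerate(obs):
        if ob.s >= region.start:
            raise InvalidObservationError(
                f"forward-read start {ob.s} is not before the region start {region.start}"
            )
        l = ob.l
        valid = (l > region.end - ob.s) & (l <= F.K - shifts)
        if not valid.any():
            continue
        denom = table.column(ob.s)
        num = np.asarray(F(l + shifts), dtype=float)
        ok = valid & (denom > 0)
        bad = valid & (denom == 0) & (num > 0)
        if bad.any():
            j = int(np.argmax(bad))
            raise InconsistentNormalizationError(
                f"N({ob.s}, {n_vals[j]}) = 0 but numerator is positive"
            )
        P[d, ok] = num[ok] / denom[ok]
    return P


def diploid_likelihood(obs: Sequence[InsertObservation], n1: int, n2: int,
                       region: STRRegion, F: InsertSizeDistribution,
                       table: NormalizationTable) -> float:
    """Log-likelihood of a diploid genotype ``(n1, n2)``.

    Each pair comes from either haplotype with equal probability, so each
    observation contributes ``log(0.5 * (P(l|n1) + P(l|n2)))``.  Symmetric in
    ``(n1, n2)``; empty observation lists score 0 with a warning.
    """
    if len(obs) == 0:
        warnings.warn("diploid_likelihood called with no observations", stacklevel=2)
        return 0.0
    total = 0.0
    for ob in obs:
        p1 = insert_likelihood(ob.l, ob.s, n1, region, F, table)
        p2 = insert_likelihood(ob.l, ob.s, n2, region, F, table)
        total += np.log(max(0.5 * (p1 + p2), LIKELIHOOD_FLOOR))
    return float(total)


def diploid_loglik_grid(obs: Sequence[InsertObservation], region: STRRegion,
                        F: InsertSizeDistribution,
                        table: NormalizationTable) -> np.ndarray:
    """Full grid ``L[j1, j2]`` of diploid log-likelihoods over the table's
    repeat range (symmetric)."""
    P = observation_likelihood_matrix(obs, region, F, table)
    mix = 0.5 * (P[:, :, None] + P[:, None, :])
    np.clip(mix, LIKELIHOOD_FLOOR, None, out=mix)
    return np.log(mix).sum(axis=0)


def basic_model_estimate(obs: Sequence[InsertObservation], region: STRRegion,
                         F: InsertSizeDistribution, n_min: int, n_max: int,
                         table: NormalizationTable | None = None) -> DiploidCall:
    """Exhaustive grid-search maximum-likelihood diploid call.

    Ties (exactly equal log-likelihood) are broken toward the reference —
    smallest ``|n1 - n_r| + |n2 - n_r|`` — then lexicographically, and the
    result is canonicalized to ``n1 <= n2``.
    """
    if n_min > n_max:
        raise ValueError("n_min must be <= n_max")
    if len(obs) == 0:
        raise NoSpanningPairsError("no spanning pairs for this individual")
    if table is None or table.n_min > n_min or table.n_max < n_max:
        table = build_normalization_table(region, F, n_min, n_max)
    L = diploid_loglik_grid(obs, region, F, table)
    n_vals = np.arange(table.n_min, table.n_max + 1)
    keep = (n_vals >= n_min) & (n_vals <= n_max)
    n_vals = n_vals[keep]
    L = L[np.ix_(keep, keep)]
    best: tuple | None = None
    best_val = -np.inf
    for j1, n1 in enumerate(n_vals):
        for j2 in range(j1, n_vals.size):
            n2 = n_vals[j2]
            val = L[j1, j2]
            if val > best_val:
                best_val = val
                best = (n1, n2)
            elif val == best_val and best is not None:
                key_new = (abs(n1 - region.ref_repeat) + abs(n2 - region.ref_repeat), n1, n2)
                key_old = (abs(best[0] - region.ref_repeat) + abs(best[1] - region.ref_repeat),
                           best[0], best[1])
                if key_new < key_old:
                    best = (n1, n2)
    assert best is not None
    return DiploidCall(int(best[0]), int(best[1]), float(best_val))
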