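"""STR mutation-rate selection by message agreement.

After loopy cycles, the cross-haplotype message into each haplotype (the
read-side evidence) and the normalized tree-aggregate message (the
genealogy-side evidence) should agree when the mutation rate is right.  The
score sums, over all haplotypes, the dot product of the two normalized
message vectors; it lies in ``[0, 2I]`` and is maximized over a candidate
rate grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .bp import BPState, build_diploid_factor, run_loopy
from .genealogy import TreeEnsemble
from .insert_model import (
    STRRegion,
    InsertSizeDistribution,
    build_normalization_table,
)
from .mutation import MutationParams

__all__ = ["RateScore", "rate_score", "select_rate", "REAL_DATA_RATE_GRID",
           "MULTIPLICATIVE_GRID"]

#: default candidate rates for real data
REAL_DATA_RATE_GRID = (0.0001, 0.0005, 0.001, 0.005, 0.01)
#: multipliers applied to a reference rate in the simulation protocol
MULTIPLICATIVE_GRID = (0.01, 0.1, 0.5, 0.75, 1.0, 1.2, 2.0, 5.0, 10.0, 100.0)


@dataclass(frozen=True)
class RateScore:
    mu_s: float
    score: float


def rate_score(state: BPState) -> float:
    """Message-agreement score of a state after loopy cycles.

    Sum over haplotypes of ``<normalized cross message, normalized tree
    aggregate>``; both message families are kept normalized by the updates.
    """
    return float((state.cross * state.agg).sum())


def select_rate(candidates: Sequence[float], obs_by_individual: dict,
                ensemble: TreeEnsemble, region: STRRegion,
                F: InsertSizeDistribution, params: MutationParams,
                n_min: int = 0, n_max: int = 40,
                loopy_cycles: int = 10) -> tuple[float, list[RateScore]]:
    """Score every candidate rate with fresh loopy runs; highest wins.

    Factors and the ensemble are shared across candidates; ties break
    toward the smaller rate.  Returns the winner and all scores.
    """
    if len(candidates) == 0:
        raise ValueError("candidate rate list must be non-empty")
    from .bp import _parse_leaf_labels  # local import to avoid cycle noise

    samples = _parse_leaf_labels(ensemble.trees[0].leaf_labels)
    table = build_normalization_table(region, F, n_min, n_max)
    factors = np.stack([
        build_diploid_factor(obs_by_individual.get(s, []), region, F, n_min, n_max, table)
        for s in samples
    ])
    scores: list[RateScore] = []
    base: BPState | None = None
    for mu in candidates:
        cand_params = replace(params, mu_s=float(mu))
        if base is None:
            base = state = BPState(factors, samples, ensemble, cand_params,
                                   n_min, n_max, region.ref_repeat)
        else:
            state = base.with_rate(cand_params)
        run_loopy(state, loopy_cycles)
        scores.append(RateScore(float(mu), rate_score(state)))
    best = max(scores, key=lambda rs: (rs.score, -rs.mu_s))
    return best.mu_s, scores
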