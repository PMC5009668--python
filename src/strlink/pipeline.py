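"""End-to-end simulation study and alignment-ingestion utilities.

The study mirrors the generative protocol used for benchmarking: draw a
coalescent tree, evolve flanking biallelic sites and STR repeat counts on
it, emit spanning read-pair observations directly from the insert-size
distribution (no read synthesis or alignment: under error-free flank
alignment the inferred insert size is exactly the true fragment length
minus ``u * (n_true - n_ref)``), then run the basic per-individual
estimator and the genealogy-coupled estimator, and evaluate RMSE with
haplotype-pairing minimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bp import RepeatCallSet, estimate_repeats
from .genealogy import (
    TRANSITION_RATE,
    TRANSVERSION_RATE,
    HaplotypePanel,
    TreeEnsemble,
    haplotype_labels,
    mutate_sites_on_tree,
    sample_trees_mcmc,
    shuffle_haplotypes,
    simulate_coalescent_tree,
    simulate_repeat_numbers,
)
from .insert_model import (
    DiploidCall,
    InsertObservation,
    InsertSizeDistribution,
    NoSpanningPairsError,
    STRRegion,
    basic_model_estimate,
    build_normalization_table,
)
from .mutation import MutationParams
from .rate_selection import MULTIPLICATIVE_GRID, select_rate

__all__ = [
    "DEFAULT_REGION",
    "SimulationConfig",
    "AlignedPairRecord",
    "EvaluationResult",
    "simulate_observations",
    "extract_spanning_pairs",
    "estimate_insert_distribution",
    "rmse",
    "run_basic_model",
    "simulate_truth",
    "run_simulation_study",
]

log = logging.getLogger(__name__)

#: TTTC repeat on GRCh37 chr7 used throughout the simulation study
DEFAULT_REGION = STRRegion("chr7", 127898719, 127898787, 4, 17, id="TTTC_chr7")


@dataclass
class SimulationConfig:
    """Settings of one simulation study."""

    I: int = 5
    coverage: float = 20.0
    read_len: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    base_error: float = 0.001  # recorded only; direct simulation bypasses reads
    mu_s: float = 2.73e-4
    Ne: float = 10400.0
    root_repeat: int = 25
    region: STRRegion = field(default_factory=lambda: DEFAULT_REGION)
    flank_bp: int = 1000
    replicates: int = 10
    seed: int = 0
    n_min: int = 0
    n_max: int = 40
    K: int = 2000
    transition_rate: float = TRANSITION_RATE
    transversion_rate: float = TRANSVERSION_RATE
    # genealogy sampling
    mcmc_burn_in: int = 50000
    mcmc_thin: int = 100
    n_trees: int = 100
    # rate selection (multipliers of the true rate); None disables selection
    rate_grid_multipliers: tuple[float, ...] | None = MULTIPLICATIVE_GRID
    methods: tuple[str, ...] = ("basic", "coalescent", "coalescent_shuffled")

    def __post_init__(self) -> None:
        if self.I < 1 or self.coverage < 0 or self.read_len < 1:
            raise ValueError("I, coverage and read_len must be positive")

    @property
    def samples(self) -> list[str]:
        return [f"s{i}" for i in range(self.I)]

    @property
    def params(self) -> MutationParams:
        return MutationParams(self.mu_s, self.Ne)


@dataclass(frozen=True)
class AlignedPairRecord:
    """One aligned read pair, reduced to what the spanning filters need."""

    sample_id: str
    fwd_start: int  # 1-based leftmost position of the forward read
    rev_end: int  # 1-based rightmost position of the reverse read
    fwd_strand: str = "+"
    rev_strand: str = "-"
    tlen: int = 0

    def __post_init__(self) -> None:
        if self.fwd_start < 1 or self.rev_end < 1:
            raise ValueError("positions must be positive")


@dataclass
class EvaluationResult:
    """RMSE per replicate plus per-individual squared errors."""

    rmses: list[float] = field(default_factory=list)
    per_individual: list[dict[str, float]] = field(default_factory=list)

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmses))

    def extend(self, other: "EvaluationResult") -> None:
        self.rmses.extend(other.rmses)
        self.per_individual.extend(other.per_individual)


def simulate_observations(true_diploid_repeats: dict[str, tuple[int, int]],
                          config: SimulationConfig,
                          rng: np.random.Generator) -> dict[str, list[InsertObservation]]:
    """Emit spanning read-pair observations for each individual.

    Fragment starts fall on ``[s_m - K, s_m)`` as a Poisson process whose
    density matches the configured read coverage split over the two
    haplotypes; fragment lengths are rounded normal draws.  A fragment is
    kept only if it spans the haplotype's true repeat tract, and its
    reported insert size is the true length shifted by
    ``-u * (n_true - n_ref)`` (the alignment-inferred value).
    """
    region = config.region
    u, n_r = region.unit, region.ref_repeat
    window = config.K
    # diploid coverage c => per-haplotype fragment density c / (4 * read_len)
    density = config.coverage / (4.0 * config.read_len)
    out: dict[str, list[InsertObservation]] = {}
    for sample, alleles in true_diploid_repeats.items():
        obs: list[InsertObservation] = []
        for n_true in alleles:
            if not (1 <= n_true):
                raise ValueError(f"true repeat count must be >= 1, got {n_true}")
            allele_end = region.end + u * (n_true - n_r)
            count = rng.poisson(density * window)
            if count == 0:
                continue
            starts = rng.integers(region.start - window, region.start, size=count)
            lengths = np.rint(rng.normal(config.insert_mean, config.insert_sd,
                                         size=count)).astype(np.int64)
            keep = (lengths >= 1) & (starts + lengths > allele_end)
            for s, lt in zip(starts[keep], lengths[keep]):
                l_reported = int(lt) - u * (n_true - n_r)
                obs.append(InsertObservation(int(s), int(s) + l_reported))
        out[sample] = obs
    return out


def extract_spanning_pairs(records: Iterable[AlignedPairRecord],
                           region: STRRegion) -> list[InsertObservation]:
    """Keep concordant pairs whose forward read starts strictly before the
    region and whose reverse read ends strictly after it."""
    obs = []
    for rec in records:
        concordant = (rec.fwd_strand == "+" and rec.rev_strand == "-"
                      and rec.rev_end > rec.fwd_start)
        if concordant and rec.fwd_start < region.start and rec.rev_end > region.end:
            obs.append(InsertObservation(rec.fwd_start, rec.rev_end))
    return obs


def estimate_insert_distribution(lengths: Sequence[int], K: int = 2000,
                                 min_lengths: int = 100,
                                 smooth_window: int = 1) -> InsertSizeDistribution:
    """Empirical insert-size pmf from observed lengths.

    Lengths above ``K`` are dropped and the mass renormalized; an optional
    centered moving average (odd ``smooth_window`` > 1) smooths the pmf.
    """
    if len(lengths) < min_lengths:
        raise ValueError(
            f"only {len(lengths)} lengths (< {min_lengths}); consider the "
            f"parametric normal fallback (InsertSizeDistribution.normal)"
        )
    dist = InsertSizeDistribution.from_lengths(lengths, K=K)
    if smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        kernel = np.ones(smooth_window) / smooth_window
        p = np.convolve(dist.p, kernel, mode="same")
        p[0] = 0.0
        dist = InsertSizeDistribution(p / p.sum(), K=K)
    return dist


def rmse(true_calls: dict[str, tuple[int, int]],
         est_calls: dict[str, tuple[int, int]]) -> EvaluationResult:
    """Diploid RMSE with per-individual haplotype-pairing minimization.

    Each individual contributes ``min(matched, swapped)`` squared error over
    its two alleles; the result is invariant to label swaps on either side.
    """
    if set(true_calls) != set(est_calls):
        raise ValueError(
            f"individual sets differ: {sorted(set(true_calls) ^ set(est_calls))}"
        )
    sq: dict[str, float] = {}
    for sample, (t1, t2) in true_calls.items():
        e1, e2 = est_calls[sample]
        matched = (t1 - e1) ** 2 + (t2 - e2) ** 2
        swapped = (t1 - e2) ** 2 + (t2 - e1) ** 2
        sq[sample] = float(min(matched, swapped))
    value = float(np.sqrt(sum(sq.values()) / (2 * len(sq))))
    return EvaluationResult([value], [sq])


def run_basic_model(obs_by_individual: dict[str, list[InsertObservation]],
                    region: STRRegion, F: InsertSizeDistribution,
                    n_min: int, n_max: int, table=None) -> dict[str, tuple[int, int]]:
    """Grid-search call per individual; reference call when no pairs span."""
    if table is None:
        table = build_normalization_table(region, F, n_min, n_max)
    calls = {}
    for sample, obs in obs_by_individual.items():
        try:
            call: DiploidCall = basic_model_estimate(obs, region, F, n_min, n_max, table)
            calls[sample] = (call.n1, call.n2)
        except NoSpanningPairsError:
            calls[sample] = (region.ref_repeat, region.ref_repeat)
    return calls


def _coalescent_calls(obs: dict, panel: HaplotypePanel, config: SimulationConfig,
                      F: InsertSizeDistribution, rng: np.random.Generator,
                      table) -> tuple[dict[str, tuple[int, int]], float, TreeEnsemble]:
    """Sample an ensemble from the panel, pick a rate, decode."""
    params = config.params
    ensemble = sample_trees_mcmc(
        panel, params, n_samples=config.n_trees, burn_in=config.mcmc_burn_in,
        thin=config.mcmc_thin, rng=rng,
        site_rate=config.transition_rate + config.transversion_rate,
    )
    if config.rate_grid_multipliers:
        candidates = [m * config.mu_s for m in config.rate_grid_multipliers]
        mu, _ = select_rate(candidates, obs, ensemble, config.region, F, params,
                            config.n_min, config.n_max)
    else:
        mu = config.mu_s
    result: RepeatCallSet = estimate_repeats(
        obs, ensemble, config.region, F, MutationParams(mu, config.Ne),
        config.n_min, config.n_max, table=table,
    )
    return result.calls, mu, ensemble


def simulate_truth(config: SimulationConfig, rng: np.random.Generator):
    """One replicate of the generative protocol.

    Returns ``(tree, panel, truth)`` where truth maps samples to their two
    true repeat counts (haplotype order matching the panel rows).
    """
    labels = haplotype_labels(config.samples)
    params = config.params
    tree = simulate_coalescent_tree(2 * config.I, params, rng, leaf_labels=labels)
    region = config.region
    positions = np.concatenate([
        np.arange(region.start - config.flank_bp, region.start),
        np.arange(region.end + 1, region.end + config.flank_bp + 1),
    ])
    panel = mutate_sites_on_tree(tree, positions, config.transition_rate,
                                 config.transversion_rate, params, rng)
    assignment = simulate_repeat_numbers(tree, config.root_repeat, params, rng)
    leaf_vals = assignment.leaf_values()
    truth = {s: (leaf_vals[f"{s}_1"], leaf_vals[f"{s}_2"]) for s in config.samples}
    return tree, panel, truth


def run_simulation_study(config: SimulationConfig,
                         return_calls: bool = False) -> dict[str, EvaluationResult]:
    """Full benchmark: generate truth and observations, run the requested
    estimators, aggregate RMSE over replicates.

    Deterministic given ``config.seed``.  Methods: ``basic`` (independent
    grid search), ``coalescent`` (genealogy sampled from the true panel),
    ``coalescent_shuffled`` (panel rows randomly permuted first — the
    control that discards genealogical information).
    """
    results = {m: EvaluationResult() for m in config.methods}
    all_calls: list[dict] = []
    F = InsertSizeDistribution.normal(config.insert_mean, config.insert_sd, config.K)
    table = build_normalization_table(config.region, F, config.n_min, config.n_max)
    seeds = np.random.SeedSequence(config.seed).spawn(config.replicates)
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        log.info("replicate %d: seed state %s", r, ss)
        tree, panel, truth = simulate_truth(config, rng)
        obs = simulate_observations(truth, config, rng)
        calls_r: dict[str, dict] = {"truth": truth}
        if "basic" in config.methods:
            calls = run_basic_model(obs, config.region, F, config.n_min,
                                    config.n_max, table)
            results["basic"].extend(rmse(truth, calls))
            calls_r["basic"] = calls
        if "coalescent" in config.methods:
            calls, mu, _ = _coalescent_calls(obs, panel, config, F, rng, table)
            results["coalescent"].extend(rmse(truth, calls))
            calls_r["coalescent"] = calls
            log.info("replicate %d: selected rate %.3g (coalescent)", r, mu)
        if "coalescent_shuffled" in config.methods:
            shuffled = shuffle_haplotypes(panel, rng)
            calls, mu, _ = _coalescent_calls(obs, shuffled, config, F, rng, table)
            results["coalescent_shuffled"].extend(rmse(truth, calls))
            calls_r["coalescent_shuffled"] = calls
            log.info("replicate %d: selected rate %.3g (shuffled)", r, mu)
        all_calls.append(calls_r)
    if return_calls:
        return results, all_calls
    return results
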