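"""Multi-tree belief propagation for joint repeat-number estimation.

The factor graph couples one diploid insert-size factor per individual with
an ensemble of sampled genealogies.  Each haplotype is a leaf of every tree;
repeat states propagate along tree branches through clipped-normal edge
potentials, across the two haplotypes of an individual through the diploid
factor, and across trees by summing the (normalized) per-tree messages into
each leaf.  Decoding runs loopy (sum-product) cycles followed by
mixed-product cycles that maximize over the leaf states while still summing
over internal nodes and trees.

Message schedule, fixed and deterministic (one cycle):

1. cross-haplotype updates for all individuals (sample-label order; for
   each individual the message h1->h2 then h2->h1, both reading the
   tree-aggregate from the previous cycle);
2. per-tree upward sweeps: all leaf-to-parent messages, then internal nodes
   children-before-parents;
3. per-tree downward sweeps: internal nodes parents-before-children, the
   root using a flat parent message;
4. refresh of the per-leaf tree aggregates (per-tree messages are
   normalized before summation, then the sum is normalized).

Trees are processed in ensemble order; because sweeps on different trees
are independent, they are executed batched across the ensemble.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genealogy import TreeEnsemble
from .insert_model import (
    STRRegion,
    InsertSizeDistribution,
    NormalizationTable,
    build_normalization_table,
    diploid_loglik_grid,
)
from .mutation import MutationParams, transition_kernel

__all__ = [
    "BPState",
    "RepeatCallSet",
    "BPNumericalError",
    "build_diploid_factor",
    "update_leaf_to_parent",
    "update_internal",
    "update_cross_haplotype",
    "run_loopy",
    "run_mixed_product",
    "decode",
    "estimate_repeats",
    "brute_force_marginal_map",
    "config_objective",
]

FACTOR_FLOOR = 1e-300
_TIE_RTOL = 1e-12


class BPNumericalError(ArithmeticError):
    """A message became non-normalizable (all-zero, NaN or infinite)."""


class LeafSampleMismatchError(ValueError):
    """Ensemble leaves and observation sample ids do not line up."""


@dataclass
class RepeatCallSet:
    """Per-individual diploid repeat calls plus decoded belief vectors."""

    calls: dict[str, tuple[int, int]]
    beliefs: dict[str, np.ndarray] = field(default_factory=dict)
    n_min: int = 0
    n_max: int = 40
    selected_rate: float | None = None

    def as_array(self, samples: list[str]) -> np.ndarray:
        return np.array([self.calls[s] for s in samples], dtype=np.int64)


def build_diploid_factor(obs_i, region: STRRegion, F: InsertSizeDistribution,
                         n_min: int, n_max: int,
                         table: NormalizationTable | None = None) -> np.ndarray:
    """Unary diploid factor table over ``(n1, n2)``.

    ``exp`` of the diploid log-likelihood grid, rescaled to a maximum entry
    of 1 (constant scale is irrelevant to the argmax).  Individuals with no
    observations get an all-ones (uninformative) table.
    """
    S = n_max - n_min + 1
    if len(obs_i) == 0:
        return np.ones((S, S))
    if table is None:
        table = build_normalization_table(region, F, n_min, n_max)
    L = diploid_loglik_grid(obs_i, region, F, table)
    n_vals = np.arange(table.n_min, table.n_max + 1)
    keep = (n_vals >= n_min) & (n_vals <= n_max)
    L = L[np.ix_(keep, keep)]
    out = np.exp(L - L.max())
    return np.clip(out, FACTOR_FLOOR, None)


def _parse_leaf_labels(labels: list[str]) -> list[str]:
    """Sample ids from ``<sample>_1/<sample>_2`` leaf labels, sorted."""
    samples: dict[str, set[str]] = {}
    for lab in labels:
        if "_" not in lab or lab.rsplit("_", 1)[1] not in ("1", "2"):
            raise LeafSampleMismatchError(
                f"leaf label {lab!r} does not follow the '<sample>_1/_2' convention"
            )
        s, h = lab.rsplit("_", 1)
        samples.setdefault(s, set()).add(h)
    bad = [s for s, hs in samples.items() if hs != {"1", "2"}]
    if bad:
        raise LeafSampleMismatchError(f"samples missing one haplotype leaf: {sorted(bad)}")
    return sorted(samples)


class BPState:
    """All messages and cached tables for one belief-propagation problem.

    Parameters
    ----------
    factors:
        ``(I, S, S)`` symmetric diploid factor tables, one per sample in
        ``samples`` order.
    samples:
        Sample ids; haplotype ``h`` of sample ``i`` is global leaf
        ``2*i + h - 1`` with label ``"<sample>_h"``.
    ensemble:
        Sampled genealogies whose leaf labels must cover exactly the
        samples' haplotypes.
    """

    def __init__(self, factors: np.ndarray, samples: list[str],
                 ensemble: TreeEnsemble, params: MutationParams,
                 n_min: int, n_max: int, ref_repeat: int):
        self.n_min, self.n_max = int(n_min), int(n_max)
        self.S = self.n_max - self.n_min + 1
        self.n_vals = np.arange(self.n_min, self.n_max + 1)
        self.samples = list(samples)
        self.ref_repeat = int(ref_repeat)
        self.params = params
        self.ensemble = ensemble
        self.factors = np.asarray(factors, dtype=float)
        I = len(samples)
        if self.factors.shape != (I, self.S, self.S):
            raise ValueError("factors must be (I, S, S)")
        if not np.allclose(self.factors, np.swapaxes(self.factors, 1, 2)):
            raise ValueError("diploid factor tables must be symmetric")

        self.L = 2 * I  # haplotype leaves
        self.G = len(ensemble)
        self.M = 2 * self.L - 1
        hap_labels = [f"{s}_{h}" for s in samples for h in (1, 2)]
        tree_labels = set(ensemble.trees[0].leaf_labels)
        if tree_labels != set(hap_labels):
            missing = sorted(set(hap_labels) - tree_labels)
            extra = sorted(tree_labels - set(hap_labels))
            raise LeafSampleMismatchError(
                f"ensemble/sample mismatch; missing leaves {missing}, extra leaves {extra}"
            )

        # stacked per-tree topology arrays
        self.leafnode = np.zeros((self.G, self.L), dtype=np.int64)
        self.post = np.zeros((self.G, self.L - 1), dtype=np.int64)
        self.post_c0 = np.zeros_like(self.post)
        self.post_c1 = np.zeros_like(self.post)
        branch_t = np.zeros((self.G, self.M))
        for g, tree in enumerate(ensemble):
            if tree.n_leaves != self.L:
                raise LeafSampleMismatchError("tree leaf count does not match samples")
            pos = {lab: j for j, lab in enumerate(tree.leaf_labels)}
            self.leafnode[g] = [pos[lab] for lab in hap_labels]
            order = tree.postorder_internal()
            self.post[g] = order
            self.post_c0[g] = tree.children[order, 0]
            self.post_c1[g] = tree.children[order, 1]
            nonroot = tree.parent >= 0
            branch_t[g, nonroot] = tree.time[tree.parent[nonroot]] - tree.time[nonroot]
        self._branch_t = branch_t
        self.kernels = self._build_kernels(branch_t)
        # mirrored kernels (k[S-1..1], k[0..S-1]) so a Toeplitz matrix is a
        # zero-copy strided view of a gathered row
        self._ext = np.ascontiguousarray(
            np.concatenate([self.kernels[:, :, :0:-1], self.kernels], axis=2)
        )

        self._g = np.arange(self.G)
        self.up = np.full((self.G, self.M, self.S), 1.0 / self.S)
        self.down = np.full((self.G, self.M, self.S), 1.0 / self.S)
        # log-scales of the raw (unnormalized) tree messages; cross-message
        # scales are identical across trees and cancel, so these capture the
        # relative per-tree weights needed for the raw-sum aggregation
        self.upS = np.zeros((self.G, self.M))
        self.downS = np.zeros((self.G, self.M))
        self.cross = np.full((self.L, self.S), 1.0 / self.S)  # cross[h]: message INTO leaf h
        self.agg = np.full((self.L, self.S), 1.0 / self.S)  # normalized tree aggregate
        i = np.arange(self.S)
        self._abs = np.abs(i[:, None] - i[None, :])
        self._context = "init"

    # -- construction helpers ------------------------------------------------

    def _build_kernels(self, branch_t: np.ndarray) -> np.ndarray:
        """Per-branch |delta| kernels ``(G, M, S)``; the potential matrix of
        a branch is the symmetric Toeplitz expansion of its kernel row."""
        var = self.params.variance(1.0) * branch_t  # Ne*mu_s*t elementwise
        d = np.arange(self.S, dtype=float)
        kern = np.zeros((self.G, self.M, self.S))
        pos = var > 0
        if pos.any():
            v = var[pos][:, None]
            kern[pos] = np.minimum(1.0, np.exp(-0.5 * d * d / v) / np.sqrt(2 * np.pi * v))
        kern[~pos, 0] = 1.0  # zero-length branch: identity potential
        return kern

    def with_rate(self, params: MutationParams) -> "BPState":
        """A fresh state over the same factors and ensemble with a new
        mutation rate: topology arrays are shared, kernels rebuilt,
        messages reset to uniform (used by rate selection)."""
        new = object.__new__(BPState)
        new.__dict__.update(self.__dict__)
        new.params = params
        new.kernels = new._build_kernels(new._branch_t)
        new._ext = np.ascontiguousarray(
            np.concatenate([new.kernels[:, :, :0:-1], new.kernels], axis=2)
        )
        new.up = np.full((new.G, new.M, new.S), 1.0 / new.S)
        new.down = np.full((new.G, new.M, new.S), 1.0 / new.S)
        new.upS = np.zeros((new.G, new.M))
        new.downS = np.zeros((new.G, new.M))
        new.cross = np.full((new.L, new.S), 1.0 / new.S)
        new.agg = np.full((new.L, new.S), 1.0 / new.S)
        new._sum_calls = None
        new._context = "init"
        return new

    def _apply_kernel(self, kern: np.ndarray, vec: np.ndarray) -> np.ndarray:
        """Batched symmetric-Toeplitz matvec: ``kern`` (B, S) kernels applied
        to ``vec`` (B, S).

        Each kernel row is expanded to its Toeplitz matrix as a zero-copy
        strided view of the mirrored kernel, so the only real work is the
        einsum contraction.
        """
        S = self.S
        ext = np.ascontiguousarray(np.concatenate([kern[:, :0:-1], kern], axis=1))
        s0, s1 = ext.strides
        mats = np.lib.stride_tricks.as_strided(
            ext[:, S - 1 :], shape=(ext.shape[0], S, S), strides=(s0, -s1, s1)
        )
        return np.einsum("bij,bj->bi", mats, vec)

    def _apply_branch(self, g: np.ndarray, nodes: np.ndarray,
                      vec: np.ndarray) -> np.ndarray:
        """Apply the potential of the branch above ``nodes`` (per tree ``g``)
        to message rows ``vec``."""
        S = self.S
        ext = self._ext[g, nodes].reshape(-1, 2 * S - 1)
        s0, s1 = ext.strides
        mats = np.lib.stride_tricks.as_strided(
            ext[:, S - 1 :], shape=(ext.shape[0], S, S), strides=(s0, -s1, s1)
        )
        out = np.einsum("bij,bj->bi", mats, vec.reshape(-1, S))
        return out.reshape(vec.shape)

    def _norm(self, arr: np.ndarray, context: str) -> np.ndarray:
        """Renormalize messages to sum 1.

        NaN/Inf raises with the offending update identified.  An exactly
        zero message signals contradictory hard (zero-potential) evidence,
        e.g. conflicting point masses through near-identity branches; the
        conventional robust choice is to reset it to uniform.
        """
        s = arr.sum(axis=-1, keepdims=True)
        if not np.isfinite(s).all():
            raise BPNumericalError(f"non-finite message during {context} "
                                   f"({self._context})")
        zero = (s == 0.0)[..., 0]
        if zero.any():
            arr = arr.copy()
            arr[zero] = 1.0
            s = arr.sum(axis=-1, keepdims=True)
        return arr / s

    # -- scheduled updates ---------------------------------------------------

    def update_cross_all(self, mode: str) -> None:
        """Cross-haplotype messages for every individual (step 1)."""
        f = self.factors
        agg1 = self.agg[0::2]
        agg2 = self.agg[1::2]
        if mode == "sum":
            to2 = np.einsum("iab,ia->ib", f, agg1)
            to1 = np.einsum("iab,ib->ia", f, agg2)
        elif mode == "max":
            to2 = (f * agg1[:, :, None]).max(axis=1)
            to1 = (f * agg2[:, None, :]).max(axis=2)
        else:
            raise ValueError(f"mode must be 'sum' or 'max', got {mode!r}")
        self.cross[1::2] = self._norm(to2, "cross-haplotype update")
        self.cross[0::2] = self._norm(to1, "cross-haplotype update")

    def _leaf_argmax_mask(self) -> np.ndarray:
        """Mask of leaf states attaining the per-leaf maximum of
        cross-message x tree-aggregate (ties kept as a set)."""
        score = self.cross * self.agg
        top = score.max(axis=1, keepdims=True)
        return score >= top * (1.0 - _TIE_RTOL)

    #: log-scale assigned to contradictory (all-zero) messages: the tree is
    #: effectively impossible and must not compete in the raw-sum aggregation
    _ZERO_MESSAGE_LOGSCALE = -1e4

    def _norm_scaled(self, arr: np.ndarray, context: str) -> tuple[np.ndarray, np.ndarray]:
        """Normalize and return the log of the normalizer (the raw scale).

        An exactly zero message signals contradictory hard (zero-potential)
        evidence; it is reset to uniform so propagation can continue, but
        its scale is set to an enormous log-penalty so the affected tree
        carries ~no weight when per-tree messages are summed.
        """
        s = arr.sum(axis=-1)
        if not np.isfinite(s).all():
            raise BPNumericalError(f"non-finite message during {context} "
                                   f"({self._context})")
        zero = s == 0.0
        if zero.any():
            arr = arr.copy()
            arr[zero] = 1.0
            s = arr.sum(axis=-1)
            logs = np.log(s)
            logs[zero] = self._ZERO_MESSAGE_LOGSCALE
            return arr / s[..., None], logs
        return arr / s[..., None], np.log(s)

    def _leaf_messages(self, vec: np.ndarray) -> np.ndarray:
        """Raw leaf-to-parent messages for all trees at once.

        The cross-message vector of a leaf is shared by every tree, so the
        Toeplitz matvecs collapse to one matmul per leaf against a
        "spread" table ``W[h, d, i] = sum_{j: |i-j|=d} vec[h, j]``.
        """
        G, L, S = self.G, self.L, self.S
        W = np.zeros((L, S, S))
        for d in range(S):
            W[:, d, d:] += vec[:, : S - d]
            if d:
                W[:, d, : S - d] += vec[:, d:]
        kern_lh = self.kernels[self._g[:, None], self.leafnode]  # (G, L, S)
        return np.matmul(kern_lh.transpose(1, 0, 2), W).transpose(1, 0, 2)

    def upward_sweep(self, mode: str) -> None:
        """Leaf-to-parent then internal upward messages (step 2)."""
        vec = self.cross
        if mode == "max":
            vec = vec * self._leaf_argmax_mask()
        G, L, S = self.G, self.L, self.S
        out, logs = self._norm_scaled(self._leaf_messages(vec), "leaf-to-parent update")
        self.up[self._g[:, None], self.leafnode] = out
        self.upS[self._g[:, None], self.leafnode] = logs
        for k in range(L - 2):  # postorder; the last entry is the root (no parent)
            v = self.post[:, k]
            c0 = self.post_c0[:, k]
            c1 = self.post_c1[:, k]
            prod = self.up[self._g, c0] * self.up[self._g, c1]
            msg = self._apply_branch(self._g, v, prod)
            out, logs = self._norm_scaled(msg, f"upward update (postorder step {k})")
            self.up[self._g, v] = out
            self.upS[self._g, v] = self.upS[self._g, c0] + self.upS[self._g, c1] + logs

    def downward_sweep(self) -> None:
        """Internal downward messages, root first (step 3).  The root's
        incoming parent message stays flat (its ``down`` row is never
        written and remains uniform at log-scale 0)."""
        for k in range(self.L - 2, -1, -1):
            v = self.post[:, k]
            c0 = self.post_c0[:, k]
            c1 = self.post_c1[:, k]
            dv = self.down[self._g, v]
            dvS = self.downS[self._g, v]
            gg = np.concatenate([self._g, self._g])
            cc = np.concatenate([c0, c1])
            vv = np.concatenate([dv * self.up[self._g, c1], dv * self.up[self._g, c0]])
            out, logs = self._norm_scaled(self._apply_branch(gg, cc, vv),
                                          f"downward update (step {k})")
            self.down[gg, cc] = out
            sibS = np.concatenate([self.upS[self._g, c1], self.upS[self._g, c0]])
            self.downS[gg, cc] = np.concatenate([dvS, dvS]) + sibS + logs

    def refresh_aggregate(self) -> None:
        """Per-leaf tree aggregate (step 4): the raw sum over trees of the
        parent-to-leaf messages, reconstructed from normalized messages and
        their per-tree log-scales, then normalized."""
        leafdown = self.down[self._g[:, None], self.leafnode]  # (G, L, S)
        logw = self.downS[self._g[:, None], self.leafnode]  # (G, L)
        w = np.exp(logw - logw.max(axis=0, keepdims=True))
        self.agg = self._norm((w[:, :, None] * leafdown).sum(axis=0), "tree aggregation")

    def run_cycles(self, cycles: int, mode: str) -> "BPState":
        for c in range(cycles):
            self._context = f"{mode}-product cycle {c + 1}/{cycles}"
            self.update_cross_all(mode)
            self.upward_sweep(mode)
            self.downward_sweep()
            self.refresh_aggregate()
        if mode == "sum":
            # snapshot of the sum-product decode, used as an extra polish
            # start by :func:`decode`
            self._sum_calls = _raw_calls(self)
        return self

    # -- decoding ------------------------------------------------------------

    def haplotype_belief(self, h: int) -> np.ndarray:
        """Unnormalized decoded belief for global haplotype index ``h``."""
        return self.cross[h] * self.agg[h]

    def _pick_state(self, belief: np.ndarray) -> int:
        """Argmax of a belief vector; ties prefer the reference repeat,
        then the smaller count."""
        top = belief.max()
        ties = np.flatnonzero(belief >= top * (1.0 - _TIE_RTOL))
        ns = self.n_vals[ties]
        if self.ref_repeat in ns:
            return self.ref_repeat
        return int(ns.min())


# ---------------------------------------------------------------------------
# operation-level surface


def update_leaf_to_parent(state: BPState, tree_index: int, leaf: int,
                          mode: str = "sum") -> np.ndarray:
    """Recompute the message from global haplotype leaf ``leaf`` to its
    parent in tree ``tree_index``; writes it into the state and returns it.

    In ``max`` mode the incoming cross-haplotype message is restricted to
    the argmax set of cross-message x tree-aggregate first.
    """
    vec = state.cross[leaf]
    if mode == "max":
        vec = vec * state._leaf_argmax_mask()[leaf]
    node = state.leafnode[tree_index, leaf]
    kern = state.kernels[tree_index, node][None, :]
    msg, logs = state._norm_scaled(state._apply_kernel(kern, vec[None, :]),
                                   "leaf-to-parent update")
    state.up[tree_index, node] = msg[0]
    state.upS[tree_index, node] = logs[0]
    return msg[0]


def update_internal(state: BPState, tree_index: int, node: int,
                    direction: str = "up") -> np.ndarray | list[np.ndarray]:
    """Recompute an internal node's message in one tree.

    ``direction='up'`` emits to the parent from the two child messages;
    ``direction='down'`` emits to both children (flat parent message at the
    root) and returns the two messages in child order.
    """
    tree = state.ensemble.trees[tree_index]
    c0, c1 = (int(c) for c in tree.children[node])
    if direction == "up":
        prod = state.up[tree_index, c0] * state.up[tree_index, c1]
        kern = state.kernels[tree_index, node][None, :]
        msg, logs = state._norm_scaled(state._apply_kernel(kern, prod[None, :]),
                                       "upward update")
        state.up[tree_index, node] = msg[0]
        state.upS[tree_index, node] = (state.upS[tree_index, c0]
                                       + state.upS[tree_index, c1] + logs[0])
        return msg[0]
    if direction == "down":
        dv = state.down[tree_index, node]
        out = []
        for child, sib in ((c0, c1), (c1, c0)):
            kern = state.kernels[tree_index, child][None, :]
            vec = (dv * state.up[tree_index, sib])[None, :]
            msg, logs = state._norm_scaled(state._apply_kernel(kern, vec),
                                           "downward update")
            state.down[tree_index, child] = msg[0]
            state.downS[tree_index, child] = (state.downS[tree_index, node]
                                              + state.upS[tree_index, sib] + logs[0])
            out.append(msg[0])
        return out
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def update_cross_haplotype(state: BPState, individual: int,
                           mode: str = "sum") -> tuple[np.ndarray, np.ndarray]:
    """Recompute one individual's two cross-haplotype messages.

    Returns ``(m_h1_to_h2, m_h2_to_h1)``; the tree aggregate
    ``sum_g m_parent->leaf`` provides the incoming evidence on each side.
    """
    f = state.factors[individual]
    h1, h2 = 2 * individual, 2 * individual + 1
    if mode == "sum":
        to2 = f.T @ state.agg[h1]
        to1 = f @ state.agg[h2]
    elif mode == "max":
        to2 = (f * state.agg[h1][:, None]).max(axis=0)
        to1 = (f * state.agg[h2][None, :]).max(axis=1)
    else:
        raise ValueError(f"mode must be 'sum' or 'max', got {mode!r}")
    m12 = state._norm(to2[None, :], "cross-haplotype update")[0]
    m21 = state._norm(to1[None, :], "cross-haplotype update")[0]
    state.cross[h2] = m12
    state.cross[h1] = m21
    return m12, m21


def run_loopy(state: BPState, cycles: int = 10) -> BPState:
    """Sum-product cycles over the full schedule (see module docstring)."""
    return state.run_cycles(cycles, "sum")


def run_mixed_product(state: BPState, cycles: int = 10) -> BPState:
    """Mixed-product cycles: max over leaf repeat states, sum over internal
    nodes and trees; normally seeded with messages from :func:`run_loopy`."""
    return state.run_cycles(cycles, "max")


#: decode polish is skipped above this estimated flop budget
_POLISH_FLOP_CAP = 2e8


def _polish_calls(calls: dict[str, tuple[int, int]], state: BPState,
                  max_sweeps: int = 3) -> dict[str, tuple[int, int]]:
    """Coordinate ascent on the exact objective, one individual at a time.

    Per-variable argmax decoding from approximate max-marginals can yield a
    jointly incoherent configuration; holding everyone else fixed, each
    individual's diploid pair is re-optimized against the true objective
    (cheap for small instances; skipped when the flop estimate is large).
    """
    S, I, G = state.S, len(state.samples), state.G
    if max_sweeps * I * S * S * G * state.M * S * S > _POLISH_FLOP_CAP:
        return calls
    factors = {s: state.factors[i] for i, s in enumerate(state.samples)}
    samples = sorted(factors)
    current = np.array([[calls[s][0] - state.n_min, calls[s][1] - state.n_min]
                        for s in samples]).reshape(-1)
    pair_grid = np.array([(a, b) for a in range(S) for b in range(S)], dtype=np.int64)

    def sweep_singles() -> bool:
        changed = False
        for j in range(I):
            configs = np.tile(current, (S * S, 1))
            configs[:, 2 * j : 2 * j + 2] = pair_grid
            scores = _config_scores(configs, factors, state.ensemble, state.params,
                                    state.n_min, state.n_max)
            cur_idx = int(current[2 * j] * S + current[2 * j + 1])
            best = int(np.argmax(scores))
            if scores[best] > scores[cur_idx] * (1.0 + _TIE_RTOL):
                current[2 * j : 2 * j + 2] = pair_grid[best]
                changed = True
        return changed

    def sweep_blocks() -> bool:
        # joint moves over two individuals catch coupled shifts that
        # single-individual ascent cannot; only meaningful when the block
        # is a strict subset of the instance (I >= 3)
        if I < 3 or I * I * S**4 * G * state.M * S * S > _POLISH_FLOP_CAP:
            return False
        quad = np.array([(a, b, c, d) for a in range(S) for b in range(S)
                         for c in range(S) for d in range(S)], dtype=np.int64)
        changed = False
        for j in range(I):
            for k in range(j + 1, I):
                cols = [2 * j, 2 * j + 1, 2 * k, 2 * k + 1]
                configs = np.tile(current, (S**4, 1))
                configs[:, cols] = quad
                scores = _config_scores(configs, factors, state.ensemble,
                                        state.params, state.n_min, state.n_max)
                cur_idx = int(np.flatnonzero((quad == current[cols]).all(axis=1))[0])
                best = int(np.argmax(scores))
                if scores[best] > scores[cur_idx] * (1.0 + _TIE_RTOL):
                    current[cols] = quad[best]
                    changed = True
        return changed

    for _ in range(max_sweeps):
        changed = sweep_singles()
        if not changed:
            changed = sweep_blocks()
        if not changed:
            break
    return {
        s: (int(state.n_vals[current[2 * j]]), int(state.n_vals[current[2 * j + 1]]))
        for j, s in enumerate(samples)
    }


def _raw_calls(state: BPState) -> dict[str, tuple[int, int]]:
    """Backtracked per-individual calls from the current messages."""
    calls: dict[str, tuple[int, int]] = {}
    for i, sample in enumerate(state.samples):
        n1 = state._pick_state(state.haplotype_belief(2 * i))
        cond = state.factors[i, n1 - state.n_min, :] * state.agg[2 * i + 1]
        if cond.max() == 0.0:
            cond = state.haplotype_belief(2 * i + 1)
        calls[sample] = (n1, state._pick_state(cond))
    return calls


def _polish_multistart(calls: dict[str, tuple[int, int]],
                       state: BPState) -> dict[str, tuple[int, int]]:
    """Polish from the mixed-product decode, the sum-product decode and the
    factor-only per-individual MLE; keep the best-scoring local optimum."""
    S, I, G = state.S, len(state.samples), state.G
    if 3 * I * S * S * G * state.M * S * S > _POLISH_FLOP_CAP:
        return calls
    factors = {s: state.factors[i] for i, s in enumerate(state.samples)}
    starts = [calls]
    if getattr(state, "_sum_calls", None) is not None:
        starts.append(state._sum_calls)
    alt: dict[str, tuple[int, int]] = {}
    for i, s in enumerate(state.samples):
        j1, j2 = np.unravel_index(int(np.argmax(state.factors[i])), (S, S))
        alt[s] = (int(state.n_vals[j1]), int(state.n_vals[j2]))
    starts.append(alt)
    # consensus start: everyone homozygous at the best joint diagonal state —
    # the relevant basin when tight genealogies link all individuals
    with np.errstate(divide="ignore"):
        diag = np.log(np.maximum(state.factors, FACTOR_FLOOR)).diagonal(axis1=1, axis2=2)
    n_star = int(state.n_vals[np.argmax(diag.sum(axis=0))])
    starts.append({s: (n_star, n_star) for s in state.samples})
    best_calls, best_score = None, -np.inf
    for start in starts:
        polished = _polish_calls(start, state, max_sweeps=6)
        score = config_objective(polished, factors, state.ensemble, state.params,
                                 state.n_min, state.n_max)
        if score > best_score:
            best_calls, best_score = polished, score
    return best_calls


def decode(state: BPState, polish: bool = True) -> RepeatCallSet:
    """Repeat calls from the final messages.

    Haplotype 1 is called by the argmax of cross-message x tree-aggregate.
    Haplotype 2 is then called by max-product backtracking through the
    diploid factor — argmax of ``factor[n_hat_1, .] x tree-aggregate`` —
    rather than by its own independent argmax: when the genealogy is
    symmetric between the two haplotypes (e.g. they form a cherry) their
    beliefs coincide and independent argmaxes can never express a
    heterozygous call.  Ties prefer the reference repeat, then the smaller
    count.  ``polish`` runs a size-capped exact coordinate-ascent pass over
    individuals to repair cross-individual incoherence.
    """
    calls: dict[str, tuple[int, int]] = {}
    beliefs: dict[str, np.ndarray] = {}
    for i, sample in enumerate(state.samples):
        b1 = state.haplotype_belief(2 * i)
        b2 = state.haplotype_belief(2 * i + 1)
        beliefs[f"{sample}_1"] = b1 / b1.sum()
        beliefs[f"{sample}_2"] = b2 / b2.sum()
        n1 = state._pick_state(b1)
        cond = state.factors[i, n1 - state.n_min, :] * state.agg[2 * i + 1]
        if cond.max() == 0.0:  # isolated zero row: fall back to the own belief
            cond = b2
        n2 = state._pick_state(cond)
        calls[sample] = (n1, n2)
    if polish:
        calls = _polish_multistart(calls, state)
    return RepeatCallSet(calls, beliefs, state.n_min, state.n_max)


def estimate_repeats(obs_by_individual: dict, ensemble: TreeEnsemble,
                     region: STRRegion, F: InsertSizeDistribution,
                     params: MutationParams, n_min: int = 0, n_max: int = 40,
                     loopy_cycles: int = 10, mixed_cycles: int = 10,
                     table: NormalizationTable | None = None) -> RepeatCallSet:
    """Full decoder: diploid factors + 10 loopy + 10 mixed-product cycles.

    ``obs_by_individual`` maps sample ids to observation lists; samples are
    taken from the ensemble leaf labels, and samples without observations
    receive uninformative factors.
    """
    samples = _parse_leaf_labels(ensemble.trees[0].leaf_labels)
    unmatched = sorted(set(obs_by_individual) - set(samples))
    if unmatched:
        raise LeafSampleMismatchError(
            f"observations for samples absent from the ensemble: {unmatched}"
        )
    if table is None:
        table = build_normalization_table(region, F, n_min, n_max)
    factors = np.stack([
        build_diploid_factor(obs_by_individual.get(s, []), region, F, n_min, n_max, table)
        for s in samples
    ])
    state = BPState(factors, samples, ensemble, params, n_min, n_max, region.ref_repeat)
    run_loopy(state, loopy_cycles)
    run_mixed_product(state, mixed_cycles)
    result = decode(state)
    result.selected_rate = params.mu_s
    return result


def _config_scores(configs: np.ndarray, factors: dict[str, np.ndarray],
                   ensemble: TreeEnsemble, params: MutationParams,
                   n_min: int, n_max: int) -> np.ndarray:
    """Exact objective ``prod_i f_i * sum_g P(N|g)`` for each leaf
    configuration (rows of ``configs``, state indices in sample order)."""
    samples = sorted(factors)
    S = n_max - n_min + 1
    hap_labels = [f"{s}_{h}" for s in samples for h in (1, 2)]
    abs_idx = np.abs(np.arange(S)[:, None] - np.arange(S)[None, :])
    C = configs.shape[0]
    total = np.zeros(C)
    for tree in ensemble:
        pos = {lab: j for j, lab in enumerate(tree.leaf_labels)}
        leafnode = [pos[lab] for lab in hap_labels]
        kmat = {}
        for u in range(tree.n_nodes):
            if tree.parent[u] >= 0:
                kern = transition_kernel(params.variance(tree.branch_time(u)), S - 1)
                kmat[u] = kern[abs_idx]
        contrib: dict[int, np.ndarray] = {}
        for h, node in enumerate(leafnode):
            contrib[node] = kmat[node][configs[:, h], :]
        val = None
        for v in tree.postorder_internal():
            c0, c1 = (int(c) for c in tree.children[v])
            A = contrib.pop(c0) * contrib.pop(c1)
            if tree.parent[v] < 0:
                val = A.sum(axis=1)
            else:
                contrib[v] = A @ kmat[v]
        total += val

    fprod = np.ones(C)
    for i, s in enumerate(samples):
        f = np.asarray(factors[s], dtype=float)
        if f.shape != (S, S):
            raise ValueError(f"factor for {s} must be ({S}, {S})")
        fprod *= f[configs[:, 2 * i], configs[:, 2 * i + 1]]
    return fprod * total


def config_objective(calls: dict[str, tuple[int, int]], factors: dict[str, np.ndarray],
                     ensemble: TreeEnsemble, params: MutationParams,
                     n_min: int, n_max: int) -> float:
    """Exact objective value of one call set (for oracle comparisons)."""
    samples = sorted(factors)
    config = np.array([[calls[s][0] - n_min, calls[s][1] - n_min]
                       for s in samples]).reshape(1, -1)
    return float(_config_scores(config, factors, ensemble, params, n_min, n_max)[0])


def brute_force_marginal_map(factors: dict[str, np.ndarray], ensemble: TreeEnsemble,
                             params: MutationParams, n_min: int, n_max: int,
                             ref_repeat: int | None = None,
                             max_configs: int = 10**7) -> RepeatCallSet:
    """Exact marginal-MAP oracle by exhaustive enumeration of leaf states.

    Internal-node repeats are eliminated exactly per tree; only usable for
    tiny instances (the leaf state space must stay below ``max_configs``).
    Ties prefer the reference repeat, then the smaller count.
    """
    samples = sorted(factors)
    I = len(samples)
    S = n_max - n_min + 1
    L = 2 * I
    if S**L > max_configs:
        raise ValueError(f"state space {S}**{L} exceeds {max_configs}; refusing")
    n_vals = np.arange(n_min, n_max + 1)
    if ref_repeat is None:
        pref = list(range(S))
    else:
        pref = sorted(range(S), key=lambda j: (n_vals[j] != ref_repeat, n_vals[j]))
    configs = np.array(list(itertools.product(pref, repeat=L)), dtype=np.int64)
    objective = _config_scores(configs, factors, ensemble, params, n_min, n_max)
    best = int(np.argmax(objective))  # first max wins: configs are in preference order
    calls = {
        s: (int(n_vals[configs[best, 2 * i]]), int(n_vals[configs[best, 2 * i + 1]]))
        for i, s in enumerate(samples)
    }
    return RepeatCallSet(calls, {}, n_min, n_max)
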