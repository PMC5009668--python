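"""Coalescent genealogies: simulation, Newick interchange, evolution of
flanking sites and repeat counts down a tree, and a Metropolis–Hastings
sampler of trees conditioned on phased flanking genotypes.

Trees are rooted, strictly binary and ultrametric.  Node times are measured
backwards from the present in units of Ne generations; leaves sit at time 0.
Leaf labels follow the ``"<sample>_1" / "<sample>_2"`` convention for the
two haplotypes of a diploid individual.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .mutation import MutationParams, stepwise_simulate

__all__ = [
    "CoalescentTree",
    "TreeEnsemble",
    "HaplotypePanel",
    "RepeatAssignment",
    "NewickParseError",
    "simulate_coalescent_tree",
    "mutate_sites_on_tree",
    "simulate_repeat_numbers",
    "sample_trees_mcmc",
    "shuffle_haplotypes",
    "read_newick",
    "write_newick",
    "haplotype_labels",
]

#: default per-generation single-base substitution rates (transition,
#: transversion) used when evolving flanking sites
TRANSITION_RATE = 5.5e-8
TRANSVERSION_RATE = 1.2e-8

_ULTRAMETRIC_TOL = 1e-6


class NewickParseError(ValueError):
    """Raised for malformed, non-binary or non-ultrametric Newick input."""


def haplotype_labels(samples: list[str]) -> list[str]:
    """Leaf labels for the two haplotypes of each sample, in panel row order."""
    return [f"{s}_{h}" for s in samples for h in (1, 2)]


class CoalescentTree:
    """Rooted binary ultrametric genealogy stored as flat arrays.

    Nodes ``0 .. n_leaves-1`` are leaves (time 0), the rest are internal.
    ``parent[root] == -1``; ``children`` rows are ``(-1, -1)`` for leaves.
    """

    def __init__(self, parent: np.ndarray, children: np.ndarray,
                 time: np.ndarray, leaf_labels: list[str]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)
        self.time = np.asarray(time, dtype=float)
        self.leaf_labels = list(leaf_labels)
        self.n_leaves = len(leaf_labels)
        self.n_nodes = self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.argmax(self.parent == -1))

    def branch_time(self, u: int) -> float:
        """Time along the branch from ``u`` to its parent."""
        p = self.parent[u]
        if p < 0:
            raise ValueError(f"node {u} is the root and has no parent branch")
        return float(self.time[p] - self.time[u])

    def postorder_internal(self) -> np.ndarray:
        """Internal node ids, children-before-parents.

        Node times are strictly increasing toward the root, so sorting the
        internal nodes by time yields a valid postorder.
        """
        internal = np.arange(self.n_leaves, self.n_nodes)
        return internal[np.argsort(self.time[internal], kind="stable")]

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        if self.n_nodes != 2 * self.n_leaves - 1:
            raise ValueError("node count must be 2 * leaves - 1")
        if (self.parent == -1).sum() != 1:
            raise ValueError("tree must have exactly one root")
        if not np.allclose(self.time[: self.n_leaves], 0.0, atol=_ULTRAMETRIC_TOL):
            raise ValueError("leaves must sit at time 0 (ultrametric)")
        for v in range(self.n_leaves, self.n_nodes):
            c = self.children[v]
            if (c < 0).any():
                raise ValueError(f"internal node {v} lacks two children")
            for u in c:
                if self.parent[u] != v:
                    raise ValueError(f"parent/children arrays disagree at node {u}")
                if self.time[v] <= self.time[u]:
                    raise ValueError(f"parent time not above child time at node {u}")

    def copy(self) -> "CoalescentTree":
        return CoalescentTree(self.parent.copy(), self.children.copy(),
                              self.time.copy(), list(self.leaf_labels))

    @property
    def tmrca(self) -> float:
        return float(self.time.max())


@dataclass
class TreeEnsemble:
    """An ordered collection of genealogies over a common leaf set."""

    trees: list[CoalescentTree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("ensemble must contain at least one tree")
        labels = set(self.trees[0].leaf_labels)
        for g in self.trees[1:]:
            if set(g.leaf_labels) != labels:
                raise ValueError("all trees in an ensemble must share one leaf set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def to_newick(self) -> str:
        return "".join(write_newick(g) + "\n" for g in self.trees)

    @classmethod
    def from_newick(cls, text: str) -> "TreeEnsemble":
        trees = [read_newick(line) for line in text.splitlines() if line.strip()]
        return cls(trees)


@dataclass
class HaplotypePanel:
    """Phased biallelic genotypes: one 0/1 row per haplotype.

    Haplotype ``h`` (1 or 2) of the ``i``-th sample is row ``2*i + h - 1``.
    """

    positions: np.ndarray
    alleles: np.ndarray  # (2I, n_sites) over {0, 1}
    labels: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != len(self.labels):
            raise ValueError("alleles must be (n_haplotypes, n_sites)")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (diploid samples)")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("one position per site required")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("panel must be biallelic (alleles in {0, 1})")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


@dataclass
class RepeatAssignment:
    """Repeat count at every node of one tree (simulation truth)."""

    tree: CoalescentTree
    values: np.ndarray  # (n_nodes,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape[0] != self.tree.n_nodes:
            raise ValueError("one repeat count per tree node required")

    def leaf_values(self) -> dict[str, int]:
        return {lab: int(self.values[j]) for j, lab in enumerate(self.tree.leaf_labels)}


# ---------------------------------------------------------------------------
# simulation


def simulate_coalescent_tree(num_haplotypes: int, params: MutationParams,
                             rng: np.random.Generator,
                             leaf_labels: list[str] | None = None) -> CoalescentTree:
    """Draw a genealogy from the standard neutral (Kingman) coalescent.

    With ``k`` open lineages the waiting time to the next merger is
    exponential with rate ``k*(k-1)/4`` in Ne-generation units (a single
    pair coalesces after 2*Ne generations on average), and the merging pair
    is uniform.
    """
    if num_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    if leaf_labels is None:
        if num_haplotypes % 2:
            leaf_labels = [f"h{j}" for j in range(num_haplotypes)]
        else:
            leaf_labels = haplotype_labels([str(i) for i in range(num_haplotypes // 2)])
    elif len(leaf_labels) != num_haplotypes:
        raise ValueError("leaf_labels length must equal num_haplotypes")
    L = num_haplotypes
    M = 2 * L - 1
    parent = np.full(M, -1, dtype=np.int64)
    children = np.full((M, 2), -1, dtype=np.int64)
    time = np.zeros(M)
    active = list(range(L))
    t = 0.0
    nxt = L
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(4.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        children[nxt] = (a, b)
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return CoalescentTree(parent, children, time, leaf_labels)


def _branch_nodes(tree: CoalescentTree) -> np.ndarray:
    """All non-root nodes (each owns the branch to its parent)."""
    return np.flatnonzero(tree.parent >= 0)


def mutate_sites_on_tree(tree: CoalescentTree, positions: np.ndarray,
                         transition_rate: float, transversion_rate: float,
                         params: MutationParams,
                         rng: np.random.Generator) -> HaplotypePanel:
    """Evolve biallelic flanking sites down the tree.

    Per site and branch, a substitution toggles the allele with probability
    ``min(1, total_rate * Ne * t)``; the root carries the ancestral allele 0
    and repeated hits on one site re-toggle, keeping every site biallelic.
    Monomorphic sites are retained.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("positions must be non-empty")
    total_rate = transition_rate + transversion_rate
    n_sites = positions.size
    states = np.zeros((tree.n_nodes, n_sites), dtype=np.uint8)
    order = tree.postorder_internal()[::-1]  # parents before children
    for v in order:
        for u in tree.children[v]:
            q = min(1.0, total_rate * params.Ne * tree.branch_time(u) * params.time_scale)
            toggles = rng.random(n_sites) < q
            states[u] = states[v] ^ toggles
    return HaplotypePanel(positions, states[: tree.n_leaves], list(tree.leaf_labels))


def simulate_repeat_numbers(tree: CoalescentTree, root_repeat: int,
                            params: MutationParams,
                            rng: np.random.Generator) -> RepeatAssignment:
    """Evolve repeat counts from the root down every branch with the exact
    stepwise model (``round(Ne * t)`` generations per branch)."""
    if root_repeat < 1:
        raise ValueError("root repeat count must be >= 1")
    values = np.zeros(tree.n_nodes, dtype=np.int64)
    values[tree.root] = root_repeat
    order = tree.postorder_internal()[::-1]
    for v in order:
        for u in tree.children[v]:
            gens = int(round(params.Ne * tree.branch_time(u) * params.time_scale))
            values[u] = stepwise_simulate(int(values[v]), gens, params.mu_s, rng)
    return RepeatAssignment(tree, values)


def shuffle_haplotypes(panel: HaplotypePanel, rng: np.random.Generator) -> HaplotypePanel:
    """Uniformly permute haplotype rows (labels keep their positions), the
    control that breaks the genotype-genealogy correspondence."""
    perm = rng.permutation(panel.n_haplotypes)
    return HaplotypePanel(panel.positions.copy(), panel.alleles[perm], list(panel.labels))


# ---------------------------------------------------------------------------
# Newick interchange


def read_newick(text: str) -> CoalescentTree:
    """Parse one Newick tree into a :class:`CoalescentTree`.

    Requires a strictly binary topology, branch lengths on every non-root
    edge, and equal root-to-leaf path lengths (ultrametric within 1e-6).
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    leaves = [nd for nd in dtree.leaf_node_iter()]
    internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    for nd in internals:
        if len(nd.child_nodes()) != 2:
            raise NewickParseError(
                f"non-binary node with {len(nd.child_nodes())} children near "
                f"{nd.child_nodes()[0] if nd.child_nodes() else nd}"
            )
    depth: dict = {dtree.seed_node: 0.0}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        if nd.edge.length is None:
            raise NewickParseError(f"missing branch length on edge above {nd}")
        depth[nd] = depth[nd.parent_node] + float(nd.edge.length)
    leaf_depths = np.array([depth[nd] for nd in leaves])
    height = float(leaf_depths.max())
    if np.ptp(leaf_depths) > _ULTRAMETRIC_TOL:
        raise NewickParseError(
            f"non-ultrametric input: leaf depths span {np.ptp(leaf_depths):g}"
        )
    L = len(leaves)
    M = 2 * L - 1
    if len(internals) != L - 1:
        raise NewickParseError("internal node count must be leaves - 1")
    ids: dict = {}
    labels = []
    for j, nd in enumerate(leaves):
        ids[nd] = j
        if nd.taxon is None or not nd.taxon.label:
            raise NewickParseError("leaf without a label")
        labels.append(nd.taxon.label.replace(" ", "_"))
    for j, nd in enumerate(internals):
        ids[nd] = L + j
    parent = np.full(M, -1, dtype=np.int64)
    children = np.full((M, 2), -1, dtype=np.int64)
    time = np.zeros(M)
    for nd, v in ids.items():
        time[v] = height - depth[nd]
        if not nd.is_leaf():
            c = nd.child_nodes()
            children[v] = (ids[c[0]], ids[c[1]])
            parent[ids[c[0]]] = parent[ids[c[1]]] = v
    time[:L] = 0.0  # absorb sub-tolerance depth jitter
    tree = CoalescentTree(parent, children, time, labels)
    tree.validate()
    return tree


def write_newick(tree: CoalescentTree) -> str:
    """Serialize a tree to Newick with branch lengths (times difference)."""
    out = io.StringIO()

    def emit(v: int) -> None:
        if v < tree.n_leaves:
            out.write(tree.leaf_labels[v])
        else:
            out.write("(")
            emit(int(tree.children[v, 0]))
            out.write(",")
            emit(int(tree.children[v, 1]))
            out.write(")")
        p = tree.parent[v]
        if p >= 0:
            out.write(f":{tree.time[p] - tree.time[v]:.10g}")

    emit(tree.root)
    out.write(";")
    return out.getvalue()


# ---------------------------------------------------------------------------
# MCMC over genealogies given phased flanking genotypes


class _TreePosterior:
    """Incremental coalescent-prior x two-state-likelihood evaluation.

    The substitution model is symmetric two-state with stationary (1/2, 1/2)
    and per-branch flip probability ``(1 - exp(-2 r Ne t)) / 2``.  Partial
    likelihoods are kept per node with per-pattern max-rescaling so updates
    after a proposal only touch the path to the root.
    """

    def __init__(self, tree: CoalescentTree, panel: HaplotypePanel,
                 params: MutationParams, site_rate: float):
        self.tree = tree
        self.params = params
        self.site_rate = site_rate
        cols, counts = (np.zeros((0, panel.n_haplotypes), dtype=np.uint8), np.zeros(0))
        if panel.n_sites:
            cols, counts = np.unique(panel.alleles.T, axis=0, return_counts=True)
        self.patterns = cols  # (P, 2I)
        self.counts = counts.astype(float)
        P, M = self.patterns.shape[0], tree.n_nodes
        self.partial = np.zeros((M, P, 2))
        self.lognorm = np.zeros((M, P))
        for leaf in range(tree.n_leaves):
            self.partial[leaf, np.arange(P), self.patterns[:, leaf]] = 1.0
        self.total_lognorm = np.zeros(P)
        if P:
            for v in tree.postorder_internal():
                self._recompute(v)

    def flip_prob(self, u: int) -> float:
        t = self.tree.branch_time(u) * self.params.time_scale
        return 0.5 * (1.0 - np.exp(-2.0 * self.site_rate * self.params.Ne * t))

    def _child_contrib(self, u: int) -> np.ndarray:
        q = self.flip_prob(u)
        part = self.partial[u]
        return (1.0 - q) * part + q * part[:, ::-1]

    def _recompute(self, v: int) -> None:
        c0, c1 = self.tree.children[v]
        A = self._child_contrib(int(c0)) * self._child_contrib(int(c1))
        m = A.max(axis=1)
        np.clip(m, 1e-300, None, out=m)
        self.total_lognorm += np.log(m) - self.lognorm[v]
        self.lognorm[v] = np.log(m)
        self.partial[v] = A / m[:, None]

    def loglik(self) -> float:
        if self.patterns.shape[0] == 0:
            return 0.0
        root_sum = 0.5 * self.partial[self.tree.root].sum(axis=1)
        return float(self.counts @ (np.log(root_sum) + self.total_lognorm))

    def logprior(self) -> float:
        times = np.sort(self.tree.time[self.tree.n_leaves :])
        k = np.arange(self.tree.n_leaves, 1, -1)
        dt = np.diff(np.concatenate(([0.0], times)))
        return float(-(k * (k - 1) / 4.0 * dt).sum())

    def update_nodes(self, nodes: list[int]) -> dict:
        """Recompute partials for the given internal nodes (must already be
        ordered children-before-parents); returns a restore snapshot."""
        snap = {
            "nodes": nodes,
            "partial": self.partial[nodes].copy(),
            "lognorm": self.lognorm[nodes].copy(),
            "total": self.total_lognorm.copy(),
        }
        if self.patterns.shape[0]:
            for v in nodes:
                self._recompute(v)
        return snap

    def restore(self, snap: dict) -> None:
        self.partial[snap["nodes"]] = snap["partial"]
        self.lognorm[snap["nodes"]] = snap["lognorm"]
        self.total_lognorm = snap["total"]

    def path_to_root(self, v: int) -> list[int]:
        path = []
        while v >= 0:
            path.append(int(v))
            v = self.tree.parent[v]
        return path


def _is_ancestor(tree: CoalescentTree, a: int, b: int) -> bool:
    """True if ``a`` is a strict ancestor of ``b``."""
    v = tree.parent[b]
    while v >= 0:
        if v == a:
            return True
        v = tree.parent[v]
    return False


def sample_trees_mcmc(panel: HaplotypePanel, params: MutationParams,
                      n_samples: int = 100, burn_in: int = 50000,
                      thin: int = 100, rng: np.random.Generator | None = None,
                      site_rate: float = TRANSITION_RATE + TRANSVERSION_RATE,
                      time_move_prob: float = 0.7) -> TreeEnsemble:
    """Sample genealogies conditioned on a phased haplotype panel.

    A Metropolis–Hastings chain over (topology, node times) targets
    coalescent-prior x panel-likelihood.  Moves: (a) redraw an internal node
    time uniformly between its children and parent (multiplicative scaling
    of the root's offset), (b) a wide subtree exchange that swaps two
    non-nested subtrees compatible in time.  Samples are taken every
    ``thin`` iterations (accepted or not) after ``burn_in`` iterations.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if panel.n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    if rng is None:
        rng = np.random.default_rng()
    tree = simulate_coalescent_tree(panel.n_haplotypes, params, rng,
                                    leaf_labels=list(panel.labels))
    post = _TreePosterior(tree, panel, params, site_rate)
    log_p = post.logprior() + post.loglik()
    L = tree.n_leaves
    internal = np.arange(L, tree.n_nodes)
    non_root_pool = None  # recomputed lazily; root id changes under exchange
    samples: list[CoalescentTree] = []
    total_iters = burn_in + n_samples * thin
    for it in range(1, total_iters + 1):
        if rng.random() < time_move_prob or L == 2:
            v = int(internal[rng.integers(internal.size)])
            c0, c1 = tree.children[v]
            lo = max(tree.time[c0], tree.time[c1])
            old_t = tree.time[v]
            log_hastings = 0.0
            if tree.parent[v] < 0:
                delta = old_t - lo
                factor = np.exp(rng.uniform(-0.7, 0.7))
                new_t = lo + delta * factor
                log_hastings = np.log(factor)
            else:
                hi = tree.time[tree.parent[v]]
                new_t = rng.uniform(lo, hi)
            tree.time[v] = new_t
            snap = post.update_nodes(post.path_to_root(v))
            log_p_new = post.logprior() + post.loglik()
            if np.log(rng.random()) < log_p_new - log_p + log_hastings:
                log_p = log_p_new
            else:
                tree.time[v] = old_t
                post.restore(snap)
        else:
            if non_root_pool is None:
                non_root_pool = _branch_nodes(tree)
            a, b = rng.integers(non_root_pool.size, size=2)
            u, w = int(non_root_pool[a]), int(non_root_pool[b])
            pu, pw = int(tree.parent[u]), int(tree.parent[w])
            feasible = (
                u != w and pu != pw
                and not _is_ancestor(tree, u, w) and not _is_ancestor(tree, w, u)
                and tree.time[pu] > tree.time[w] and tree.time[pw] > tree.time[u]
            )
            if feasible:
                tree.children[pu, tree.children[pu] == u] = w
                tree.children[pw, tree.children[pw] == w] = u
                tree.parent[u], tree.parent[w] = pw, pu
                touched = sorted(set(post.path_to_root(pu)) | set(post.path_to_root(pw)),
                                 key=lambda x: tree.time[x])
                snap = post.update_nodes(touched)
                log_p_new = post.logprior() + post.loglik()
                if np.log(rng.random()) < log_p_new - log_p:
                    log_p = log_p_new
                else:
                    tree.children[pu, tree.children[pu] == w] = u
                    tree.children[pw, tree.children[pw] == u] = w
                    tree.parent[u], tree.parent[w] = pu, pw
                    post.restore(snap)
        if it > burn_in and (it - burn_in) % thin == 0:
            samples.append(tree.copy())
    return TreeEnsemble(samples)
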