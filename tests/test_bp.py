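import itertools

import numpy as np
import pytest

from strlink.bp import (
    BPState,
    LeafSampleMismatchError,
    brute_force_marginal_map,
    build_diploid_factor,
    config_objective,
    decode,
    estimate_repeats,
    run_loopy,
    run_mixed_product,
    update_cross_haplotype,
    update_internal,
    update_leaf_to_parent,
)
from strlink.genealogy import (
    TreeEnsemble,
    haplotype_labels,
    read_newick,
    simulate_coalescent_tree,
)
from strlink.insert_model import build_normalization_table
from strlink.mutation import MutationParams, transition_kernel

from conftest import make_obs

#: branch time giving unit Brownian variance at mu_s = 1e-3, Ne = 10400
T_VAR1 = 1.0 / 10.4


def pair_tree(sample: str, t: float):
    return read_newick(f"({sample}_1:{t},{sample}_2:{t});")


def make_state(factors, samples, ensemble, mu_s=1e-3, n_min=4, n_max=6, ref=5):
    return BPState(np.asarray(factors, dtype=float), samples, ensemble,
                   MutationParams(mu_s), n_min, n_max, ref)


class TestBuildDiploidFactor:
    def test_zero_observations_all_ones(self, toy_region, toy_F):
        f = build_diploid_factor([], toy_region, toy_F, 0, 10)
        assert np.all(f == 1.0)

    def test_symmetric(self, toy_region, peaked_F):
        f = build_diploid_factor(make_obs([(95, 16), (96, 15)]), toy_region,
                                 peaked_F, 0, 10)
        assert np.allclose(f, f.T)
        assert f.max() == pytest.approx(1.0)

    def test_toy_entry_ratio(self, toy_region, toy_F):
        # entry (5,6) proportional to 0.5*(0.2 + 1/3); entry (5,5) to 0.2
        f = build_diploid_factor(make_obs([(95, 15)]), toy_region, toy_F, 0, 10)
        assert f[5, 6] / f[5, 5] == pytest.approx(0.5 * (0.2 + 1 / 3) / 0.2)


class TestUpdateLeafToParent:
    def test_flat_transition_gives_uniform(self):
        ens = TreeEnsemble([pair_tree("a", 1e22)])
        st = make_state(np.ones((1, 3, 3)), ["a"], ens)
        st.cross[0] = np.array([0.7, 0.2, 0.1])
        msg = update_leaf_to_parent(st, 0, 0)
        assert np.allclose(msg, 1 / 3)

    def test_identity_transition_copies_message(self):
        ens = TreeEnsemble([pair_tree("a", 1.0)])
        st = make_state(np.ones((1, 3, 3)), ["a"], ens, mu_s=0.0)
        st.cross[0] = np.array([0.7, 0.2, 0.1])
        msg = update_leaf_to_parent(st, 0, 0)
        assert np.allclose(msg, [0.7, 0.2, 0.1])

    def test_variance_one_point_mass(self):
        # kernel row for |d| = 0,1: (0.3989, 0.2420); point mass on middle state
        ens = TreeEnsemble([pair_tree("a", T_VAR1)])
        st = make_state(np.ones((1, 3, 3)), ["a"], ens)
        st.cross[0] = np.array([0.0, 1.0, 0.0])
        msg = update_leaf_to_parent(st, 0, 0)
        expected = np.array([0.2420, 0.3989, 0.2420])
        assert np.allclose(msg, expected / expected.sum(), atol=1e-4)


class TestUpdateInternal:
    def test_uniform_in_flat_out(self, params, rng):
        labels = haplotype_labels(["a", "b"])
        tree = read_newick("((a_1:1e22,a_2:1e22):1e22,(b_1:1e22,b_2:1e22):1e22);")
        st = make_state(np.ones((2, 3, 3)), ["a", "b"], TreeEnsemble([tree]))
        v = int(tree.children[tree.root][0])
        if v < 4:
            v = int(tree.children[tree.root][1])
        msg = update_internal(st, 0, v, "up")
        assert np.allclose(msg, 1 / 3)

    def test_matrix_product_oracle(self):
        tree = read_newick(f"(a_1:{T_VAR1},a_2:{T_VAR1});")
        st = make_state(np.ones((1, 3, 3)), ["a"], TreeEnsemble([tree]))
        m1 = np.array([0.6, 0.3, 0.1])
        m2 = np.array([0.2, 0.2, 0.6])
        i1 = tree.leaf_labels.index("a_1")
        i2 = tree.leaf_labels.index("a_2")
        st.up[0, i1] = m1
        st.up[0, i2] = m2
        K = transition_kernel(1.0, 2)[np.abs(np.arange(3)[:, None] - np.arange(3))]
        down = update_internal(st, 0, tree.root, "down")
        exp1 = K @ (np.ones(3) / 3 * m2)
        assert np.allclose(down[0], exp1 / exp1.sum())
        exp2 = K @ (np.ones(3) / 3 * m1)
        assert np.allclose(down[1], exp2 / exp2.sum())

    def test_identity_chain_propagates_point_mass(self):
        tree = read_newick("((a_1:0.5,a_2:0.5):0.5,(b_1:0.7,b_2:0.7):0.3);")
        st = make_state(np.ones((2, 3, 3)), ["a", "b"], TreeEnsemble([tree]), mu_s=0.0)
        i1 = tree.leaf_labels.index("a_1")
        st.cross[0] = np.array([0.0, 1.0, 0.0])
        msg = update_leaf_to_parent(st, 0, 0)
        assert np.allclose(msg, [0, 1, 0])
        parent = int(tree.parent[i1])
        up = update_internal(st, 0, parent, "up")
        # sibling message still uniform; identity kernel keeps the point mass
        assert np.argmax(up) == 1


class TestUpdateCrossHaplotype:
    def test_uniform_everything_stays_uniform(self):
        ens = TreeEnsemble([pair_tree("a", 1.0)])
        st = make_state(np.ones((1, 3, 3)), ["a"], ens)
        m12, m21 = update_cross_haplotype(st, 0, "sum")
        assert np.allclose(m12, 1 / 3)
        assert np.allclose(m21, 1 / 3)

    @pytest.mark.parametrize("mode", ["sum", "max"])
    def test_point_mass_factor(self, mode):
        ens = TreeEnsemble([pair_tree("a", 1.0)])
        f = np.zeros((3, 3))
        f[0, 2] = f[2, 0] = 1.0  # point mass at (4, 6) and its mirror
        st = make_state(f[None], ["a"], ens)
        st.agg[0] = np.array([1.0, 0.0, 0.0])  # T(a) > 0 only at state 4
        m12, _ = update_cross_haplotype(st, 0, mode)
        assert np.allclose(m12, [0.0, 0.0, 1.0])

    @pytest.mark.parametrize("mode", ["sum", "max"])
    def test_exhaustive_oracle_two_trees(self, mode, rng):
        trees = [pair_tree("a", 0.11), pair_tree("a", 0.45)]
        f = rng.random((3, 3))
        f = f + f.T
        st = make_state(f[None] / f.max(), ["a"], TreeEnsemble(trees))
        # distinct per-tree parent messages; aggregate is their raw sum
        d1 = np.array([0.5, 0.3, 0.2])
        d2 = np.array([0.1, 0.1, 0.8])
        for g, d in enumerate((d1, d2)):
            st.down[g, st.leafnode[g, 0]] = d
            st.downS[g, st.leafnode[g, 0]] = 0.0
        st.refresh_aggregate()
        T = (d1 + d2) / (d1 + d2).sum()
        fn = f / f.max()
        if mode == "sum":
            expected = np.array([sum(fn[a, b] * T[a] for a in range(3)) for b in range(3)])
        else:
            expected = np.array([max(fn[a, b] * T[a] for a in range(3)) for b in range(3)])
        m12, _ = update_cross_haplotype(st, 0, mode)
        assert np.allclose(m12, expected / expected.sum())


def exact_leaf_marginals_bruteforce(tree, params, n_min, n_max):
    """Independent oracle: leaf marginals of the single-tree prior with flat
    evidence, by exhaustive enumeration over all node states."""
    S = n_max - n_min + 1
    idx = np.abs(np.arange(S)[:, None] - np.arange(S)[None, :])
    kmat = {
        u: transition_kernel(params.variance(tree.branch_time(u)), S - 1)[idx]
        for u in range(tree.n_nodes) if tree.parent[u] >= 0
    }
    margs = np.zeros((tree.n_leaves, S))
    for config in itertools.product(range(S), repeat=tree.n_nodes):
        w = 1.0
        for u, p in enumerate(tree.parent):
            if p >= 0:
                w *= kmat[u][config[u], config[p]]
        for leaf in range(tree.n_leaves):
            margs[leaf, config[leaf]] += w
    return margs / margs.sum(axis=1, keepdims=True)


class TestRunLoopy:
    def test_cycle_free_exactness(self, rng):
        params = MutationParams(3e-4)
        for _ in range(3):
            L = int(rng.integers(2, 5)) * 2
            samples = [f"s{i}" for i in range(L // 2)]
            tree = simulate_coalescent_tree(L, params, rng,
                                            leaf_labels=haplotype_labels(samples))
            if tree.n_nodes > 7:  # keep the brute-force oracle tractable
                continue
            S = 4
            st = BPState(np.ones((L // 2, S, S)), samples, TreeEnsemble([tree]),
                         params, 4, 7, 5)
            run_loopy(st, 10)
            exact = exact_leaf_marginals_bruteforce(tree, params, 4, 7)
            for h in range(L):
                node = st.leafnode[0, h]
                belief = st.haplotype_belief(h)
                assert np.allclose(belief / belief.sum(), exact[node], atol=1e-9)

    def test_identity_converges_fast(self):
        tree = read_newick("(a_1:0.5,a_2:0.5);")
        f = np.zeros((3, 3))
        f[1, 1] = 1.0
        st = make_state(f[None], ["a"], TreeEnsemble([tree]), mu_s=0.0)
        run_loopy(st, 2)
        dec = decode(st, polish=False)
        assert dec.calls["a"] == (5, 5)

    def test_bit_identical_reruns(self, rng):
        params = MutationParams(5e-4)
        samples = ["a", "b"]
        trees = [simulate_coalescent_tree(4, params, rng,
                                          leaf_labels=haplotype_labels(samples))
                 for _ in range(2)]
        f = rng.random((2, 4, 4))
        f = f + np.swapaxes(f, 1, 2)
        results = []
        for _ in range(2):
            st = BPState(f, samples, TreeEnsemble(trees), params, 0, 3, 1)
            run_loopy(st, 10)
            run_mixed_product(st, 10)
            results.append((st.cross.copy(), st.agg.copy()))
        assert np.array_equal(results[0][0], results[1][0])
        assert np.array_equal(results[0][1], results[1][1])


class TestDecode:
    def test_uniform_beliefs_return_reference(self):
        ens = TreeEnsemble([pair_tree("a", 1e22)])
        st = make_state(np.ones((1, 3, 3)), ["a"], ens)
        run_loopy(st, 2)
        run_mixed_product(st, 2)
        assert decode(st).calls["a"] == (5, 5)  # ref = 5 via tie-break

    def test_point_mass_beliefs(self):
        ens = TreeEnsemble([pair_tree("a", 1.0)])
        f = np.zeros((3, 3))
        f[0, 2] = f[2, 0] = 1.0
        st = make_state(f[None], ["a"], ens)
        st.cross[0] = np.array([1.0, 0.0, 0.0])
        st.cross[1] = np.array([0.0, 0.0, 1.0])
        dec = decode(st, polish=False)
        assert sorted(dec.calls["a"]) == [4, 6]

    def test_small_instance_matches_enumeration(self, rng):
        params = MutationParams(8e-4)
        samples = ["a", "b"]
        tree = simulate_coalescent_tree(4, params, rng,
                                        leaf_labels=haplotype_labels(samples))
        f = rng.random((2, 3, 3))
        f = f + np.swapaxes(f, 1, 2)
        facs = {"a": f[0], "b": f[1]}
        ens = TreeEnsemble([tree])
        st = BPState(f, samples, ens, params, 4, 6, 5)
        run_loopy(st, 10)
        run_mixed_product(st, 10)
        dec = decode(st)
        oracle = brute_force_marginal_map(facs, ens, params, 4, 6, ref_repeat=5)
        got = config_objective(dec.calls, facs, ens, params, 4, 6)
        best = config_objective(oracle.calls, facs, ens, params, 4, 6)
        assert got >= 0.99 * best


class TestEstimateRepeats:
    def test_reduction_to_basic_model(self, rng, default_F):
        from strlink.insert_model import basic_model_estimate
        from strlink.pipeline import DEFAULT_REGION, SimulationConfig, simulate_observations

        cfg = SimulationConfig(I=1, coverage=20, mu_s=2.73e-4)
        obs = simulate_observations({"s0": (20, 25)}, cfg, rng)
        ens = TreeEnsemble([pair_tree("s0", 1e22)])  # flat transitions
        res = estimate_repeats(obs, ens, DEFAULT_REGION, default_F,
                               MutationParams(2.73e-4), 0, 40)
        basic = basic_model_estimate(obs["s0"], DEFAULT_REGION, default_F, 0, 40)
        assert sorted(res.calls["s0"]) == [basic.n1, basic.n2]

    def test_readless_individual_inherits_clade(self, default_F):
        from strlink.pipeline import DEFAULT_REGION, SimulationConfig, simulate_observations

        rng = np.random.default_rng(5)
        cfg = SimulationConfig(I=3, coverage=40, mu_s=2.73e-4)
        truth = {"a": (21, 21), "b": (21, 21)}
        obs = simulate_observations(truth, cfg, rng)
        obs["c"] = []  # read-less
        nwk = ("(((a_1:0.01,a_2:0.01):0.01,(b_1:0.01,b_2:0.01):0.01):0.02,"
               "(c_1:0.03,c_2:0.03):0.01);")
        tree = read_newick(nwk)
        ens = TreeEnsemble([tree])
        params = MutationParams(1e-5)
        res = estimate_repeats(obs, ens, DEFAULT_REGION, default_F, params, 18, 24)
        # near-identity transitions force one clade-wide state; the read-less
        # individual inherits it
        assert res.calls["c"] == res.calls["a"] == res.calls["b"]
        table = build_normalization_table(DEFAULT_REGION, default_F, 18, 24)
        facs = {s: build_diploid_factor(obs[s], DEFAULT_REGION, default_F, 18, 24, table)
                for s in ("a", "b", "c")}
        oracle = brute_force_marginal_map(facs, ens, params, 18, 24,
                                          ref_repeat=DEFAULT_REGION.ref_repeat)
        assert res.calls["c"] == oracle.calls["c"]

    def test_unmatched_sample_error(self, default_F):
        from strlink.pipeline import DEFAULT_REGION

        ens = TreeEnsemble([pair_tree("a", 1.0)])
        with pytest.raises(LeafSampleMismatchError):
            estimate_repeats({"zz": []}, ens, DEFAULT_REGION, default_F,
                             MutationParams(1e-3), 0, 40)

    def test_label_equivariance(self, rng, default_F):
        from strlink.pipeline import DEFAULT_REGION, SimulationConfig, simulate_observations

        params = MutationParams(2.73e-4)
        samples = ["a", "b"]
        tree = simulate_coalescent_tree(4, params, rng,
                                        leaf_labels=haplotype_labels(samples))
        cfg = SimulationConfig(I=2, coverage=20, mu_s=2.73e-4)
        truth = {"a": (20, 22), "b": (25, 25)}
        obs = simulate_observations(truth, cfg, rng)
        r1 = estimate_repeats(dict(obs), TreeEnsemble([tree]), DEFAULT_REGION,
                              default_F, params, 0, 40)
        r2 = estimate_repeats({k: obs[k] for k in reversed(list(obs))},
                              TreeEnsemble([tree]), DEFAULT_REGION,
                              default_F, params, 0, 40)
        assert r1.calls == r2.calls


class TestBruteForce:
    def test_single_individual_flat_tree_matches_factor_argmax(self):
        ens = TreeEnsemble([pair_tree("a", 1e22)])
        f = np.zeros((3, 3))
        f[1, 2] = f[2, 1] = 1.0
        f += 0.01
        res = brute_force_marginal_map({"a": f}, ens, MutationParams(1e-3), 4, 6,
                                       ref_repeat=5)
        assert sorted(res.calls["a"]) == [5, 6]

    def test_scale_invariance(self, rng):
        params = MutationParams(1e-3)
        samples = ["a", "b"]
        trees = [simulate_coalescent_tree(4, params, rng,
                                          leaf_labels=haplotype_labels(samples))
                 for _ in range(2)]
        ens = TreeEnsemble(trees)
        f = rng.random((3, 3))
        f = f + f.T
        facs = {"a": f, "b": f.copy()}
        r1 = brute_force_marginal_map(facs, ens, params, 4, 6, ref_repeat=5)
        facs_scaled = {"a": 7.3 * f, "b": f.copy()}
        r2 = brute_force_marginal_map(facs_scaled, ens, params, 4, 6, ref_repeat=5)
        assert r1.calls == r2.calls

    def test_refuses_large_state_space(self):
        ens = TreeEnsemble([pair_tree("a", 1.0)])
        with pytest.raises(ValueError):
            brute_force_marginal_map({"a": np.ones((50, 50))}, ens,
                                     MutationParams(1e-3), 0, 49, max_configs=100)
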