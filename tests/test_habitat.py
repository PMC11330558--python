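"""Mk likelihoods, stochastic mapping, rjMCMC and regime paintings."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from eurysize import habitat as H
from eurysize.simulate import simulate_discrete
from eurysize.trees import Phylogeny, RegimeMap

from .conftest import random_tree

STATES2 = ("a", "b")
STATES3 = ("a", "b", "c")
Q3 = np.array([[-0.3, 0.2, 0.1], [0.15, -0.25, 0.1], [0.05, 0.2, -0.25]])


def _enumeration_loglik(tree, tips, Q, states, root_prior_vec):
    """Brute-force sum over all internal-node state assignments."""
    sidx = {s: i for i, s in enumerate(states)}
    P = {v: expm(Q * tree.length[v]) for v in range(tree.n_nodes) if v != tree.root}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    total = 0.0
    for combo in itertools.product(range(len(states)), repeat=len(internal)):
        st = dict(zip(internal, combo))
        for v in tree.tips:
            st[v] = sidx[tips[tree.labels[v]]]
        p = root_prior_vec[st[tree.root]]
        for v in range(tree.n_nodes):
            if v != tree.root:
                p *= P[v][st[tree.parent[v]], st[v]]
        total += p
    return np.log(total)


class TestMkLoglik:
    def test_zero_rates_probability_one(self, six_tip):
        tips = {lb: "a" for lb in six_tip.tip_labels}
        ll = H.mk_loglik(six_tip, tips, np.zeros((2, 2)), STATES2, root_prior="a")
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_single_branch_closed_form(self):
        q, t = 0.1, 5.0
        tree = Phylogeny(parent=[-1, 0], length=[np.nan, t], labels=[None, "A"])
        Q = np.array([[-q, q], [q, -q]])
        ll = H.mk_loglik(tree, {"A": "a"}, Q, STATES2, root_prior="a")
        assert np.exp(ll) == pytest.approx(0.5 + 0.5 * np.exp(-2 * q * t), abs=1e-12)
        assert np.exp(ll) == pytest.approx(0.683940, abs=1e-6)

    def test_matches_exhaustive_enumeration(self, six_tip):
        rng = np.random.default_rng(3)
        tips = {lb: STATES3[rng.integers(3)] for lb in six_tip.tip_labels}
        ll = H.mk_loglik(six_tip, tips, Q3, STATES3, root_prior="uniform")
        want = _enumeration_loglik(six_tip, tips, Q3, STATES3, np.full(3, 1 / 3))
        assert ll == pytest.approx(want, abs=1e-10)

    def test_missing_state_is_ambiguous(self, six_tip):
        tips = {lb: "a" for lb in six_tip.tip_labels}
        tips[six_tip.tip_labels[0]] = "?"
        full = sum(
            np.exp(H.mk_loglik(six_tip, {**tips, six_tip.tip_labels[0]: s},
                               Q3, STATES3, "uniform"))
            for s in STATES3
        )
        amb = np.exp(H.mk_loglik(six_tip, tips, Q3, STATES3, "uniform"))
        assert amb == pytest.approx(full, rel=1e-10)


class TestStochasticMapping:
    def test_node_marginals_match_enumeration(self, three_tip):
        """Empirical node-state frequencies across many maps agree with the
        exact marginal posteriors computed by enumeration."""
        q = 0.25
        Q = np.array([[-q, q], [q, -q]])
        tips = {"A": "a", "B": "b", "C": "a"}
        n_maps = 8000
        maps = H.stochastic_map(three_tip, tips, Q, STATES2, n_maps=n_maps, seed=3)
        freq = np.zeros((three_tip.n_nodes, 2))
        for mp in maps:
            for v, s in enumerate(mp.node_regime):
                freq[v, STATES2.index(s)] += 1
        freq /= n_maps
        # exact marginals by enumerating internal assignments
        P = {v: expm(Q * three_tip.length[v]) for v in range(three_tip.n_nodes)
             if v != three_tip.root}
        internal = [v for v in range(three_tip.n_nodes) if three_tip.children[v]]
        sidx = {s: i for i, s in enumerate(STATES2)}
        post = np.zeros((three_tip.n_nodes, 2))
        for combo in itertools.product(range(2), repeat=len(internal)):
            st = dict(zip(internal, combo))
            for v in three_tip.tips:
                st[v] = sidx[tips[three_tip.labels[v]]]
            p = 0.5
            for v in range(three_tip.n_nodes):
                if v != three_tip.root:
                    p *= P[v][st[three_tip.parent[v]], st[v]]
            for v in internal:
                post[v, st[v]] += p
        post[internal] /= post[internal].sum(axis=1, keepdims=True)
        for v in internal:
            assert np.max(np.abs(freq[v] - post[v])) <= 0.025

    def test_transitions_at_least_parsimony(self, six_tip):
        tips = dict(zip(six_tip.tip_labels, ["a", "a", "b", "b", "a", "b"]))
        maps = H.stochastic_map(six_tip, tips, np.array([[-0.05, 0.05], [0.05, -0.05]]),
                                STATES2, n_maps=300, seed=5)
        # Fitch parsimony minimum for this tip configuration
        pars = _fitch_length(six_tip, tips)
        for mp in maps:
            assert mp.n_transitions() >= pars

    def test_maps_consistent_with_tips(self, six_tip):
        rng = np.random.default_rng(11)
        tips = {lb: STATES3[rng.integers(3)] for lb in six_tip.tip_labels}
        maps = H.stochastic_map(six_tip, tips, Q3, STATES3, n_maps=50, seed=6)
        for mp in maps:
            mp.validate()
            for t in six_tip.tips:
                assert mp.node_regime[t] == tips[six_tip.labels[t]]

    def test_deterministic(self, six_tip):
        tips = dict(zip(six_tip.tip_labels, ["a", "a", "b", "b", "a", "b"]))
        Q = np.array([[-0.1, 0.1], [0.1, -0.1]])
        a = H.stochastic_map(six_tip, tips, Q, STATES2, n_maps=20, seed=7)
        b = H.stochastic_map(six_tip, tips, Q, STATES2, n_maps=20, seed=7)
        assert [m.segments for m in a] == [m.segments for m in b]


def _fitch_length(tree, tips):
    sets = {}
    changes = 0
    for v in tree.postorder():
        if not tree.children[v]:
            sets[v] = {tips[tree.labels[v]]}
            continue
        inter = None
        for c in tree.children[v]:
            inter = sets[c] if inter is None else inter & sets[c]
        if inter:
            sets[v] = inter
        else:
            union = set()
            for c in tree.children[v]:
                union |= sets[c]
            sets[v] = union
            changes += 1
    return changes


class TestSummaries:
    def test_single_map_bands_collapse(self, six_tip):
        tips = dict(zip(six_tip.tip_labels, ["a", "a", "b", "b", "a", "b"]))
        maps = H.stochastic_map(six_tip, tips, np.array([[-0.1, 0.1], [0.1, -0.1]]),
                                STATES2, n_maps=1, seed=1)
        summ = H.summarize_maps(maps)
        assert np.array_equal(summ.ltt["median"], summ.ltt["lo"])
        assert np.array_equal(summ.ltt["median"], summ.ltt["hi"])

    def test_state_counts_conserve_lineage_count(self, six_tip):
        rng = np.random.default_rng(2)
        tips = {lb: STATES3[rng.integers(3)] for lb in six_tip.tip_labels}
        maps = H.stochastic_map(six_tip, tips, Q3, STATES3, n_maps=30, seed=3)
        summ = H.summarize_maps(maps)
        live = np.zeros(summ.grid.size)
        for v in range(six_tip.n_nodes):
            if v == six_tip.root:
                continue
            older, younger = six_tip.branch_age_interval(v)
            live += (summ.grid < older) & (summ.grid >= younger)
        assert np.allclose(summ.counts.sum(axis=1), live[None, :])

    def test_hand_built_transition_shifts_counts(self):
        t = Phylogeny.from_newick("(A:4,B:4);")
        segs = [[] if i == t.root else ([(1.0, "a"), (3.0, "b")] if t.labels[i] == "A"
                                        else [(4.0, "a")]) for i in range(t.n_nodes)]
        mp = RegimeMap(t, segs)
        summ = H.summarize_maps([mp], time_grid=np.array([3.5, 2.5]))
        # ages: transition on A's branch at age 3.0; at age 3.5 both 'a',
        # at age 2.5 one 'a' one 'b'
        by = {(r.state, r.age_ma): r["median"] for _, r in summ.ltt.iterrows()}
        assert by[("a", 3.5)] == 2 and by.get(("b", 3.5), 0) == 0
        assert by[("a", 2.5)] == 1 and by[("b", 2.5)] == 1


class TestColonizations:
    def test_no_target_segments(self, six_tip):
        mp = RegimeMap(six_tip, [[] if i == six_tip.root else
                                 [(float(six_tip.length[i]), "a")]
                                 for i in range(six_tip.n_nodes)])
        assert H.count_colonizations([mp], "c")["median"] == 0

    def test_hand_built_three_entries(self):
        t = Phylogeny.from_newick("((A:2,B:2):2,(C:2,D:2):2);")
        segs = [[] for _ in range(t.n_nodes)]
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            L = float(t.length[v])
            if t.labels[v] in ("A", "B", "C"):
                segs[v] = [(L / 2, "m"), (L / 2, "cont")]
            else:
                segs[v] = [(L, "m")]
        mp = RegimeMap(t, segs)
        assert H.count_colonizations([mp], "cont")["median"] == 3

    def test_counts_match_forward_simulation_truth(self, six_tip):
        """Mean colonization count over unconditional histories equals the
        forward-simulation expectation (same process, the histories ARE
        forward simulations)."""
        Q = np.array([[-0.2, 0.2, 0.0], [0.15, -0.3, 0.15], [0.0, 0.1, -0.1]])
        n = 600
        counts = []
        truth = []
        for seed in range(n):
            _, rm = simulate_discrete(six_tip, Q, STATES3, "a", seed=seed)
            truth.append(sum(1 for segs in rm.segments
                             for p, q in zip(segs, segs[1:]) if q[1] == "c"))
        got = H.count_colonizations(
            [simulate_discrete(six_tip, Q, STATES3, "a", seed=10_000 + s)[1]
             for s in range(n)], "c")
        t_mean = float(np.mean(truth))
        se = np.std(truth, ddof=1) / np.sqrt(n) * np.sqrt(2)
        assert abs(got["mean"] - t_mean) <= 3 * se + 1e-9


class TestPaintings:
    def test_two_peak_merges_marine_and_continental(self, six_tip):
        segs = [[] if i == six_tip.root else
                [(float(six_tip.length[i]) / 3, "marine"),
                 (float(six_tip.length[i]) / 3, "marginal"),
                 (float(six_tip.length[i]) / 3, "continental")]
                for i in range(six_tip.n_nodes)]
        mp = RegimeMap(six_tip, segs)
        two = H.paint_habitat_regimes(mp, "two_peak")
        assert set(two.regimes()) == {"other", "marginal"}
        for v in range(six_tip.n_nodes):
            if v != six_tip.root:
                assert [s for _, s in two.segments[v]] == ["other", "marginal", "other"]
        # segment lengths conserved
        assert sum(two.dwell_times().values()) == pytest.approx(
            sum(mp.dwell_times().values()), abs=1e-12)

    def test_all_marginal_single_regime(self, six_tip):
        segs = [[] if i == six_tip.root else [(float(six_tip.length[i]), "marginal")]
                for i in range(six_tip.n_nodes)]
        two = H.paint_habitat_regimes(RegimeMap(six_tip, segs), "two_peak")
        assert two.regimes() == ["marginal"]

    def test_crisis_split_arithmetic(self):
        t = Phylogeny.from_newick("(A:10,B:10);", root_age_ma=20.0)
        # branch spans ages 20 -> 10; crisis 4 Myr above the child end
        rm = H.paint_crisis_regimes(t, 14.0, ["A"], ["B"])
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            assert rm.segments[v][0] == (6.0, "PRE")
            assert rm.segments[v][1][0] == pytest.approx(4.0)
        rm.validate()

    def test_crisis_older_than_root(self, six_tip):
        rm = H.paint_crisis_regimes(six_tip, six_tip.root_age_ma + 5,
                                    ["A", "B"], ["E", "F"])
        # every segment is painted by clade membership alone
        assert set(rm.regimes()) <= {"S1", "S2", "PRE"}
        assert sum(rm.dwell_times().values()) == pytest.approx(six_tip.total_length())

    def test_crisis_younger_than_tips(self, six_tip):
        rm = H.paint_crisis_regimes(six_tip, -5.0, ["A", "B"], ["E", "F"])
        assert rm.regimes() == ["PRE"]

    def test_overlapping_clades_error(self, six_tip):
        with pytest.raises(ValueError, match="overlap"):
            H.paint_crisis_regimes(six_tip, 1.0, ["A", "B"], ["B", "C"])


class TestSerialization:
    def test_simmap_newick_lists_segments_rootward_first(self):
        t = Phylogeny.from_newick("(A:4,B:4);")
        segs = [[] if i == t.root else
                ([(1.0, "a"), (3.0, "b")] if t.labels[i] == "A" else [(4.0, "a")])
                for i in range(t.n_nodes)]
        out = RegimeMap(t, segs).to_simmap_newick()
        assert "{a,1.0:b,3.0}" in out and "{a,4.0}" in out
        # segment table round-trips lengths exactly
        tab = RegimeMap(t, segs).to_table()
        assert tab["length_myr"].sum() == pytest.approx(8.0)


class TestRjmcmc:
    def test_same_seed_same_stream(self, six_tip):
        tips = dict(zip(six_tip.tip_labels, ["a", "a", "b", "b", "a", "c"]))
        a = H.rjmcmc_mk(six_tip, tips, STATES3, n_iter=1500, seed=3)
        b = H.rjmcmc_mk(six_tip, tips, STATES3, n_iter=1500, seed=3)
        assert a.samples["lnL"].equals(b.samples["lnL"])
        assert a.modal_structure == b.modal_structure

    def test_prior_stationarity_no_data(self):
        """With no data the chain must target the uniform prior over the
        5 canonical structures of the 2-entry (2-state) space."""
        t = Phylogeny.from_newick("(A:1,B:1);")
        res = H.rjmcmc_mk(t, None, STATES2, n_iter=200_000, burnin=20_000,
                          thin=5, seed=1)
        freq = res.structure_freq
        assert len(freq) == 5
        p = freq.to_numpy()
        kl = float(np.sum(p * np.log(p / (1.0 / 5))))
        assert kl <= 0.01
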