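"""Trait-model likelihoods against independent oracles, plus fitting."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from eurysize import models as M
from eurysize.envcurves import fit_smoothing_spline
from eurysize.simulate import simulate_continuous
from eurysize.trees import Phylogeny, RegimeMap

from .conftest import random_tree


def _whole_tree_regime(tree, regime="r"):
    segs = [[] if i == tree.root else [(float(tree.length[i]), regime)]
            for i in range(tree.n_nodes)]
    return RegimeMap(tree, segs)


def _flat_curve(level, lo=200.0, hi=500.0):
    ages = np.linspace(lo, hi, 31)
    return fit_smoothing_spline(np.c_[ages, np.full(31, level)], smoothing=0.0)


class TestGaussianExamples:
    def test_bm_two_tips_at_mean(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        ll = M.loglik_gaussian(t, [0.0, 0.0], "BM", {"z0": 0.0, "sigma2": 1.0})
        assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_kappa_one_equals_bm(self, six_tip):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(6)
        a = M.loglik_gaussian(six_tip, x, "KAPPA", {"z0": 0.1, "sigma2": 0.8, "kappa": 1.0})
        b = M.loglik_gaussian(six_tip, x, "BM", {"z0": 0.1, "sigma2": 0.8})
        assert a == pytest.approx(b, abs=1e-10)

    def test_ou_against_integral_oracle(self):
        """OU mean/covariance rebuilt entry-by-entry from the closed-form
        integrals and evaluated with scipy's MVN density."""
        t = random_tree(6, seed=21)
        rng = np.random.default_rng(2)
        x = rng.standard_normal(t.n_tips)
        z0, s2, a, th = 0.4, 1.3, 0.35, -0.2
        ll = M.loglik_gaussian(t, x, "OU", {"z0": z0, "sigma2": s2, "alpha": a,
                                            "theta": th})
        T = t.tip_depths
        Mm = t.shared_path_matrix()
        n = t.n_tips
        mean = np.empty(n)
        cov = np.empty((n, n))
        for i in range(n):
            mean[i] = th + (z0 - th) * np.exp(-a * T[i])
            for j in range(n):
                ta = Mm[i, j]
                cov[i, j] = (s2 / (2 * a) * np.exp(-a * (T[i] - ta)) *
                             np.exp(-a * (T[j] - ta)) * (1 - np.exp(-2 * a * ta)))
        want = multivariate_normal(mean=mean, cov=cov).logpdf(x)
        assert ll == pytest.approx(want, abs=1e-8)

    def test_loglik_invariant_to_tip_order(self, six_tip):
        rng = np.random.default_rng(3)
        x = dict(zip(six_tip.tip_labels, rng.standard_normal(6)))
        import dendropy

        # a rotated version of the same topology
        rot = Phylogeny.from_newick(
            "((E:2.1,F:0.7):0.4,((C:0.9,D:1.4):0.3,(A:1.2,B:0.8):0.6):0.5);")
        for name, par in [("BM", {"z0": 0, "sigma2": 1}),
                          ("OU", {"z0": 0, "sigma2": 1, "alpha": 0.4, "theta": 1}),
                          ("EB", {"z0": 0, "sigma2": 1, "r_eb": -0.2})]:
            a = M.loglik_gaussian(six_tip, x, name, par)
            b = M.loglik_gaussian(rot, x, name, par)
            assert a == pytest.approx(b, abs=1e-10)

    def test_singular_covariance_raises(self, three_tip):
        with pytest.raises(ValueError, match="singular"):
            M.loglik_gaussian(three_tip, [0, 0, 0], "BM", {"z0": 0, "sigma2": 0.0})


class TestNestingIdentities:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_reductions(self, seed):
        t = random_tree(7, seed=400 + seed)
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(t.n_tips)
        bm = M.loglik_gaussian(t, x, "BM", {"z0": 0.2, "sigma2": 1.1})
        assert M.loglik_gaussian(t, x, "KAPPA", {"z0": 0.2, "sigma2": 1.1, "kappa": 1.0}) \
            == pytest.approx(bm, abs=1e-8)
        assert M.loglik_gaussian(t, x, "EB", {"z0": 0.2, "sigma2": 1.1, "r_eb": 0.0}) \
            == pytest.approx(bm, abs=1e-8)
        assert M.loglik_gaussian(t, x, "TREND", {"z0": 0.2, "sigma2": 1.1, "mu_trend": 0.0}) \
            == pytest.approx(bm, abs=1e-8)
        assert M.loglik_pulsed(t, x, {"z0": 0.2, "sigma2": 1.1, "lam_jump": 0.0,
                                      "delta2": 5.0}) == pytest.approx(bm, abs=1e-9)
        ou = M.loglik_gaussian(t, x, "OU", {"z0": 0.2, "sigma2": 1.1, "alpha": 0.5,
                                            "theta": 0.9})
        env = M.loglik_env_ou(t, x, {"z0": 0.2, "sigma2": 1.1, "alpha": 0.5,
                                     "theta0": 0.9, "beta": 0.0},
                              _flat_curve(7.0, 0.0, t.root_age_ma + 1.0))
        assert env == pytest.approx(ou, abs=1e-8)
        reg = _whole_tree_regime(t)
        oum = M.loglik_oum(reg, x, {"z0": 0.2, "sigma2": 1.1, "alpha": 0.5,
                                    "theta": {"r": 0.9}})
        assert oum == pytest.approx(ou, abs=1e-8)
        # OU -> BM in the weak-selection limit
        ou0 = M.loglik_gaussian(t, x, "OU", {"z0": 0.2, "sigma2": 1.1,
                                             "alpha": 1e-8, "theta": 0.9})
        assert ou0 == pytest.approx(bm, abs=1e-4)


class TestPulsed:
    def test_single_branch_truncated_series(self):
        """One tip at its root value: lnL = ln sum_k pois(k;1) N(0; 0, 1+k)."""
        t = Phylogeny(parent=[-1, 0], length=[np.nan, 1.0], labels=[None, "A"])
        ll = M.loglik_pulsed(t, [0.0], {"z0": 0.0, "sigma2": 1.0,
                                        "lam_jump": 1.0, "delta2": 1.0})
        k = np.arange(60)
        from scipy.special import gammaln

        terms = (-1.0 + k * 0.0 + -gammaln(k + 1)) + \
            (-0.5 * (np.log(2 * np.pi * (1.0 + k))))
        want = float(np.log(np.exp(terms).sum()))
        assert ll == pytest.approx(want, abs=1e-8)

    def test_monte_carlo_oracle_four_tips(self):
        """Pulsed likelihood vs a Monte-Carlo average over jump-count
        configurations (exact conditional MVN given the counts)."""
        t = random_tree(4, seed=77)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4) * 0.8
        params = {"z0": 0.1, "sigma2": 0.4, "lam_jump": 0.3, "delta2": 2.0}
        ll = M.loglik_pulsed(t, x, params)
        mc, se = _pulsed_mc_loglik(t, x, params, n_draws=200_000, seed=6)
        assert abs(ll - mc) <= 3 * se

    def test_negative_rates_rejected(self, three_tip):
        with pytest.raises(ValueError):
            M.loglik_pulsed(three_tip, [0, 0, 0],
                            {"z0": 0, "sigma2": 1, "lam_jump": -1, "delta2": 1})


def _pulsed_mc_loglik(tree, x, params, n_draws, seed):
    """MC oracle: draw Poisson jump counts per branch, average the exact
    conditional Gaussian density.  Returns (log mean, SE on the log scale)."""
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    edges = [v for v in range(tree.n_nodes) if v != tree.root]
    # indicator: which branches lie on the root-to-tip path of each tip
    on_path = np.zeros((n, len(edges)))
    for pos, tip in enumerate(tree.tips):
        v = tip
        while v != tree.root:
            on_path[pos, edges.index(v)] = 1.0
            v = int(tree.parent[v])
    lens = np.array([float(tree.length[v]) for v in edges])
    lam, d2, s2, z0 = params["lam_jump"], params["delta2"], params["sigma2"], params["z0"]
    dev = np.asarray(x, float) - z0
    batch = 20_000
    vals = []
    done = 0
    while done < n_draws:
        b = min(batch, n_draws - done)
        ks = rng.poisson(lam * lens, size=(b, len(edges)))
        bv = s2 * lens + ks * d2  # per-branch displacement variance
        cov = np.einsum("ie,be,je->bij", on_path, bv, on_path)
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        sol = np.linalg.solve(L, np.broadcast_to(dev, (b, n))[..., None])[..., 0]
        logdet = 2 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
        logpdf = -0.5 * (n * np.log(2 * np.pi) + logdet + (sol ** 2).sum(axis=1))
        vals.append(logpdf)
        done += b
    logpdf = np.concatenate(vals)
    mx = logpdf.max()
    w = np.exp(logpdf - mx)
    mean = w.mean()
    se_lin = w.std(ddof=1) / np.sqrt(len(w))
    return mx + np.log(mean), se_lin / mean


class TestEnvOu:
    def test_constant_curve_absorbs_into_theta(self, six_tip):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(6)
        curve = _flat_curve(5.0, 0.0, six_tip.root_age_ma + 1)
        env = M.loglik_env_ou(six_tip, x, {"z0": 0.0, "sigma2": 1.0, "alpha": 0.7,
                                           "theta0": 0.2, "beta": 0.5}, curve)
        ou = M.loglik_gaussian(six_tip, x, "OU", {"z0": 0.0, "sigma2": 1.0,
                                                  "alpha": 0.7, "theta": 2.7})
        assert env == pytest.approx(ou, abs=1e-8)

    def test_linear_ramp_means_match_fine_ode(self):
        """Tip means under a linearly ramping optimum match an RK4
        integration of dm/dt = alpha (theta(t) - m) at a 1e-3 Myr step."""
        t = Phylogeny.from_newick("(A:6,B:10);", root_age_ma=100.0)
        ages = np.linspace(80.0, 110.0, 31)
        slope, icpt = 0.3, -20.0
        curve = fit_smoothing_spline(np.c_[ages, icpt + slope * ages], smoothing=0.0)
        z0, a, th0, beta = 1.0, 0.22, 0.5, 0.8
        mean = M._env_ou_means(t.tip_depths, z0, a, th0, beta, curve, 100.0, 0.25)

        def theta(s):  # s = time since the root
            return th0 + beta * (icpt + slope * (100.0 - s))

        for pos, T in enumerate(t.tip_depths):
            h = 1e-3
            m = z0
            s = 0.0
            while s < T - 1e-12:
                step = min(h, T - s)
                k1 = a * (theta(s) - m)
                k2 = a * (theta(s + step / 2) - (m + step / 2 * k1))
                k3 = a * (theta(s + step / 2) - (m + step / 2 * k2))
                k4 = a * (theta(s + step) - (m + step * k3))
                m += step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                s += step
            assert mean[pos] == pytest.approx(m, abs=1e-6)

    def test_out_of_range_curve_errors(self, six_tip):
        curve = _flat_curve(5.0, 0.0, 1.0)  # far too short for the tree
        with pytest.raises(ValueError, match="outside"):
            M.loglik_env_ou(six_tip, np.zeros(6),
                            {"z0": 0, "sigma2": 1, "alpha": 0.5, "theta0": 0,
                             "beta": 1.0}, curve)


class TestOum:
    def test_strong_pull_means_reach_regime_optima(self):
        """With alpha * path >> 1 and regime-pure paths, tip means approach
        their regime's optimum."""
        t = Phylogeny.from_newick("(A:50,B:50);")
        segs = [[], [(50.0, "hot")], [(50.0, "cold")]]
        segs = [[] if i == t.root else [(50.0, "hot" if t.labels[i] == "A" else "cold")]
                for i in range(t.n_nodes)]
        reg = RegimeMap(t, segs)
        mean, cov = M.oum_mean_cov(reg, {"z0": 0.0, "sigma2": 0.1, "alpha": 1.0,
                                         "theta": {"hot": 4.0, "cold": -4.0}})
        by = dict(zip(t.tip_labels, mean))
        assert by["A"] == pytest.approx(4.0, abs=1e-4)
        assert by["B"] == pytest.approx(-4.0, abs=1e-4)

    def test_against_segment_recursion_oracle(self):
        """5-tip painted tree vs an independent entry-by-entry recursion for
        E[X] and Cov computed along explicit root-to-tip segment lists."""
        t = random_tree(5, seed=31)
        rng = np.random.default_rng(8)
        # paint each branch with 2 random segments
        segs = [[] for _ in range(t.n_nodes)]
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            L = float(t.length[v])
            cut = rng.uniform(0.2, 0.8) * L
            segs[v] = [(cut, rng.choice(["p", "q"])), (L - cut, rng.choice(["p", "q"]))]
        reg = RegimeMap(t, segs)
        params = {"z0": 0.3, "sigma2": {"p": 0.5, "q": 1.5},
                  "alpha": {"p": 0.15, "q": 0.6},
                  "theta": {"p": 2.0, "q": -1.0}}
        mean, cov = M.oum_mean_cov(reg, params)

        # oracle: explicit per-tip path segment lists
        def path_segments(tip):
            out = []
            v = tip
            chain = []
            while v != t.root:
                chain.append(v)
                v = int(t.parent[v])
            for v in reversed(chain):
                out.extend(segs[v])
            return out

        def moments(tip):
            m, var, disc = 0.3, 0.0, 1.0
            marks = []  # (cumulative discount after segment, var at end)
            for L, r in path_segments(tip):
                a, s2, th = params["alpha"][r], params["sigma2"][r], params["theta"][r]
                e = np.exp(-a * L)
                m = m * e + th * (1 - e)
                var = var * e * e + s2 * (1 - np.exp(-2 * a * L)) / (2 * a)
                disc *= e
            return m, var

        for pos in range(t.n_tips):
            m_o, v_o = moments(t.tips[pos])
            assert mean[pos] == pytest.approx(m_o, abs=1e-8)
            assert cov[pos, pos] == pytest.approx(v_o, abs=1e-8)
        # off-diagonals: Cov(i,j) = Var(mrca) * disc_i * disc_j where the
        # discounts run from the mrca to each tip
        Mn = t.mrca_matrix()
        for i in range(t.n_tips):
            for j in range(i + 1, t.n_tips):
                anc = Mn[i, j]

                def disc_from(tip):
                    v, chain = tip, []
                    while v != anc:
                        chain.append(v)
                        v = int(t.parent[v])
                    d = 1.0
                    for v in chain:
                        for L, r in segs[v]:
                            d *= np.exp(-params["alpha"][r] * L)
                    return d

                def var_at_anc():
                    v, chain = anc, []
                    while v != t.root:
                        chain.append(v)
                        v = int(t.parent[v])
                    var = 0.0
                    for v in reversed(chain):
                        for L, r in segs[v]:
                            a, s2 = params["alpha"][r], params["sigma2"][r]
                            e = np.exp(-a * L)
                            var = var * e * e + s2 * (1 - np.exp(-2 * a * L)) / (2 * a)
                    return var

                want = var_at_anc() * disc_from(t.tips[i]) * disc_from(t.tips[j])
                assert cov[i, j] == pytest.approx(want, abs=1e-8)

    def test_unpainted_branch_error(self, three_tip):
        segs = [[] for _ in range(three_tip.n_nodes)]
        reg = RegimeMap.__new__(RegimeMap)
        reg.tree = three_tip
        reg.segments = segs
        reg.node_regime = [""] * three_tip.n_nodes
        with pytest.raises(ValueError, match="unpainted"):
            M.loglik_oum(reg, [0.0, 0.0, 0.0],
                         {"z0": 0, "sigma2": 1, "alpha": 0.5, "theta": {"r": 0}})


class TestFitting:
    def test_bm_rate_recovery_small(self):
        t = random_tree(40, seed=9)
        hats = []
        for rep in range(8):
            x = simulate_continuous(t, "BM", {"z0": 1.0, "sigma2": 2.0},
                                    seed=600 + rep)
            fit = M.fit_model(t, x, "BM", n_restarts=2, seed=1)
            hats.append(fit.params["sigma2"])
        assert 1.4 <= float(np.median(hats)) <= 2.6

    def test_trend_refused_on_ultrametric(self):
        from eurysize.simulate import simulate_fbd_tree

        t = simulate_fbd_tree(0.4, 0.0, 0.0, n_extant=10, seed=3)
        with pytest.raises(ValueError, match="ultrametric"):
            M.fit_model(t, np.zeros(10), "TREND")

    def test_aicc_precondition(self, three_tip):
        with pytest.raises(ValueError, match="n - k - 1"):
            M.fit_model(three_tip, [0.1, 0.2, 0.3], "OU")

    def test_unknown_model(self, three_tip):
        with pytest.raises(ValueError, match="unknown model"):
            M.fit_model(three_tip, [0.1, 0.2, 0.3], "JUMPY")

    def test_fit_deterministic(self):
        t = random_tree(20, seed=13)
        x = simulate_continuous(t, "BM", {"z0": 0.0, "sigma2": 1.0}, seed=4)
        a = M.fit_model(t, x, "KAPPA", n_restarts=3, seed=5)
        b = M.fit_model(t, x, "KAPPA", n_restarts=3, seed=5)
        assert a.params == b.params
        assert a.lnL == b.lnL
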