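"""Likelihoods and ML fitting for the 11 continuous trait-evolution models.

The trait is log body length (ln cm) evolving along a time-scaled,
generally non-ultrametric tree.  Models:

========== =============================================================
BM          Brownian motion: random walk, constant variance ``sigma2``.
TREND       BM plus directional drift ``mu_trend`` per Myr.
EB          early burst: rate ``sigma2 * exp(r_eb * t)``, t from the root.
KAPPA       branch lengths raised to the power ``kappa`` before BM
            (kappa = 0 is purely punctuational, kappa = 1 recovers BM).
OU          Ornstein-Uhlenbeck with pull ``alpha`` toward optimum
            ``theta``; the root state ``z0`` is a free parameter
            (fixed-root, non-stationary form - safe on fossil trees).
PULSED      BM plus compound-Poisson normal jumps: rate ``lam_jump`` per
            Myr, per-jump variance ``delta2``.
ENV_OU_*    OU whose optimum tracks an environmental curve linearly:
            theta(t) = theta0 + beta * E(t)  (TEMP / OXY variants differ
            only in which curve is attached).
OUM*        multi-peak OU on a regime painting: one optimum per regime
            (optionally regime-specific sigma2 and alpha).
========== =============================================================

All models except PULSED are Gaussian: the tip vector is multivariate
normal with a model-specific mean and covariance, evaluated exactly.  The
pulsed likelihood is computed by pruning over Gaussian-mixture messages
(see :func:`loglik_pulsed`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import qmc

from .envcurves import EnvCurve
from .selection import aicc
from .trees import Phylogeny, RegimeMap

__all__ = [
    "MODEL_NAMES",
    "GAUSSIAN_MODELS",
    "ModelFit",
    "param_count",
    "loglik_gaussian",
    "loglik_pulsed",
    "loglik_env_ou",
    "loglik_oum",
    "loglik",
    "fit_model",
]

GAUSSIAN_MODELS = ("BM", "OU", "TREND", "EB", "KAPPA")
ENV_MODELS = ("ENV_OU_TEMP", "ENV_OU_OXY")
OUM_MODELS = ("OUM3_HABITAT", "OUM2_HABITAT", "OUM3_CRISIS")
MODEL_NAMES = GAUSSIAN_MODELS + ("PULSED",) + ENV_MODELS + OUM_MODELS

_LOG2PI = float(np.log(2.0 * np.pi))

# documented parameter counts (shared-alpha/sigma2 OUM variant)
_BASE_K = {"BM": 2, "TREND": 3, "EB": 3, "KAPPA": 3, "OU": 4, "PULSED": 4,
           "ENV_OU_TEMP": 5, "ENV_OU_OXY": 5}

# optimizer bounds (natural scale)
BOUNDS = {
    "sigma2": (1e-8, 1e4),
    "alpha": (1e-8, 1e2),
    "kappa": (0.0, 3.0),
    "lam_jump": (1e-8, 10.0),
    "delta2": (1e-8, 1e4),
    "beta": (-1e2, 1e2),
    "mu_trend": (-10.0, 10.0),
}


def param_count(name: str, n_regimes: int | None = None, free_regime_dynamics: bool = False) -> int:
    """Number of free parameters k of a model, as used in AICc."""
    if name in _BASE_K:
        return _BASE_K[name]
    if name in OUM_MODELS:
        if n_regimes is None:
            n_regimes = 2 if name == "OUM2_HABITAT" else 3
        if free_regime_dynamics:
            return 1 + 3 * n_regimes  # z0 + per-regime theta, sigma2, alpha
        return 3 + n_regimes  # z0, sigma2, alpha + per-regime theta
    raise ValueError(f"unknown model {name!r}; supported: {MODEL_NAMES}")


@dataclass
class ModelFit:
    """Result of fitting one model to one tree."""

    model: str
    params: dict
    lnL: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_restarts_used: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {p: float(v) for p, v in self.params.items()},
            "lnL": float(self.lnL),
            "k": int(self.k),
            "n": int(self.n),
            "aicc": float(self.aicc),
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
            "seed": self.seed,
        }


# ------------------------------------------------------------------ Gaussian


def _mvn_loglik(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    n = x.size
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular model covariance (collinear tips or degenerate parameters)"
        ) from exc
    u = solve_triangular(L, x - mean, lower=True)
    return float(-0.5 * (n * _LOG2PI + u @ u) - np.sum(np.log(np.diag(L))))


def _transformed_shared_paths(tree: Phylogeny, kappa: float) -> np.ndarray:
    """Shared-path matrix after raising every branch length to power kappa."""
    depth_k = np.zeros(tree.n_nodes)
    for v in tree.preorder():
        if v != tree.root:
            depth_k[v] = depth_k[tree.parent[v]] + float(tree.length[v]) ** kappa
    return depth_k[tree.mrca_matrix()]


def gaussian_mean_cov(tree: Phylogeny, name: str, params: dict):
    """Exact MVN mean vector and covariance for BM/OU/TREND/EB/KAPPA."""
    z0 = params["z0"]
    s2 = params["sigma2"]
    T = tree.tip_depths
    n = tree.n_tips
    M = tree.shared_path_matrix()
    if name == "BM":
        return np.full(n, z0), s2 * M
    if name == "TREND":
        return z0 + params["mu_trend"] * T, s2 * M
    if name == "KAPPA":
        return np.full(n, z0), s2 * _transformed_shared_paths(tree, params["kappa"])
    if name == "EB":
        r = params["r_eb"]
        if abs(r) < 1e-12:
            C = M.copy()
        else:
            C = np.expm1(r * M) / r
        return np.full(n, z0), s2 * C
    if name == "OU":
        a = params["alpha"]
        th = params["theta"]
        mean = th + (z0 - th) * np.exp(-a * T)
        cov = _ou_fixed_root_cov(T, M, a, s2)
        return mean, cov
    raise ValueError(f"{name!r} is not a closed-form Gaussian model")


def _ou_fixed_root_cov(T: np.ndarray, M: np.ndarray, alpha: float, sigma2: float) -> np.ndarray:
    """Fixed-root OU covariance on a (possibly non-ultrametric) tree.

    Cov(i,j) = s2/(2a) * exp(-a*(T_i + T_j - 2*t_mrca)) * (1 - exp(-2a*t_mrca)).
    """
    if alpha < 1e-10:
        return sigma2 * M
    Ti = T[:, None]
    Tj = T[None, :]
    return (
        sigma2
        / (2.0 * alpha)
        * np.exp(-alpha * (Ti + Tj - 2.0 * M))
        * (-np.expm1(-2.0 * alpha * M))
    )


def loglik_gaussian(tree: Phylogeny, x, name: str, params: dict) -> float:
    """Exact log-likelihood for the closed-form Gaussian models."""
    xv = _tip_vector(tree, x)
    mean, cov = gaussian_mean_cov(tree, name, params)
    return _mvn_loglik(xv, mean, cov)


# ------------------------------------------------------------- environment OU


def loglik_env_ou(
    tree: Phylogeny,
    x,
    params: dict,
    curve: EnvCurve,
    root_age_ma: float | None = None,
    step_myr: float = 0.25,
) -> float:
    """OU log-likelihood with optimum tracking an environmental curve.

    theta(t) = theta0 + beta * E(age), integrated along each root-to-tip
    path on a ``step_myr`` grid.  All tips share one mean function of the
    root-to-tip time because the age axis is common to the whole tree.
    Covariance is the fixed-root OU covariance.  ``beta = 0`` collapses
    exactly to the standard OU model.
    """
    xv = _tip_vector(tree, x)
    z0, s2, a = params["z0"], params["sigma2"], params["alpha"]
    th0, beta = params["theta0"], params["beta"]
    root_age = tree.root_age_ma if root_age_ma is None else float(root_age_ma)
    T = tree.tip_depths
    mean = _env_ou_means(T, z0, a, th0, beta, curve, root_age, step_myr)
    cov = _ou_fixed_root_cov(T, tree.shared_path_matrix(), a, s2)
    return _mvn_loglik(xv, mean, cov)


def _env_ou_means(T, z0, alpha, theta0, beta, curve, root_age, step):
    """Integrate dm/dt = alpha*(theta(t) - m) exactly over a piecewise-linear
    interpolant of the curve on the step grid."""
    Tmax = float(np.max(T))
    grid = np.unique(np.concatenate([np.arange(0.0, Tmax, step), np.atleast_1d(T), [Tmax]]))
    ages = root_age - grid
    E = np.asarray(curve.value_at(ages))
    # J(t) = alpha * int_0^t exp(-alpha (t-s)) E(root_age - s) ds
    J = np.zeros(grid.size)
    for i in range(1, grid.size):
        h = grid[i] - grid[i - 1]
        e0, e1 = E[i - 1], E[i]
        b = (e1 - e0) / h
        em = -np.expm1(-alpha * h)  # 1 - exp(-a h)
        if alpha > 1e-10:
            inc = e1 * em - (b / alpha) * (1.0 - np.exp(-alpha * h) * (1.0 + alpha * h))
        else:
            inc = alpha * h * 0.5 * (e0 + e1)
        J[i] = J[i - 1] * (1.0 - em) + inc
    Jt = np.interp(T, grid, J)
    eaT = np.exp(-alpha * np.asarray(T, float))
    return z0 * eaT + theta0 * (1.0 - eaT) + beta * Jt


# ------------------------------------------------------------------ multi-peak


def loglik_oum(regimes: RegimeMap, x, params: dict) -> float:
    """Multi-peak OU log-likelihood on a painted tree.

    ``params`` carries ``z0`` plus per-regime optima ``theta`` (a mapping
    regime -> value).  ``sigma2`` and ``alpha`` may be scalars (shared) or
    mappings for the free-dynamics variant.  Means, variances and the
    between-lineage discounting are accumulated segment by segment along the
    painting; with all regimes identical this collapses to single-peak OU.
    """
    tree = regimes.tree
    xv = _tip_vector(tree, x)
    mean, cov = oum_mean_cov(regimes, params)
    return _mvn_loglik(xv, mean, cov)


def oum_mean_cov(regimes: RegimeMap, params: dict):
    tree = regimes.tree
    theta = params["theta"]
    alpha = params["alpha"]
    sigma2 = params["sigma2"]
    z0 = params["z0"]
    get_a = alpha.__getitem__ if isinstance(alpha, dict) else (lambda r: alpha)
    get_s = sigma2.__getitem__ if isinstance(sigma2, dict) else (lambda r: sigma2)

    n = tree.n_nodes
    m = np.zeros(n)
    V = np.zeros(n)
    logG = np.zeros(n)  # log of the cumulative discount exp(-int alpha)
    for v in tree.preorder():
        if v == tree.root:
            m[v] = z0
            continue
        p = tree.parent[v]
        mm, vv, lg = m[p], V[p], logG[p]
        segs = regimes.segments[v]
        if not segs:
            raise ValueError(f"unpainted branch above node {v}")
        for L, r in segs:
            try:
                a, s2, th = get_a(r), get_s(r), theta[r]
            except KeyError as exc:
                raise ValueError(f"regime {r!r} on branch above node {v} has no parameters") from exc
            e = np.exp(-a * L)
            one_m = -np.expm1(-a * L)
            mm = mm * e + th * one_m
            if a > 1e-10:
                vv = vv * e * e + s2 * (-np.expm1(-2.0 * a * L)) / (2.0 * a)
            else:
                vv = vv + s2 * L
            lg -= a * L
        m[v], V[v], logG[v] = mm, vv, lg
    Mn = tree.mrca_matrix()
    tips = np.asarray(tree.tips)
    lg_t = logG[tips]
    cov = V[Mn] * np.exp(lg_t[:, None] + lg_t[None, :] - 2.0 * logG[Mn])
    return m[tips], cov


# ---------------------------------------------------------------------- pulsed


def loglik_pulsed(
    tree: Phylogeny,
    x,
    params: dict,
    poisson_tail: float = 1e-10,
    weight_floor: float = 1e-12,
    max_components: int = 256,
    merge_tol: float = 0.01,
    max_dropped_mass: float = 1e-6,
) -> float:
    """Log-likelihood of BM plus compound-Poisson normal jumps, by pruning.

    The conditional likelihood at each node is a finite Gaussian mixture in
    the (unknown) node state.  Moving up a branch of length t convolves the
    mixture with ``Normal(0, sigma2*t + K*delta2)``, ``K ~ Poisson(lam_jump*t)``
    truncated at the smallest count with tail mass < ``poisson_tail``.
    Messages from sibling subtrees are multiplied (products of Gaussians are
    Gaussian up to a scalar).  Components below ``weight_floor`` of the
    current maximum are pruned (the discarded mass is tracked and must stay
    below ``max_dropped_mass``); near-coincident components — means within
    ``merge_tol`` local standard deviations and variances within a relative
    ``merge_tol`` — are merged by moment matching, which conserves the
    mixture mass.  If the mixture still exceeds ``max_components`` the merge
    resolution is coarsened adaptively.  With ``lam_jump = 0`` or
    ``delta2 = 0`` this reduces exactly to BM.
    """
    m, vv, lw = _pulsed_root_message(
        tree, _tip_vector(tree, x), params,
        poisson_tail=poisson_tail, weight_floor=weight_floor,
        max_components=max_components, merge_tol=merge_tol,
        max_dropped_mass=max_dropped_mass,
    )
    z0 = params["z0"]
    if np.any(vv <= 0):
        bad = vv <= 0
        if np.any(np.abs(m[bad] - z0) > 0):
            return -np.inf
        raise ValueError("zero-variance component at the root")
    return float(logsumexp(lw - 0.5 * (_LOG2PI + np.log(vv) + (z0 - m) ** 2 / vv)))


def _pulsed_root_message(
    tree: Phylogeny,
    xv: np.ndarray,
    params: dict,
    poisson_tail: float = 1e-10,
    weight_floor: float = 1e-12,
    max_components: int = 256,
    merge_tol: float = 0.01,
    max_dropped_mass: float = 1e-6,
    gauss_approx_rate: float = 25.0,
):
    """Gaussian-mixture message at the root (does not depend on z0).

    Branches whose expected jump count ``lam*t`` exceeds ``gauss_approx_rate``
    contribute a single moment-matched Gaussian (CLT regime) instead of the
    truncated Poisson mixture.
    """
    s2 = params["sigma2"]
    lam, d2 = params["lam_jump"], params["delta2"]
    if lam < 0 or d2 < 0:
        raise ValueError("lam_jump and delta2 must be non-negative")
    if lam * tree.total_length() > 2000.0:
        raise ValueError(
            "expected total jump count exceeds the mixture-pruning budget; "
            "lam_jump is implausibly high for this tree"
        )
    pure_bm = lam <= 0 or d2 <= 0
    tip_of = {t: k for k, t in enumerate(tree.tips)}
    dropped = 0.0

    def convolve(msg, t):
        m, v, lw = msg
        v_bm = s2 * t
        if pure_bm:
            return m, v + v_bm, lw
        rate = lam * t
        if rate > gauss_approx_rate:
            return m, v + v_bm + rate * d2, lw
        ks, logpk = _poisson_trunc(rate, poisson_tail)
        K = ks.size
        m2 = np.repeat(m, K)
        v2 = (v[:, None] + v_bm + ks[None, :] * d2).ravel()
        lw2 = (lw[:, None] + logpk[None, :]).ravel()
        return m2, v2, lw2

    def product(a, b):
        mA, vA, lwA = a
        mB, vB, lwB = b
        vs = vA[:, None] + vB[None, :]
        if np.any(vs <= 0):
            raise ValueError("degenerate zero-variance product in pulsed pruning")
        diff = mA[:, None] - mB[None, :]
        logf = -0.5 * (_LOG2PI + np.log(vs) + diff * diff / vs)
        m = (mA[:, None] * vB[None, :] + mB[None, :] * vA[:, None]) / vs
        v = vA[:, None] * vB[None, :] / vs
        lw = lwA[:, None] + lwB[None, :] + logf
        return m.ravel(), v.ravel(), lw.ravel()

    def compress(msg):
        nonlocal dropped
        m, v, lw = msg
        if m.size <= 1:
            return msg
        shift = lw.max()
        w = np.exp(lw - shift)  # weights relative to the largest component
        keep = w >= weight_floor
        if not np.all(keep):
            tot = w.sum()
            dropped += float(1.0 - w[keep].sum() / tot)
            m, v, w = m[keep], v[keep], w[keep]
        tol = merge_tol
        while m.size > 1:
            # bin by mean (in units of the local sd) and by log variance
            k1 = np.round(m / (tol * np.sqrt(v))).astype(np.int64)
            k2 = np.round(np.log(v) / tol).astype(np.int64)
            _, inv = np.unique(k1 * np.int64(1_000_003) + k2, return_inverse=True)
            ng = int(inv.max()) + 1
            if ng < m.size:
                wsum = np.bincount(inv, weights=w, minlength=ng)
                mb = np.bincount(inv, weights=w * m, minlength=ng) / wsum
                # moment matching: merged variance includes the mean spread
                ev2 = np.bincount(inv, weights=w * (v + m * m), minlength=ng) / wsum
                vb = np.maximum(ev2 - mb * mb, 1e-300)
                m, v, w = mb, vb, wsum
            if m.size <= max_components:
                break
            tol *= 4.0  # coarsen until under the component cap
        return m, v, np.log(w) + shift

    msgs: dict[int, tuple] = {}
    for v in tree.postorder():
        if not tree.children[v]:
            msgs[v] = (np.array([xv[tip_of[v]]]), np.array([0.0]), np.array([0.0]))
        else:
            acc = None
            for c in tree.children[v]:
                up = compress(convolve(msgs.pop(c), float(tree.length[c])))
                acc = up if acc is None else compress(product(acc, up))
            msgs[v] = acc
    if dropped > max_dropped_mass:
        raise ValueError(
            f"pulsed pruning discarded {dropped:.2e} of the mixture mass; "
            "lower weight_floor or raise max_components"
        )
    return msgs[tree.root]


def _poisson_trunc(rate: float, tail: float):
    """Counts 0..K and log-pmf with Poisson tail mass below ``tail``."""
    if rate <= 0:
        return np.array([0]), np.array([0.0])
    ks = [0]
    logp = [-rate]
    cdf = np.exp(-rate)
    lp = -rate
    k = 0
    while 1.0 - cdf > tail and k < 400:
        k += 1
        lp = lp + np.log(rate) - np.log(k)
        ks.append(k)
        logp.append(lp)
        cdf += np.exp(lp)
    return np.asarray(ks), np.asarray(logp)


# ------------------------------------------------------------------- dispatch


def loglik(
    tree: Phylogeny,
    x,
    name: str,
    params: dict,
    curve: EnvCurve | None = None,
    regimes: RegimeMap | None = None,
    root_age_ma: float | None = None,
) -> float:
    """Log-likelihood of any of the 11 models (dispatching on ``name``)."""
    if name in GAUSSIAN_MODELS:
        return loglik_gaussian(tree, x, name, params)
    if name == "PULSED":
        return loglik_pulsed(tree, x, params)
    if name in ENV_MODELS:
        if curve is None:
            raise ValueError(f"{name} requires an environmental curve")
        return loglik_env_ou(tree, x, params, curve, root_age_ma=root_age_ma)
    if name in OUM_MODELS:
        if regimes is None:
            raise ValueError(f"{name} requires a regime painting")
        return loglik_oum(regimes, x, params)
    raise ValueError(f"unknown model {name!r}; supported: {MODEL_NAMES}")


# -------------------------------------------------------------------- fitting


def _tip_vector(tree: Phylogeny, x) -> np.ndarray:
    if isinstance(x, dict):
        return np.array([x[lb] for lb in tree.tip_labels], dtype=float)
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = arr[None]
    if arr.shape[0] != tree.n_tips:
        raise ValueError(f"trait vector length {arr.shape[0]} != n_tips {tree.n_tips}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("trait vector must be complete (no NaN) on the tips")
    return arr


def _bm_moment_start(tree: Phylogeny, xv: np.ndarray):
    """Cheap moment-based starting values: GLS root and BM rate."""
    C = tree.shared_path_matrix()
    Ci = np.linalg.inv(C + 1e-12 * np.eye(len(xv)))
    one = np.ones(len(xv))
    z0 = float(one @ Ci @ xv / (one @ Ci @ one))
    s2 = float((xv - z0) @ Ci @ (xv - z0) / len(xv))
    return z0, max(s2, 1e-8)


def _free_param_layout(name: str, regimes: RegimeMap | None, free_regime_dynamics: bool):
    """Ordered (name, transform) pairs.  transform 'log' keeps positivity."""
    layout: list[tuple[str, str]] = [("z0", "lin")]
    if name in OUM_MODELS:
        regs = regimes.regimes()
        layout += [(f"theta@{r}", "lin") for r in regs]
        if free_regime_dynamics:
            layout += [(f"sigma2@{r}", "log") for r in regs]
            layout += [(f"alpha@{r}", "log") for r in regs]
        else:
            layout += [("sigma2", "log"), ("alpha", "log")]
        return layout
    layout.append(("sigma2", "log"))
    if name == "OU":
        layout += [("alpha", "log"), ("theta", "lin")]
    elif name == "TREND":
        layout += [("mu_trend", "lin")]
    elif name == "EB":
        layout += [("r_eb", "lin")]
    elif name == "KAPPA":
        layout += [("kappa", "lin")]
    elif name == "PULSED":
        layout += [("lam_jump", "log"), ("delta2", "log")]
    elif name in ENV_MODELS:
        layout += [("alpha", "log"), ("theta0", "lin"), ("beta", "lin")]
    return layout


def _bounds_for(pname: str, xv: np.ndarray, tree: Phylogeny):
    base = pname.split("@")[0]
    lo_x, hi_x = float(xv.min()), float(xv.max())
    span = max(hi_x - lo_x, 1.0)
    depth = float(tree.tip_depths.max())
    if base in ("z0", "theta", "theta0"):
        return lo_x - 5 * span, hi_x + 5 * span
    if base == "r_eb":
        return -10.0 / depth, 10.0 / depth
    return BOUNDS[base]


def fit_model(
    tree: Phylogeny,
    x,
    name: str,
    curve: EnvCurve | None = None,
    regimes: RegimeMap | None = None,
    root_age_ma: float | None = None,
    free_regime_dynamics: bool = False,
    n_restarts: int = 10,
    seed: int = 0,
    maxiter: int = 500,
) -> ModelFit:
    """Maximum-likelihood fit of one model by bounded multi-start optimization.

    Positive parameters are optimized on the log scale within documented
    bounds; restarts are Latin-hypercube draws (seeded, hence deterministic)
    plus one moment-based start.  Returns a :class:`ModelFit` with AICc.
    Refuses TREND on ultrametric trees (the drift is confounded with z0).
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; supported: {MODEL_NAMES}")
    xv = _tip_vector(tree, x)
    n = xv.size
    n_reg = len(regimes.regimes()) if (regimes is not None and name in OUM_MODELS) else None
    k = param_count(name, n_regimes=n_reg, free_regime_dynamics=free_regime_dynamics)
    if n - k - 1 <= 0:
        raise ValueError(f"cannot fit {name}: AICc needs n - k - 1 > 0 (n={n}, k={k})")
    if name == "TREND" and tree.is_ultrametric():
        raise ValueError("TREND is non-identifiable on an ultrametric tree (confounded with z0)")
    if name == "PULSED":
        return _fit_pulsed(tree, xv, k=k, n=n, n_restarts=n_restarts, seed=seed, maxiter=maxiter)

    layout = _free_param_layout(name, regimes, free_regime_dynamics)
    bounds_nat = [_bounds_for(p, xv, tree) for p, _ in layout]
    tband = [
        (np.log(lo), np.log(hi)) if tr == "log" else (lo, hi)
        for (p, tr), (lo, hi) in zip(layout, bounds_nat)
    ]

    def unpack(vec: np.ndarray) -> dict:
        flat = {}
        for (p, tr), val in zip(layout, vec):
            flat[p] = float(np.exp(val)) if tr == "log" else float(val)
        if name in OUM_MODELS:
            params: dict = {"z0": flat["z0"]}
            theta = {p.split("@")[1]: v for p, v in flat.items() if p.startswith("theta@")}
            params["theta"] = theta
            if free_regime_dynamics:
                params["sigma2"] = {p.split("@")[1]: v for p, v in flat.items() if p.startswith("sigma2@")}
                params["alpha"] = {p.split("@")[1]: v for p, v in flat.items() if p.startswith("alpha@")}
            else:
                params["sigma2"] = flat["sigma2"]
                params["alpha"] = flat["alpha"]
            return params
        return flat

    def nll(vec: np.ndarray) -> float:
        try:
            ll = loglik(tree, xv, name, unpack(vec), curve=curve, regimes=regimes,
                        root_age_ma=root_age_ma)
        except (ValueError, np.linalg.LinAlgError):
            return 1e10
        return 1e10 if not np.isfinite(ll) else -ll

    # start points: one moment-based + Latin-hypercube draws
    z0_hat, s2_hat = _bm_moment_start(tree, xv)
    depth = float(tree.tip_depths.max())
    smart = []
    for p, tr in layout:
        base = p.split("@")[0]
        val = {
            "z0": z0_hat, "theta": float(np.mean(xv)), "theta0": float(np.mean(xv)),
            "sigma2": s2_hat, "alpha": 1.0 / depth, "kappa": 1.0,
            "mu_trend": 0.0, "r_eb": 0.0, "beta": 0.0,
            "lam_jump": 1.0 / depth, "delta2": max(s2_hat * depth / 3.0, 1e-6),
        }[base]
        lo, hi = _bounds_for(p, xv, tree)
        val = min(max(val, lo), hi)
        smart.append(np.log(val) if tr == "log" else val)
    starts = [np.asarray(smart)]
    if n_restarts > 1:
        sampler = qmc.LatinHypercube(d=len(layout), seed=seed)
        u = sampler.random(n_restarts - 1)
        lo = np.array([b[0] for b in tband])
        hi = np.array([b[1] for b in tband])
        starts += list(lo + u * (hi - lo))

    best = None
    used = 0
    for s0 in starts:
        used += 1
        res = minimize(nll, s0, method="L-BFGS-B", bounds=tband,
                       options={"maxiter": maxiter, "ftol": 1e-10})
        if np.isfinite(res.fun) and res.fun < 1e9 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return ModelFit(model=name, params={}, lnL=-np.inf, k=k, n=n, aicc=np.inf,
                        converged=False, n_restarts_used=used, seed=seed)
    params = unpack(best.x)
    lnL = -float(best.fun)
    flat = _flatten_params(params)
    return ModelFit(model=name, params=flat, lnL=lnL, k=k, n=n, aicc=aicc(lnL, k, n),
                    converged=True, n_restarts_used=used, seed=seed)


def _profile_z0(msg):
    """Maximize the root-mixture density over z0 (grid over component means
    plus a local refinement)."""
    from scipy.optimize import minimize_scalar

    m, v, lw = msg
    if np.any(v <= 0):
        raise ValueError("zero-variance component at the root")
    logv = np.log(v)

    def ll(z):
        return float(logsumexp(lw - 0.5 * (_LOG2PI + logv + (z - m) ** 2 / v)))

    cand = logsumexp(
        lw[None, :] - 0.5 * (_LOG2PI + logv[None, :] + (m[:, None] - m[None, :]) ** 2 / v[None, :]),
        axis=1,
    )
    j = int(np.argmax(cand))
    w = float(np.sqrt(v[j]))
    res = minimize_scalar(lambda z: -ll(z), bounds=(m[j] - 3 * w, m[j] + 3 * w), method="bounded")
    if -res.fun >= cand[j]:
        return float(res.x), float(-res.fun)
    return float(m[j]), float(cand[j])


def _fit_pulsed(tree, xv, k, n, n_restarts, seed, maxiter):
    """PULSED fit: optimize (sigma2, lam_jump, delta2) on the log scale with
    coarse mixture pruning, profiling z0 out of the root message; the final
    log-likelihood is re-evaluated at the default (fine) pruning settings."""
    rough = dict(merge_tol=0.2, max_components=32, poisson_tail=1e-6, weight_floor=1e-10)
    coarse = dict(merge_tol=0.05, max_components=96, poisson_tail=1e-8, weight_floor=1e-10)
    depth = float(tree.tip_depths.max())
    z0_hat, s2_hat = _bm_moment_start(tree, xv)

    def neg_profiled(vec, opts):
        s2, lam, d2 = np.exp(vec)
        try:
            msg = _pulsed_root_message(
                tree, xv, {"sigma2": s2, "lam_jump": lam, "delta2": d2}, **opts
            )
            _, ll = _profile_z0(msg)
        except (ValueError, np.linalg.LinAlgError):
            return 1e10
        return 1e10 if not np.isfinite(ll) else -ll

    tband = [
        (np.log(BOUNDS["sigma2"][0]), np.log(BOUNDS["sigma2"][1])),
        (np.log(BOUNDS["lam_jump"][0]), np.log(BOUNDS["lam_jump"][1])),
        (np.log(BOUNDS["delta2"][0]), np.log(BOUNDS["delta2"][1])),
    ]
    # Start points probe the lam*delta2 ridge: the same apparent variance
    # flux can come from rare large jumps or frequent small ones.  Half the
    # BM moment rate is assigned to jumps at several candidate jump counts.
    total_len = tree.total_length()
    starts = []
    for n_jumps in (2.0, 8.0, 32.0):
        lam0 = n_jumps / total_len
        d20 = max(0.5 * s2_hat / lam0, 1e-8)
        starts.append(np.log([max(0.5 * s2_hat, 1e-8), lam0, d20]))
    if n_restarts > len(starts):
        sampler = qmc.LatinHypercube(d=3, seed=seed)
        u = sampler.random(n_restarts - len(starts))
        lo = np.array([b[0] for b in tband])
        hi = np.array([b[1] for b in tband])
        starts += list(lo + u * (hi - lo))
    # phase 1: cheap derivative-free exploration; phase 2: polish best start
    lo = np.array([b[0] for b in tband])
    hi = np.array([b[1] for b in tband])

    def clipped(fun, opts):
        return lambda v: fun(np.clip(v, lo, hi), opts)

    best, used = None, 0
    for s0 in starts:
        used += 1
        res = minimize(clipped(neg_profiled, rough), np.clip(s0, lo, hi),
                       method="Nelder-Mead",
                       options={"maxfev": 120, "fatol": 0.02, "xatol": 0.02})
        if np.isfinite(res.fun) and res.fun < 1e9 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return ModelFit(model="PULSED", params={}, lnL=-np.inf, k=k, n=n, aicc=np.inf,
                        converged=False, n_restarts_used=used, seed=seed)
    res = minimize(clipped(neg_profiled, coarse), np.clip(best.x, lo, hi),
                   method="Nelder-Mead",
                   options={"maxfev": 80, "fatol": 0.005, "xatol": 0.005})
    if np.isfinite(res.fun) and res.fun < 1e9 and res.fun <= best.fun + 1.0:
        best = res
    s2, lam, d2 = np.exp(np.clip(best.x, lo, hi))
    msg = _pulsed_root_message(tree, xv, {"sigma2": s2, "lam_jump": lam, "delta2": d2})
    z0, lnL = _profile_z0(msg)
    params = {"z0": z0, "sigma2": float(s2), "lam_jump": float(lam), "delta2": float(d2)}
    return ModelFit(model="PULSED", params=params, lnL=lnL, k=k, n=n,
                    aicc=aicc(lnL, k, n), converged=True, n_restarts_used=used, seed=seed)


def _flatten_params(params: dict) -> dict:
    flat = {}
    for key, val in params.items():
        if isinstance(val, dict):
            for r, v in val.items():
                flat[f"{key}@{r}"] = float(v)
        else:
            flat[key] = float(val)
    return flat
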