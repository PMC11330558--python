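"""AICc model ranking across posterior trees, ancestral states, origin counts.

Models are compared with the small-sample-corrected Akaike information
criterion.  Because every model is fitted to every tree in a posterior
sample, the headline ranking statistic is the *median* AICc weight of each
model across trees (means are reported alongside).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trees import Phylogeny, bm_covariance

__all__ = [
    "aicc",
    "akaike_weights",
    "rank_models",
    "ancestral_root",
    "ancestral_states",
    "count_size_origins",
]


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``2k - 2 lnL + 2k(k+1)/(n-k-1)``."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: need n - k - 1 > 0 (n={n}, k={k})")
    return 2.0 * k - 2.0 * lnL + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized weights ``exp(-dAICc/2)`` within one tree."""
    a = np.asarray(aicc_values, dtype=float)
    d = a - np.nanmin(a)
    w = np.exp(-0.5 * d)
    w[~np.isfinite(a)] = 0.0
    return w / w.sum()


def rank_models(fits: pd.DataFrame, exclude_threshold: float = 0.5) -> pd.DataFrame:
    """Rank models by median AICc weight across trees.

    Parameters
    ----------
    fits
        Long-format table with columns ``tree`` (identifier), ``model``,
        ``aicc``, ``k`` and optionally ``converged`` (defaults to True).
    exclude_threshold
        Models that failed to converge on more than this fraction of trees
        are dropped from the ranking (with a printed warning).

    Returns
    -------
    DataFrame indexed by model with columns ``median_waicc``, ``mean_waicc``,
    ``q2.5``, ``q97.5``, ``median_aicc``, ``n_trees``, ``rank``.
    """
    df = fits.copy()
    if "converged" not in df.columns:
        df["converged"] = True
    if df["model"].nunique() < 1 or df["tree"].nunique() < 1:
        raise ValueError("need at least one tree and one model")

    conv_frac = df.groupby("model")["converged"].mean()
    dropped = conv_frac[conv_frac < (1.0 - exclude_threshold)].index.tolist()
    if dropped:
        import warnings

        warnings.warn(f"models excluded (unconverged on >50% of trees): {dropped}")
        df = df[~df["model"].isin(dropped)]
    df = df[df["converged"]]

    rows = []
    for tree_id, grp in df.groupby("tree"):
        w = akaike_weights(grp["aicc"].to_numpy())
        for (_, rec), wi in zip(grp.iterrows(), w):
            rows.append({"tree": tree_id, "model": rec["model"], "k": rec["k"],
                         "aicc": rec["aicc"], "waicc": wi})
    long = pd.DataFrame(rows)
    out = long.groupby("model").agg(
        median_waicc=("waicc", "median"),
        mean_waicc=("waicc", "mean"),
        **{"q2.5": ("waicc", lambda s: float(np.quantile(s, 0.025)))},
        **{"q97.5": ("waicc", lambda s: float(np.quantile(s, 0.975)))},
        median_aicc=("aicc", "median"),
        n_trees=("waicc", "size"),
        k=("k", "first"),
    )
    # rank by median weight; ties broken by smaller k then model name
    out = (
        out.reset_index()
        .sort_values(by=["median_waicc", "k", "model"], ascending=[False, True, True])
        .set_index("model")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# -------------------------------------------------------- ancestral states


def _gls_root(tree: Phylogeny, x: np.ndarray):
    C = bm_covariance(tree)
    n = len(x)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Ci @ one
    z0 = (one @ Ci @ x) / denom
    resid = x - z0
    sigma2 = (resid @ Ci @ resid) / n  # ML estimate of the BM rate
    var_z0 = sigma2 / denom
    return z0, var_z0, sigma2, Ci


def ancestral_root(tree: Phylogeny, x, back_transform: bool = True):
    """GLS estimate of the root state under Brownian motion, with 95% CI.

    ``x`` is log size (ln cm), keyed by tip order or given as a mapping from
    tip label.  When ``back_transform`` is True the point estimate and CI are
    also returned in cm, as customarily reported.
    """
    x = _as_tip_vector(tree, x)
    z0, var_z0, sigma2, _ = _gls_root(tree, x)
    half = 1.959963984540054 * np.sqrt(var_z0)
    res = {
        "root_log": float(z0),
        "ci_log": (float(z0 - half), float(z0 + half)),
        "sigma2": float(sigma2),
    }
    if back_transform:
        res["root_cm"] = float(np.exp(z0))
        res["ci_cm"] = (float(np.exp(z0 - half)), float(np.exp(z0 + half)))
    return res


def ancestral_states(tree: Phylogeny, x) -> np.ndarray:
    """BM-GLS point reconstruction at every node (indexed like tree nodes).

    The reconstruction is the conditional expectation of each internal node
    given the tips under Brownian motion with the GLS root and ML rate.
    """
    x = _as_tip_vector(tree, x)
    z0, _, _, Ci = _gls_root(tree, x)
    # Cov(node, tip i) = sigma^2 * shared path length; sigma^2 cancels.
    desc = tree.descendant_tips()
    n_tips = tree.n_tips
    anc = np.empty(tree.n_nodes)
    resid = x - z0
    w = Ci @ resid
    depth = tree.depth
    tip_of = {t: k for k, t in enumerate(tree.tips)}
    for v in tree.preorder():
        if not tree.children[v]:
            anc[v] = x[tip_of[v]]
            continue
        # shared path of node v with tip i = depth of mrca(v, i); for tips
        # below v this is depth[v]; otherwise it is the depth of the mrca of
        # v and the tip, found by walking v's ancestors.
        shared = np.empty(n_tips)
        below = set(desc[v])
        shared[list(below)] = depth[v]
        # ancestors of v partition the remaining tips
        u = v
        while u != tree.root:
            p = tree.parent[u]
            outside = set(desc[p]) - set(desc[u])
            shared[list(outside)] = depth[p]
            u = p
        anc[v] = z0 + shared @ w
    return anc


def count_size_origins(tree: Phylogeny, x, threshold_ln: float) -> int:
    """Number of independent origins of size >= threshold (on the log scale).

    Ancestral values are reconstructed by BM-GLS; an origin is an edge whose
    parent value is below the threshold and whose child value (internal node
    or tip) is at or above it.
    """
    xv = _as_tip_vector(tree, x)
    anc = ancestral_states(tree, xv)
    count = 0
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        if anc[tree.parent[v]] < threshold_ln <= anc[v]:
            count += 1
    if anc[tree.root] >= threshold_ln:
        count += 1  # the root itself is already large: one ancestral origin
    return count


def _as_tip_vector(tree: Phylogeny, x) -> np.ndarray:
    if isinstance(x, dict):
        return np.array([x[lb] for lb in tree.tip_labels], dtype=float)
    if isinstance(x, pd.Series):
        return x.reindex(tree.tip_labels).to_numpy(dtype=float)
    arr = np.asarray(x, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise ValueError(f"trait vector length {arr.shape} != n_tips {tree.n_tips}")
    return arr
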