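"""Non-model downstream tests: PGLS on palaeolatitude, permutational ANOVA
on ecospace occupancy, and predator/prey tallies.

The predator/prey rules encode feeding ecology: a predator of a eurypterid
is any carnivorous fish, nautiloid or eurypterine more than twice its
length (sweep-feeding stylonurines need a 5x advantage; suspension-feeding
hibbertopterids never count); prey of a predatory eurypterid is any mobile
benthic or nektonic animal under half its length (sessile taxa excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trees import Phylogeny, bm_covariance

__all__ = [
    "pgls",
    "classify_predators_prey",
    "ecospace_table",
    "permutational_anova",
    "correlation_report",
    "EcospaceRecord",
]

LARGE_THRESHOLD_CM = 50.0  # 0.5 m split used throughout

PREDATOR_GUILDS_2X = {"carnivorous_fish", "nautiloid", "eurypterine"}
PREY_GUILDS = {"mobile_benthic", "nektonic"}


# ----------------------------------------------------------------------- PGLS


def pgls(tree: Phylogeny, y, x, lambda_policy: str = "fixed_1"):
    """Phylogenetic GLS regression of y (log size) on x (palaeolatitude).

    The residual covariance is Pagel's lambda structure: the BM covariance
    with off-diagonals multiplied by lambda.  ``lambda_policy`` is
    ``"fixed_1"`` (plain BM, the default), ``"fixed_0"`` (ordinary least
    squares) or ``"ml"`` (lambda estimated by maximum likelihood).  Taxa
    with missing x or y are dropped (with at least 3 required).

    Returns a dict: slope, intercept, r2, lambda_used, n.
    """
    yv = _aligned(tree, y)
    xv = _aligned(tree, x)
    ok = np.isfinite(yv) & np.isfinite(xv)
    if ok.sum() < 3:
        raise ValueError(f"fewer than 3 taxa with complete data ({int(ok.sum())})")
    C_full = bm_covariance(tree)
    C = C_full[np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))]
    yv, xv = yv[ok], xv[ok]

    def fit_at(lam):
        V = lam * C + (1 - lam) * np.diag(np.diag(C))
        return _gls_fit(yv, xv, V)

    if lambda_policy == "fixed_1":
        lam = 1.0
    elif lambda_policy == "fixed_0":
        lam = 0.0
    elif lambda_policy == "ml":
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda l: -fit_at(l)["lnL"], bounds=(0.0, 1.0),
                              method="bounded")
        lam = float(res.x)
    else:
        raise ValueError("lambda_policy must be 'fixed_1', 'fixed_0' or 'ml'")
    out = fit_at(lam)
    out["lambda_used"] = lam
    out["n"] = int(ok.sum())
    return out


def _gls_fit(y, x, V):
    n = len(y)
    Vi = np.linalg.inv(V)
    X = np.column_stack([np.ones(n), x])
    XtVi = X.T @ Vi
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    resid = y - X @ beta
    rss = float(resid @ Vi @ resid)
    # GLS R^2 against the intercept-only model in the same metric
    one = np.ones(n)
    mu = float(one @ Vi @ y / (one @ Vi @ one))
    tss = float((y - mu) @ Vi @ (y - mu))
    sigma2 = max(rss / n, 1e-300)
    sign, logdet = np.linalg.slogdet(V)
    lnL = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return {
        "slope": float(beta[1]),
        "intercept": float(beta[0]),
        "r2": 1.0 - rss / tss if tss > 0 else np.nan,
        "lnL": float(lnL),
    }


def _aligned(tree: Phylogeny, v) -> np.ndarray:
    if isinstance(v, dict):
        return np.array([v.get(lb, np.nan) for lb in tree.tip_labels], dtype=float)
    if isinstance(v, pd.Series):
        return v.reindex(tree.tip_labels).to_numpy(dtype=float)
    arr = np.asarray(v, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise ValueError("vector length != number of tips")
    return arr


# --------------------------------------------------------------- predator/prey


@dataclass
class EcospaceRecord:
    """Per-eurypterid ecospace occupancy counts within its assemblage."""

    taxon: str
    n_predators: int
    n_prey: int
    n_co_eurypterids: int
    assemblage_richness: int
    size_group: str  # 'small' (<0.5 m) or 'large' (>=0.5 m)
    max_length_cm: float


def classify_predators_prey(community: pd.DataFrame, focal) -> EcospaceRecord:
    """Tally potential predators and prey of one eurypterid in its assemblage.

    ``community`` needs columns species, assemblage, guild, max_length_cm,
    is_eurypterid; ``focal`` is a row (Series/dict) of that table.
    """
    guilds = set(community["guild"].unique())
    unknown = guilds - {"carnivorous_fish", "nautiloid", "eurypterine", "stylonurine",
                        "hibbertopterid", "sessile", "mobile_benthic", "nektonic"}
    if unknown:
        raise ValueError(f"unknown guild labels: {sorted(unknown)}")
    if isinstance(focal, dict):
        focal = pd.Series(focal)
    length = float(focal["max_length_cm"])
    local = community[(community["assemblage"] == focal["assemblage"])
                      & (community["species"] != focal["species"])]

    pred_2x = local["guild"].isin(PREDATOR_GUILDS_2X) & (local["max_length_cm"] > 2.0 * length)
    pred_5x = (local["guild"] == "stylonurine") & (local["max_length_cm"] > 5.0 * length)
    n_predators = int((pred_2x | pred_5x).sum())  # hibbertopterids never qualify

    prey = local["guild"].isin(PREY_GUILDS) & (local["max_length_cm"] < 0.5 * length)
    n_prey = int(prey.sum())

    n_co = int(local["is_eurypterid"].sum())
    richness = int(len(local)) + 1
    return EcospaceRecord(
        taxon=str(focal["species"]),
        n_predators=n_predators,
        n_prey=n_prey,
        n_co_eurypterids=n_co,
        assemblage_richness=richness,
        size_group="large" if length >= LARGE_THRESHOLD_CM else "small",
        max_length_cm=length,
    )


def ecospace_table(community: pd.DataFrame) -> pd.DataFrame:
    """Ecospace records for every eurypterid in the community table."""
    rows = []
    for _, focal in community[community["is_eurypterid"]].iterrows():
        rec = classify_predators_prey(community, focal)
        rows.append(rec.__dict__)
    return pd.DataFrame(rows)


# --------------------------------------------------------- permutational ANOVA

ECOSPACE_VARS = ("n_predators", "n_prey", "n_co_eurypterids", "assemblage_richness")


def permutational_anova(records: pd.DataFrame, variables=ECOSPACE_VARS,
                        group_col: str = "size_group", n_perm: int = 1000,
                        seed: int = 0) -> dict:
    """One-way PERMANOVA on the Euclidean distances of standardized
    ecospace variables between size groups.

    The pseudo-F is computed from between/within sums of squared distances;
    the p-value is ``(1 + #{permuted F >= observed}) / (1 + n_perm)`` with
    group labels permuted.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    groups = records[group_col].to_numpy()
    uniq = np.unique(groups)
    if len(uniq) < 2 or any((groups == g).sum() < 1 for g in uniq):
        raise ValueError("need at least two non-empty groups")
    X = records.loc[:, list(variables)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant ecospace variables: {bad}")
    X = (X - X.mean(axis=0)) / sd
    D2 = _sq_euclidean(X)
    n = len(X)
    f_obs = _pseudo_f(D2, groups, uniq)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(D2, groups[perm], uniq) >= f_obs:
            count += 1
    return {"F": float(f_obs), "p_value": (1 + count) / (1 + n_perm),
            "n_perm": n_perm, "groups": {g: int((groups == g).sum()) for g in uniq}}


def _sq_euclidean(X):
    G = X @ X.T
    d = np.diag(G)
    return np.maximum(d[:, None] + d[None, :] - 2 * G, 0.0)


def _pseudo_f(D2, groups, uniq):
    n = len(groups)
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        if idx.size:
            ss_within += D2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    ss_between = ss_total - ss_within
    a = len(uniq)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


# ------------------------------------------------------------------ reporting


def correlation_report(records: pd.DataFrame, size_col: str = "max_length_cm",
                       variables=ECOSPACE_VARS, n_perm: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Spearman rank correlations of size against each ecospace variable,
    with permutation p-values.  Non-phylogenetic by design (a preliminary
    screen, not a comparative test); degenerate covariates are reported as
    missing."""
    if len(records) < 4:
        raise ValueError("need at least 4 records")
    size = records[size_col].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for var in variables:
        v = records[var].to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(size) == 0:
            rows.append({"variable": var, "rho": np.nan, "p_value": np.nan,
                         "note": "constant covariate"})
            continue
        rho = stats.spearmanr(size, v).statistic
        count = 0
        for _ in range(n_perm):
            r = stats.spearmanr(size, rng.permutation(v)).statistic
            if abs(r) >= abs(rho):
                count += 1
        rows.append({"variable": var, "rho": float(rho),
                     "p_value": (1 + count) / (1 + n_perm), "note": ""})
    return pd.DataFrame(rows)
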