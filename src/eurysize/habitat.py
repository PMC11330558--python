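"""Discrete habitat evolution: Mk likelihoods, rjMCMC over rate structures,
stochastic character mapping, regime paintings and state-through-time counts.

Habitat is a 3-state character (marine, marginal marine, continental).
Transition-rate structures are explored by reversible-jump MCMC over
groupings of the six off-diagonal rates (with an optional zero class);
character histories are drawn by stochastic mapping with endpoint-
conditioned branch paths sampled by uniformization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import Phylogeny, RegimeMap

__all__ = [
    "mk_loglik",
    "fit_mk",
    "best_mk",
    "stationary_distribution",
    "rjmcmc_mk",
    "RjmcmcResult",
    "stochastic_map",
    "summarize_maps",
    "MapSummary",
    "count_colonizations",
    "paint_habitat_regimes",
    "paint_crisis_regimes",
]

DEFAULT_STATES = ("marine", "marginal", "continental")


# ------------------------------------------------------------- Mk likelihood


def _validate_q(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("Q off-diagonal rates must be non-negative")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-8):
        raise ValueError("Q rows must sum to zero")
    return Q


def _transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """P(t) for every branch length at once (eigendecomposition with an
    ``expm`` fallback for defective Q)."""
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vi = np.linalg.inv(V)
        # sanity check of the decomposition (defective Q falls through)
        if np.abs(V @ Vi - np.eye(k)).max() < 1e-9:
            E = np.exp(np.multiply.outer(ts, w))  # (T, k)
            P = np.einsum("ij,tj,jk->tik", V, E, Vi).real
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=2, keepdims=True)
            return P
    except np.linalg.LinAlgError:
        pass
    return np.stack([expm(Q * t) for t in ts])


def _tip_partials(tree: Phylogeny, tip_states, states) -> np.ndarray:
    """One-hot partial likelihoods; missing states are fully ambiguous.

    ``tip_states`` is a mapping/Series keyed by tip label, or a sequence
    ordered like ``tree.tip_labels``.
    """
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    part = np.zeros((tree.n_nodes, k))
    if isinstance(tip_states, pd.Series):
        tip_states = tip_states.to_dict()
    if not isinstance(tip_states, dict):
        seq = list(tip_states)
        if len(seq) != tree.n_tips:
            raise ValueError("tip state sequence length != number of tips")
        tip_states = dict(zip(tree.tip_labels, seq))
    for pos, t in enumerate(tree.tips):
        s = tip_states.get(tree.labels[t])
        if s is None or (isinstance(s, float) and np.isnan(s)) or s in ("?", "-", ""):
            part[t] = 1.0
        else:
            if s not in idx:
                raise ValueError(f"tip state {s!r} not in alphabet {list(states)}")
            part[t, idx[s]] = 1.0
    return part


def _root_prior_vector(root_prior, Q, states) -> np.ndarray:
    k = len(states)
    if root_prior == "uniform" or root_prior is None:
        return np.full(k, 1.0 / k)
    if root_prior == "stationary":
        return stationary_distribution(Q)
    if isinstance(root_prior, str):
        if root_prior not in states:
            raise ValueError(f"unknown root prior {root_prior!r}")
        v = np.zeros(k)
        v[list(states).index(root_prior)] = 1.0
        return v
    v = np.asarray(root_prior, dtype=float)
    return v / v.sum()


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of Q (least-squares null vector; uniform
    fallback for degenerate rate matrices)."""
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    s = pi.sum()
    if s <= 1e-12 or not np.all(np.isfinite(pi)):
        return np.full(k, 1.0 / k)
    return pi / s


def _level_schedule(tree: Phylogeny):
    """Internal nodes grouped into levels that can be evaluated together
    (every child strictly earlier); cached on the tree."""
    if "mk_levels" not in tree._cache:
        rank = np.zeros(tree.n_nodes, dtype=int)
        for v in tree.postorder():
            if tree.children[v]:
                rank[v] = 1 + max(rank[c] for c in tree.children[v])
        levels = []
        for r in range(1, rank.max() + 1):
            nodes = [v for v in range(tree.n_nodes) if tree.children[v] and rank[v] == r]
            max_kids = max(len(tree.children[v]) for v in nodes)
            slots = []
            for slot in range(max_kids):
                rows = np.array([i for i, v in enumerate(nodes)
                                 if len(tree.children[v]) > slot])
                kids = np.array([tree.children[nodes[i]][slot] for i in rows])
                slots.append((rows, kids))
            levels.append((np.array(nodes), slots))
        tree._cache["mk_levels"] = levels
    return tree._cache["mk_levels"]


def _pruning(tree: Phylogeny, part: np.ndarray, P: np.ndarray):
    """Scaled postorder partial likelihoods.  Returns (partials, log-scale).

    Internal nodes are processed level by level so the (children x states)
    contractions run as batched matrix products.
    """
    part = part.copy()
    logscale = 0.0
    for nodes, slots in _level_schedule(tree):
        acc = np.ones((nodes.size, part.shape[1]))
        # grouped by child position; binary trees take exactly two passes
        for rows, kids in slots:
            acc[rows] *= np.einsum("nij,nj->ni", P[kids], part[kids])
        mx = acc.max(axis=1)
        if np.any(mx <= 0):
            return part, -np.inf
        part[nodes] = acc / mx[:, None]
        logscale += float(np.log(mx).sum())
    return part, logscale


def mk_loglik(tree: Phylogeny, tip_states, Q, states=DEFAULT_STATES,
              root_prior="stationary") -> float:
    """Felsenstein-pruning log-likelihood of a k-state Markov character.

    Missing tip states are treated as fully ambiguous.  ``root_prior`` is
    ``"uniform"``, ``"stationary"``, a state name (fixed root) or an
    explicit probability vector.
    """
    Q = _validate_q(Q)
    P = _transition_matrices(Q, tree.length.copy())
    part = _tip_partials(tree, tip_states, states)
    part, logscale = _pruning(tree, part, P)
    if not np.isfinite(logscale):
        return -np.inf
    prior = _root_prior_vector(root_prior, Q, states)
    like = float(prior @ part[tree.root])
    return -np.inf if like <= 0 else float(np.log(like) + logscale)


# ---------------------------------------------------------------- ML fitting

_STRUCTURES = ("ER", "SYM", "ARD")


def _build_q(rates: np.ndarray, structure: str, k: int) -> np.ndarray:
    Q = np.zeros((k, k))
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    if structure == "ER":
        for i, j in pairs:
            Q[i, j] = rates[0]
    elif structure == "SYM":
        sym_pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        for r, (i, j) in zip(rates, sym_pairs):
            Q[i, j] = Q[j, i] = r
    elif structure == "ARD":
        for r, (i, j) in zip(rates, pairs):
            Q[i, j] = r
    else:
        raise ValueError(f"unknown structure {structure!r}; use one of {_STRUCTURES}")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def fit_mk(tree: Phylogeny, tip_states, states=DEFAULT_STATES, structure="ER",
           root_prior="stationary"):
    """ML fit of an Mk model with an equal-rates, symmetric or all-rates-
    different structure.  Returns (Q, lnL, n_params)."""
    k = len(states)
    n_rates = {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[structure]
    scale = 3.0 / tree.total_length()

    def nll(logr):
        Q = _build_q(np.exp(logr), structure, k)
        ll = mk_loglik(tree, tip_states, Q, states, root_prior)
        return 1e10 if not np.isfinite(ll) else -ll

    best = None
    for mult in (0.1, 1.0, 10.0):
        x0 = np.full(n_rates, np.log(scale * mult))
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(np.log(1e-9), np.log(10.0))] * n_rates)
        if best is None or res.fun < best.fun:
            best = res
    Q = _build_q(np.exp(best.x), structure, k)
    return Q, -float(best.fun), n_rates


def best_mk(tree: Phylogeny, tip_states, states=DEFAULT_STATES, root_prior="stationary"):
    """Pick the ML Mk structure (ER/SYM/ARD) by AICc; returns
    (Q, structure, table)."""
    from .selection import aicc

    rows = []
    fits = {}
    for st in _STRUCTURES:
        Q, lnL, npar = fit_mk(tree, tip_states, states, st, root_prior)
        fits[st] = Q
        rows.append({"structure": st, "lnL": lnL, "k": npar,
                     "aicc": aicc(lnL, npar, tree.n_tips)})
    tab = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    best = tab.loc[0, "structure"]
    return fits[best], best, tab


# -------------------------------------------------------------------- rjMCMC

def _offdiag_pairs(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(k) if i != j]


def _canonical(assign: tuple) -> tuple:
    """Canonical form: nonzero classes renumbered by first appearance."""
    mapping: dict[int, int] = {}
    out = []
    nxt = 1
    for a in assign:
        if a == 0:
            out.append(0)
        else:
            if a not in mapping:
                mapping[a] = nxt
                nxt += 1
            out.append(mapping[a])
    return tuple(out)


def _neighbours(assign: tuple, entry: int) -> list[tuple]:
    """Distinct canonical structures reachable by re-assigning one entry."""
    others = [a for i, a in enumerate(assign) if i != entry]
    options = {0}
    options.update(a for a in others if a != 0)
    options.add(max(assign) + 1)  # a fresh class
    out = set()
    for o in options:
        cand = list(assign)
        cand[entry] = o
        c = _canonical(tuple(cand))
        if c != _canonical(assign):
            out.add(c)
    return sorted(out)


def _q_from_structure(assign: tuple, rates: dict[int, float], k: int) -> np.ndarray:
    Q = np.zeros((k, k))
    for (i, j), a in zip(_offdiag_pairs(k), assign):
        Q[i, j] = 0.0 if a == 0 else rates[a]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _parsimony_changes(tree: Phylogeny, tip_states, states) -> int:
    """Fitch parsimony length of the tip configuration (missing = any)."""
    part = _tip_partials(tree, tip_states, states) > 0
    sets: dict[int, frozenset] = {}
    changes = 0
    for v in tree.postorder():
        if not tree.children[v]:
            sets[v] = frozenset(np.flatnonzero(part[v]))
            continue
        inter = None
        union: set = set()
        for c in tree.children[v]:
            inter = sets[c] if inter is None else inter & sets[c]
            union |= sets[c]
        if inter:
            sets[v] = frozenset(inter)
        else:
            sets[v] = frozenset(union)
            changes += 1
    return changes


@dataclass
class RjmcmcResult:
    """Posterior sample over Mk rate structures."""

    samples: pd.DataFrame               # iteration, structure, lnL, rates (json)
    structure_freq: pd.Series           # visit frequency per structure
    modal_structure: tuple
    zero_pattern_freq: pd.Series        # visit frequency per zero/nonzero pattern
    modal_zero_pattern: tuple           # 1 where the entry sits in the zero class
    acceptance_rate: float
    states: tuple
    seed: int

    def rate_posterior(self, entry: int) -> np.ndarray:
        """Posterior draws of the rate of one off-diagonal entry (0..5)."""
        vals = []
        for _, row in self.samples.iterrows():
            a = row["structure"][entry]
            vals.append(0.0 if a == 0 else row["rates"][a])
        return np.asarray(vals)


def rjmcmc_mk(
    tree: Phylogeny,
    tip_states,
    states=DEFAULT_STATES,
    n_iter: int = 20000,
    burnin: int | None = None,
    thin: int = 10,
    seed: int = 0,
    rate_prior_mean: float | None = None,
    root_prior="stationary",
) -> RjmcmcResult:
    """Reversible-jump MCMC over groupings of the six off-diagonal Mk rates.

    The model space is every assignment of the 6 entries to shared-rate
    classes, including a zero class (structural absence of a transition);
    the prior is uniform over canonical structures and exponential (mean
    ``rate_prior_mean``, default 3 changes per total tree length) on each
    class rate.  Moves alternate between structure changes (one entry moves
    to the zero class, an existing class or a fresh class; new class rates
    are drawn from the prior, which makes the dimension-matching Jacobian 1)
    and log-scale random-walk rate updates.  ``tip_states=None`` runs the
    chain without data (prior target), which is used to validate detailed
    balance.
    """
    if burnin is None:
        burnin = n_iter // 5
    if n_iter <= burnin:
        raise ValueError("n_iter must exceed burnin")
    k = len(states)
    n_entries = k * (k - 1)
    rng = np.random.default_rng(seed)
    if rate_prior_mean is not None:
        prior_mean = rate_prior_mean
    elif tip_states is not None:
        # empirical scale: parsimony changes per unit tree length (doubled,
        # since parsimony is a lower bound on the true change count), so the
        # prior spreads real mass across the range the data can distinguish
        # from zero (a rate prior crowded near 0 would erase the reversible-
        # jump Occam penalty that lets the zero class win)
        changes = _parsimony_changes(tree, tip_states, states)
        prior_mean = 2.0 * max(changes, 1.0) / tree.total_length()
    else:
        prior_mean = 3.0 / tree.total_length()

    have_data = tip_states is not None
    if have_data:
        P_cache_part = _tip_partials(tree, tip_states, states)

    def loglik(assign, rates):
        if not have_data:
            return 0.0
        Q = _q_from_structure(assign, rates, k)
        P = _transition_matrices(Q, tree.length.copy())
        part, logscale = _pruning(tree, P_cache_part.copy(), P)
        if not np.isfinite(logscale):
            return -np.inf
        prior = _root_prior_vector(root_prior, Q, states)
        like = float(prior @ part[tree.root])
        return -np.inf if like <= 0 else float(np.log(like) + logscale)

    assign = _canonical(tuple([1] * n_entries))  # start at equal rates
    rates = {1: prior_mean}
    lnL = loglik(assign, rates)
    records = []
    accepted = 0
    proposed = 0
    for it in range(n_iter):
        if rng.random() < 0.5:
            # Structure move: re-assign ONE entry (to the zero class, an
            # existing class or a fresh class).  Classes that persist keep
            # their current rates — only a freshly created class draws its
            # rate from the prior, and an emptied class drops its rate, so
            # the birth/death proposal densities cancel against the rate
            # prior and the acceptance ratio is the likelihood ratio times
            # the neighbourhood-size ratio (uniform structure prior).
            e = int(rng.integers(n_entries))
            nbs = _neighbours(assign, e)
            if nbs:
                proposed += 1
                cand_struct = nbs[int(rng.integers(len(nbs)))]
                new_rates: dict[int, float] = {}
                for cls in set(cand_struct) - {0}:
                    carrier = next((i for i in range(n_entries)
                                    if i != e and cand_struct[i] == cls), None)
                    if carrier is not None:
                        new_rates[cls] = rates[assign[carrier]]
                    else:  # class contains only the moved entry: fresh rate
                        new_rates[cls] = float(rng.exponential(prior_mean))
                lnL_new = loglik(cand_struct, new_rates)
                nbs_rev = _neighbours(cand_struct, e)
                log_a = (lnL_new - lnL) + np.log(len(nbs)) - np.log(len(nbs_rev))
                if np.log(rng.random()) < log_a:
                    assign, rates, lnL = cand_struct, new_rates, lnL_new
                    accepted += 1
        else:
            # rate update on a random class (log-scale random walk)
            classes = sorted(set(assign) - {0})
            if classes:
                proposed += 1
                cls = classes[int(rng.integers(len(classes)))]
                old = rates[cls]
                new = old * float(np.exp(rng.uniform(-1.0, 1.0)))
                cand_rates = dict(rates)
                cand_rates[cls] = new
                lnL_new = loglik(assign, cand_rates)
                # exponential prior ratio and multiplier-proposal Jacobian
                log_a = (lnL_new - lnL) + (old - new) / prior_mean + np.log(new / old)
                if np.log(rng.random()) < log_a:
                    rates, lnL = cand_rates, lnL_new
                    accepted += 1
        if it >= burnin and (it - burnin) % thin == 0:
            records.append({"iteration": it, "structure": assign,
                            "lnL": lnL, "rates": dict(rates)})
    samples = pd.DataFrame(records)
    freq = samples["structure"].value_counts(normalize=True)
    # the zero pattern marginalizes over how the nonzero rates are grouped:
    # it answers "which transitions are structurally absent"
    zpat = samples["structure"].map(lambda s: tuple(int(a == 0) for a in s))
    zfreq = zpat.value_counts(normalize=True)
    return RjmcmcResult(
        samples=samples,
        structure_freq=freq,
        modal_structure=freq.index[0],
        zero_pattern_freq=zfreq,
        modal_zero_pattern=zfreq.index[0],
        acceptance_rate=accepted / max(proposed, 1),
        states=tuple(states),
        seed=seed,
    )


# --------------------------------------------------------- stochastic mapping


def stochastic_map(
    tree: Phylogeny,
    tip_states,
    Q,
    states=DEFAULT_STATES,
    n_maps: int = 1000,
    seed: int = 0,
    root_prior="stationary",
) -> list[RegimeMap]:
    """Draw full character histories conditional on the tip data and Q.

    Node states are sampled from their joint conditional distribution
    (root from prior x partial likelihood, then preorder); branch paths are
    endpoint-conditioned samples obtained by uniformization.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    Q = _validate_q(np.asarray(Q, dtype=float))
    k = len(states)
    P = _transition_matrices(Q, tree.length.copy())
    part = _tip_partials(tree, tip_states, states)
    part, logscale = _pruning(tree, part, P)
    if not np.isfinite(logscale):
        raise ValueError("tip data have zero likelihood under this Q")
    prior = _root_prior_vector(root_prior, Q, states)
    rng = np.random.default_rng(seed)

    omega = float(max(-np.diag(Q).min(), 1e-12)) * 1.05 + 1e-12
    R = np.eye(k) + Q / omega
    Rpow = [np.eye(k), R]

    def rpow(n):
        while len(Rpow) <= n:
            Rpow.append(Rpow[-1] @ R)
        return Rpow[n]

    preorder = tree.preorder()
    maps = []
    for _ in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=int)
        pr = prior * part[tree.root]
        node_state[tree.root] = rng.choice(k, p=pr / pr.sum())
        segs: list[list[tuple[float, str]]] = [[] for _ in range(tree.n_nodes)]
        for v in preorder:
            if v == tree.root:
                continue
            p_state = node_state[tree.parent[v]]
            w = P[v][p_state] * part[v]
            c_state = int(rng.choice(k, p=w / w.sum()))
            node_state[v] = c_state
            segs[v] = _sample_branch_path(
                p_state, c_state, float(tree.length[v]), Q, omega, rpow, P[v], states, rng
            )
        maps.append(RegimeMap(tree, segs, [states[s] for s in node_state]))
    return maps


def _sample_branch_path(a, b, t, Q, omega, rpow, P_t, states, rng, max_events=None):
    """Endpoint-conditioned CTMC path on one branch via uniformization."""
    pab = P_t[a, b]
    if pab <= 0:
        raise ValueError("impossible endpoint pair in path sampling")
    if max_events is None:
        max_events = int(20 + 10 * omega * t)
    # sample the number of uniformized events
    u = rng.random() * pab
    log_pois = -omega * t
    acc = 0.0
    n = 0
    while True:
        term = np.exp(log_pois) * rpow(n)[a, b]
        acc += term
        if acc >= u or n >= max_events:
            break
        n += 1
        log_pois += np.log(omega * t) - np.log(n)
    # state sequence conditional on n events
    seq = [a]
    for i in range(1, n):
        prev = seq[-1]
        wts = rpow(1)[prev] * rpow(n - i)[:, b]
        seq.append(int(rng.choice(len(states), p=wts / wts.sum())))
    if n >= 1:
        seq.append(b)
    times = np.sort(rng.uniform(0.0, t, n)) if n else np.array([])
    # collapse virtual (self) transitions into segments
    segs: list[tuple[float, str]] = []
    cur = a
    last = 0.0
    for i in range(n):
        if seq[i + 1] != cur:
            segs.append((float(times[i] - last), states[cur]))
            last = float(times[i])
            cur = seq[i + 1]
    segs.append((t - last, states[cur]))
    return segs


# ------------------------------------------------------------------ summaries


@dataclass
class MapSummary:
    """Summary of a set of stochastic maps on one tree."""

    node_freq: pd.DataFrame          # per-node marginal state frequencies
    transition_counts: np.ndarray    # per-map total transition count
    ltt: pd.DataFrame                # age, state, median, lo, hi lineage counts
    grid: np.ndarray
    states: tuple
    counts: np.ndarray = field(repr=False, default=None)  # (n_maps, k, n_grid)


def summarize_maps(maps: list[RegimeMap], time_grid=None, n_grid: int = 101) -> MapSummary:
    """Node marginal frequencies, transition counts and state-dependent
    lineage-through-time curves (median and 95% band across maps)."""
    if not maps:
        raise ValueError("need at least one map")
    tree = maps[0].tree
    states = tuple(sorted(set().union(*(m.regimes() for m in maps)) |
                          set(m for mp in maps for m in mp.node_regime)))
    sidx = {s: i for i, s in enumerate(states)}
    ages = tree.node_age
    if time_grid is None:
        oldest = tree.root_age_ma
        youngest = float(ages[tree.tips].min())
        time_grid = np.linspace(youngest, oldest, n_grid)
    grid = np.asarray(time_grid, dtype=float)

    counts = np.zeros((len(maps), len(states), grid.size))
    node_state_counts = np.zeros((tree.n_nodes, len(states)))
    transitions = np.zeros(len(maps), dtype=int)
    for mi, mp in enumerate(maps):
        transitions[mi] = mp.n_transitions()
        for v, s in enumerate(mp.node_regime):
            node_state_counts[v, sidx[s]] += 1
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            older, younger = tree.branch_age_interval(v)
            sel = (grid < older) & (grid >= younger)
            if not np.any(sel):
                continue
            g = grid[sel]
            bounds = older - np.cumsum([L for L, _ in mp.segments[v]])
            seg_idx = np.searchsorted(-bounds, -(g - 1e-12))
            seg_idx = np.clip(seg_idx, 0, len(mp.segments[v]) - 1)
            for gi, si in zip(np.flatnonzero(sel), seg_idx):
                counts[mi, sidx[mp.segments[v][si][1]], gi] += 1

    med = np.median(counts, axis=0)
    lo = np.quantile(counts, 0.025, axis=0)
    hi = np.quantile(counts, 0.975, axis=0)
    rows = []
    for si, s in enumerate(states):
        for gi, g in enumerate(grid):
            rows.append({"age_ma": g, "state": s, "median": med[si, gi],
                         "lo": lo[si, gi], "hi": hi[si, gi]})
    ltt = pd.DataFrame(rows)
    node_freq = pd.DataFrame(node_state_counts / len(maps), columns=list(states))
    return MapSummary(node_freq=node_freq, transition_counts=transitions,
                      ltt=ltt, grid=grid, states=states, counts=counts)


def count_colonizations(maps: list[RegimeMap], target_state: str) -> dict:
    """Distribution over maps of the number of transition events INTO
    ``target_state`` anywhere on the tree."""
    counts = []
    for mp in maps:
        c = 0
        for segs in mp.segments:
            for prev, nxt in zip(segs, segs[1:]):
                if nxt[1] == target_state and prev[1] != target_state:
                    c += 1
        counts.append(c)
    arr = np.asarray(counts)
    return {
        "counts": arr,
        "median": float(np.median(arr)),
        "q2.5": float(np.quantile(arr, 0.025)),
        "q97.5": float(np.quantile(arr, 0.975)),
        "mean": float(arr.mean()),
    }


# ------------------------------------------------------------------ paintings


def paint_habitat_regimes(maps, mode: str = "three_peak"):
    """Habitat regime paintings for the multi-peak OU models.

    ``three_peak`` keeps the 3 habitat states; ``two_peak`` merges marine and
    continental into ``"other"`` (marginal marine kept as its own peak).
    Accepts one map or a list; returns the same shape.
    """
    if mode not in ("three_peak", "two_peak"):
        raise ValueError("mode must be 'three_peak' or 'two_peak'")
    single = isinstance(maps, RegimeMap)
    mlist = [maps] if single else list(maps)
    if mode == "three_peak":
        out = [m.relabel({}) for m in mlist]
    else:
        mapping = {"marine": "other", "continental": "other"}
        out = [m.relabel(mapping) for m in mlist]
    return out[0] if single else out


def paint_crisis_regimes(
    tree: Phylogeny,
    crisis_age_ma: float,
    clade1_tips,
    clade2_tips,
    outside_regime: str = "PRE",
) -> RegimeMap:
    """Paint a pre-crisis peak plus separate peaks for two surviving clades.

    Branch segments older than ``crisis_age_ma`` get regime ``PRE``; younger
    segments get ``S1``/``S2`` inside the two named clades (defined as the
    full subtree of each clade's MRCA) and ``outside_regime`` (default
    ``PRE``) elsewhere.  Branches crossing the age are split exactly there.
    """
    tip_index = tree.tip_index()
    missing = [x for x in list(clade1_tips) + list(clade2_tips) if x not in tip_index]
    if missing:
        raise KeyError(f"clade tips not in tree: {missing}")
    desc = tree.descendant_tips()

    def mrca_of(tipset):
        want = {tip_index[x] for x in tipset}
        best = tree.root
        for v in tree.preorder():
            if want <= set(desc[v]) and len(desc[v]) <= len(desc[best]):
                best = v
        return best

    m1, m2 = mrca_of(clade1_tips), mrca_of(clade2_tips)
    in1 = np.zeros(tree.n_nodes, dtype=bool)
    in2 = np.zeros(tree.n_nodes, dtype=bool)

    def mark(root_node, arr):
        stack = [root_node]
        while stack:
            v = stack.pop()
            arr[v] = True
            stack.extend(tree.children[v])

    mark(m1, in1)
    mark(m2, in2)
    if np.any(in1 & in2):
        raise ValueError("surviving clades overlap")

    segs: list[list[tuple[float, str]]] = [[] for _ in range(tree.n_nodes)]
    node_regime = [""] * tree.n_nodes
    for v in range(tree.n_nodes):
        post = "S1" if in1[v] else ("S2" if in2[v] else outside_regime)
        node_age = tree.root_age_ma - tree.depth[v]
        node_regime[v] = "PRE" if node_age > crisis_age_ma else post
        if v == tree.root:
            continue
        older, younger = tree.branch_age_interval(v)
        if younger >= crisis_age_ma:
            segs[v] = [(float(tree.length[v]), "PRE")]
        elif older <= crisis_age_ma:
            segs[v] = [(float(tree.length[v]), post)]
        else:
            segs[v] = [(float(older - crisis_age_ma), "PRE"),
                       (float(crisis_age_ma - younger), post)]
    return RegimeMap(tree, segs, node_regime)
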