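"""Synthetic data with the statistical structure of a fossil-rich clade.

Everything downstream (model fitting, mapping, ranking, ecology tests) is
exercised on data from this module: trees from a forward fossilized
birth-death simulation, continuous traits drawn exactly from each trait
model, discrete habitat histories from a continuous-time Markov chain,
smooth environmental curves, and faunal community tables.  Every generator
is a pure function of its inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .envcurves import EnvCurve, fit_smoothing_spline
from .trees import Phylogeny, RegimeMap, TreeSet, prune_to_taxa

__all__ = [
    "simulate_fbd_tree",
    "simulate_continuous",
    "simulate_discrete",
    "simulate_env_curve",
    "simulate_community",
    "eurypterid_scenario",
    "HABITAT_STATES",
    "GUILDS",
]

HABITAT_STATES = ("marine", "marginal", "continental")
GUILDS = (
    "carnivorous_fish",
    "nautiloid",
    "eurypterine",
    "stylonurine",
    "hibbertopterid",
    "sessile",
    "mobile_benthic",
    "nektonic",
)


# ----------------------------------------------------------------- FBD trees


def simulate_fbd_tree(
    birth: float,
    death: float = 0.0,
    psi: float = 0.0,
    duration: float | None = None,
    n_extant: int | None = None,
    seed: int = 0,
    min_tips: int = 3,
    keep_extant: bool = True,
    max_retries: int = 100,
) -> Phylogeny:
    """Forward-simulate a fossilized birth-death tree and reconstruct it.

    Lineages speciate at rate ``birth``, go extinct at rate ``death`` and
    are fossil-sampled at rate ``psi`` (all per lineage per Myr).  The
    simulation stops either after ``duration`` Myr or when ``n_extant``
    lineages are simultaneously alive.  The returned tree spans the sampled
    tips only: fossil samples with no sampled descendants become tips at
    their sampling age (a lineage's latest sample wins; earlier samples and
    samples with sampled descendants are "sampled ancestors" and are
    dropped so every branch keeps a strictly positive length), plus the
    extant tips if ``keep_extant``.  Non-ultrametric whenever ``psi > 0``.

    Retries (up to ``max_retries``) on total extinction or fewer than
    ``min_tips`` sampled tips; deterministic given the seed.
    """
    if birth <= 0:
        raise ValueError("birth rate must be positive")
    if death < 0 or psi < 0:
        raise ValueError("death and psi rates must be non-negative")
    if (duration is None) == (n_extant is None):
        raise ValueError("specify exactly one stop condition: duration or n_extant")
    if duration is not None and duration <= 0:
        raise ValueError("duration must be positive")
    if n_extant is not None and n_extant < 2:
        raise ValueError("n_extant must be >= 2")

    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(attempt,)))
        tree = _fbd_once(birth, death, psi, duration, n_extant, keep_extant, rng)
        if tree is not None and tree.n_tips >= min_tips:
            return tree
    raise RuntimeError(
        f"no surviving tree with >= {min_tips} sampled tips in {max_retries} attempts; "
        "raise the rates or the duration"
    )


def _fbd_once(birth, death, psi, duration, n_extant, keep_extant, rng):
    # lineage records: parent lineage, birth time, end time, fate, samples
    parent = [-1]
    t_birth = [0.0]
    t_end = [np.nan]
    fate = [None]  # 'speciation' | 'extinction' | 'extant'
    samples: list[list[float]] = [[]]
    kids: list[list[int]] = [[]]
    active = [0]
    t = 0.0
    total_rate_per = birth + death + psi
    while active:
        if n_extant is not None and len(active) >= n_extant:
            # survive a final waiting time so tip branches are positive
            t += rng.exponential(1.0 / (len(active) * total_rate_per))
            break
        dt = rng.exponential(1.0 / (len(active) * total_rate_per))
        t += dt
        if duration is not None and t >= duration:
            t = duration
            break
        li = active[rng.integers(len(active))]
        u = rng.random() * total_rate_per
        if u < birth:
            t_end[li] = t
            fate[li] = "speciation"
            active.remove(li)
            for _ in range(2):
                parent.append(li)
                t_birth.append(t)
                t_end.append(np.nan)
                fate.append(None)
                samples.append([])
                kids.append([])
                kids[li].append(len(parent) - 1)
                active.append(len(parent) - 1)
        elif u < birth + death:
            t_end[li] = t
            fate[li] = "extinction"
            active.remove(li)
        else:
            samples[li].append(t)
    for li in active:
        t_end[li] = t
        fate[li] = "extant"

    # Reconstruct the sampled tree.  Each surviving element carries the time
    # of its node; pass-through lineages vanish (edges concatenate).
    out_parent: list[int] = []
    out_length: list[float] = []
    out_labels: list[str | None] = []
    counter = [0]

    def new_node(parent_idx, time, top_time, label):
        idx = len(out_parent)
        out_parent.append(parent_idx)
        out_length.append(time - top_time if parent_idx >= 0 else np.nan)
        out_labels.append(label)
        return idx

    def reconstruct(li):
        """Return (node_time, builder) or None; builder(parent_idx, top_time)
        emits the subtree into the output arrays."""
        here_samples = samples[li]
        if fate[li] == "speciation":
            subs = [r for r in (reconstruct(c) for c in kids[li]) if r is not None]
            if len(subs) == 2:
                node_time = t_end[li]

                def build(parent_idx, top_time, _subs=subs, _t=node_time):
                    idx = new_node(parent_idx, _t, top_time, None)
                    for st, sb in _subs:
                        sb(idx, _t)

                return t_birth[li], build
            if len(subs) == 1:
                st, sb = subs[0]
                return t_birth[li], sb  # pass-through: edge spans both lineages
            # no sampled descendants: fall through to own samples
        elif fate[li] == "extant" and keep_extant:
            node_time = t_end[li]
            counter[0] += 1
            lab = f"t{counter[0]}"

            def build(parent_idx, top_time, _t=node_time, _lab=lab):
                new_node(parent_idx, _t, top_time, _lab)

            return t_birth[li], build
        if here_samples:
            node_time = here_samples[-1]
            counter[0] += 1
            lab = f"t{counter[0]}"

            def build(parent_idx, top_time, _t=node_time, _lab=lab):
                new_node(parent_idx, _t, top_time, _lab)

            return t_birth[li], build
        return None

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(parent) + 1000))
    try:
        res = reconstruct(0)
        if res is None:
            return None
        _, build = res
        build(-1, 0.0)
    finally:
        sys.setrecursionlimit(old)
    if len(out_parent) < 2:
        return None
    try:
        return Phylogeny(out_parent, out_length, out_labels)
    except Exception:
        return None


# ------------------------------------------------------------- trait values


def simulate_continuous(
    tree: Phylogeny,
    name: str,
    params: dict,
    seed: int = 0,
    curve: EnvCurve | None = None,
    regimes: RegimeMap | None = None,
    root_age_ma: float | None = None,
    n_reps: int = 1,
):
    """Draw tip values under any of the continuous trait models.

    Gaussian models (everything except PULSED) are sampled exactly from the
    model's multivariate normal.  PULSED is simulated branch by branch (BM
    increment plus compound-Poisson normal jumps placed uniformly along the
    branch) and the true jump history is returned alongside:
    ``(values, histories)`` where each history maps node -> list of
    (time_from_branch_start, jump_size).

    Returns an array of shape (n_tips,) for ``n_reps == 1`` else
    (n_reps, n_tips), tips ordered as ``tree.tip_labels``.
    """
    from . import models as M

    rng = np.random.default_rng(seed)
    if name == "PULSED":
        return _simulate_pulsed(tree, params, rng, n_reps)
    if name in M.GAUSSIAN_MODELS:
        mean, cov = M.gaussian_mean_cov(tree, name, params)
    elif name in M.ENV_MODELS:
        if curve is None:
            raise ValueError(f"{name} requires a curve")
        T = tree.tip_depths
        root_age = tree.root_age_ma if root_age_ma is None else root_age_ma
        mean = M._env_ou_means(T, params["z0"], params["alpha"], params["theta0"],
                               params["beta"], curve, root_age, 0.25)
        cov = M._ou_fixed_root_cov(T, tree.shared_path_matrix(), params["alpha"],
                                   params["sigma2"])
    elif name in M.OUM_MODELS:
        if regimes is None:
            raise ValueError(f"{name} requires a regime painting")
        mean, cov = M.oum_mean_cov(regimes, params)
    else:
        raise ValueError(f"unknown model {name!r}; supported: {M.MODEL_NAMES}")
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(mean)))
    draws = mean + rng.standard_normal((n_reps, len(mean))) @ L.T
    return draws[0] if n_reps == 1 else draws


def _simulate_pulsed(tree: Phylogeny, params: dict, rng, n_reps: int):
    z0, s2 = params["z0"], params["sigma2"]
    lam, d2 = params["lam_jump"], params["delta2"]
    out = np.empty((n_reps, tree.n_tips))
    histories = []
    tip_pos = {t: k for k, t in enumerate(tree.tips)}
    for rep in range(n_reps):
        vals = np.empty(tree.n_nodes)
        hist: dict[int, list[tuple[float, float]]] = {}
        for v in tree.preorder():
            if v == tree.root:
                vals[v] = z0
                continue
            t = float(tree.length[v])
            inc = rng.normal(0.0, np.sqrt(s2 * t)) if s2 > 0 else 0.0
            nj = rng.poisson(lam * t) if lam > 0 else 0
            if nj and d2 > 0:
                times = np.sort(rng.uniform(0.0, t, nj))
                sizes = rng.normal(0.0, np.sqrt(d2), nj)
                hist[v] = list(zip(times.tolist(), sizes.tolist()))
                inc += sizes.sum()
            vals[v] = vals[tree.parent[v]] + inc
        out[rep] = [vals[t] for t in tree.tips]
        histories.append(hist)
    if n_reps == 1:
        return out[0], histories[0]
    return out, histories


def simulate_discrete(tree: Phylogeny, Q: np.ndarray, states, root_state, seed: int = 0):
    """Simulate a continuous-time Markov character along the tree.

    Returns ``(tip_states, history)`` where ``tip_states`` is a pandas
    Series indexed by tip label and ``history`` is the full :class:`RegimeMap`
    (segments ordered rootward -> tipward on every branch).
    """
    Q = np.asarray(Q, dtype=float)
    states = list(states)
    k = len(states)
    if Q.shape != (k, k):
        raise ValueError("Q shape does not match the state list")
    if np.any(Q - np.diag(np.diag(Q)) < 0) or np.any(np.abs(Q.sum(axis=1)) > 1e-9):
        raise ValueError("Q must have non-negative off-diagonals and zero row sums")
    idx = {s: i for i, s in enumerate(states)}
    rng = np.random.default_rng(seed)
    state_at = np.empty(tree.n_nodes, dtype=int)
    segs: list[list[tuple[float, str]]] = [[] for _ in range(tree.n_nodes)]
    for v in tree.preorder():
        if v == tree.root:
            state_at[v] = idx[root_state] if not isinstance(root_state, int) else root_state
            continue
        s = state_at[tree.parent[v]]
        t_left = float(tree.length[v])
        pieces: list[tuple[float, str]] = []
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                pieces.append((t_left, states[s]))
                break
            w = rng.exponential(1.0 / rate)
            if w >= t_left:
                pieces.append((t_left, states[s]))
                break
            pieces.append((w, states[s]))
            t_left -= w
            probs = Q[s].clip(min=0.0)
            probs[s] = 0.0
            s = rng.choice(k, p=probs / probs.sum())
        # merge zero-length artifacts (none expected, lengths are continuous)
        segs[v] = pieces
        state_at[v] = s
    tips = pd.Series({tree.labels[t]: states[state_at[t]] for t in tree.tips})
    node_regime = [states[state_at[v]] for v in range(tree.n_nodes)]
    return tips, RegimeMap(tree, segs, node_regime)


# -------------------------------------------------------------- environment


def simulate_env_curve(
    window: tuple[float, float],
    roughness: float = 1.0,
    seed: int = 0,
    base: float = 25.0,
    amplitude: float = 4.0,
    trend: float = 0.0,
    bounds: tuple[float, float] | None = None,
    step: float = 1.0,
    n_harmonics: int = 6,
) -> EnvCurve:
    """Generate a smooth environmental series sampled every ``step`` Myr.

    The curve is a sum of low-order harmonics with 1/k amplitude decay,
    scaled by ``roughness`` (0 gives a constant at ``base``), plus an
    optional linear ``trend`` per Myr toward the present, clipped to
    ``bounds``.  ``window`` is (older, younger) in Ma.
    """
    t0, t1 = window
    if not (t0 > t1 >= 0):
        raise ValueError("window must satisfy older > younger >= 0 (Ma)")
    rng = np.random.default_rng(seed)
    span = t0 - t1
    n = int(round(span / step))
    ages = t1 + step * np.arange(n + 1)
    vals = np.full(ages.shape, float(base))
    vals += trend * (t0 - ages)
    for kh in range(1, n_harmonics + 1):
        amp = roughness * amplitude / kh
        phase = rng.uniform(0, 2 * np.pi)
        vals += amp * rng.standard_normal() * np.sin(2 * np.pi * kh * (ages - t1) / span + phase)
    if bounds is not None:
        vals = np.clip(vals, bounds[0], bounds[1])
    return fit_smoothing_spline(np.c_[ages, vals], smoothing=0.0)


# ---------------------------------------------------------------- community


def simulate_community(
    n_taxa: int,
    mu_ln: float = 3.0,
    sigma_ln: float = 1.0,
    guild_mix: dict[str, float] | None = None,
    n_assemblages: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a faunal community table for the predator/prey analysis.

    Species sizes are log-normal (``mu_ln``, ``sigma_ln`` on ln cm); guilds
    are drawn from ``guild_mix`` (probabilities over :data:`GUILDS`);
    species are spread over ``n_assemblages`` assemblages.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if guild_mix is None:
        guild_mix = {
            "carnivorous_fish": 0.12, "nautiloid": 0.08, "eurypterine": 0.2,
            "stylonurine": 0.08, "hibbertopterid": 0.04, "sessile": 0.18,
            "mobile_benthic": 0.2, "nektonic": 0.1,
        }
    unknown = set(guild_mix) - set(GUILDS)
    if unknown:
        raise ValueError(f"unknown guilds in mix: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    names = [g for g in GUILDS if g in guild_mix]
    probs = np.array([guild_mix[g] for g in names], dtype=float)
    probs = probs / probs.sum()
    guilds = rng.choice(names, size=n_taxa, p=probs)
    sizes = np.exp(rng.normal(mu_ln, sigma_ln, n_taxa))
    eury = {"eurypterine", "stylonurine", "hibbertopterid"}
    return pd.DataFrame({
        "species": [f"sp{i+1}" for i in range(n_taxa)],
        "assemblage": rng.integers(1, n_assemblages + 1, n_taxa),
        "guild": guilds,
        "max_length_cm": sizes,
        "is_eurypterid": [g in eury for g in guilds],
    })


# ------------------------------------------------------------- full scenario


@dataclass
class ScenarioConfig:
    """Defaults for the synthetic sea-scorpion-like study scenario."""

    seed: int = 0
    n_tips: int = 135
    n_trees: int = 20
    window: tuple[float, float] = (467.0, 252.0)
    birth: float = 0.05
    death: float = 0.028
    psi: float = 0.04
    # pulsed size evolution (the dynamics the real data favour)
    z0: float = 2.8            # ln cm; e^2.8 ~ 16 cm root
    sigma2: float = 0.0015     # ln-cm^2 per Myr of gradual change
    lam_jump: float = 0.003    # jumps per lineage-Myr (a handful per tree)
    delta2: float = 1.0        # ln-cm^2 per jump: ~e-fold size shifts
    # ordered habitat transitions; marine <-> continental direct rate is 0
    q_marine_marginal: float = 0.004
    q_marginal_marine: float = 0.004
    q_marginal_continental: float = 0.003
    q_continental_marginal: float = 0.002
    branch_jitter_sd: float = 0.08
    community_taxa: int = 160


def habitat_rate_matrix(cfg: ScenarioConfig) -> np.ndarray:
    """Ordered 3-state Q: terrestrialization only through marginal settings."""
    q = np.array([
        [0.0, cfg.q_marine_marginal, 0.0],
        [cfg.q_marginal_marine, 0.0, cfg.q_marginal_continental],
        [0.0, cfg.q_continental_marginal, 0.0],
    ])
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def eurypterid_scenario(config: ScenarioConfig | None = None, seed: int | None = None) -> dict:
    """Generate a complete synthetic study: trees, traits, curves, community.

    Returns a dict with keys ``trees`` (TreeSet with mcc), ``traits``
    (DataFrame: taxon, max_length_cm, log_size, habitat, palaeolatitude_deg,
    clade, suborder), ``habitat_map`` (true RegimeMap on the mcc tree),
    ``temp_curve``, ``oxy_curve``, ``community``, ``config``.
    """
    cfg = config or ScenarioConfig()
    if seed is not None:
        cfg = ScenarioConfig(**{**cfg.__dict__, "seed": seed})
    root_age, end_age = cfg.window
    duration = root_age - end_age
    rng = np.random.default_rng(cfg.seed)

    base = simulate_fbd_tree(cfg.birth, cfg.death, cfg.psi, duration=duration,
                             seed=cfg.seed, min_tips=cfg.n_tips)
    if base.n_tips > cfg.n_tips:
        keep = list(rng.choice(base.tip_labels, size=cfg.n_tips, replace=False))
        base = prune_to_taxa(base, keep)
    base.root_age_ma = root_age
    # relabel tips to stable taxon names
    mapping = {lb: f"taxon_{i+1:03d}" for i, lb in enumerate(sorted(base.tip_labels))}
    base.labels = [mapping.get(lb) if lb is not None else None for lb in base.labels]

    # posterior-like tree set: multiplicative branch-length jitter
    trees = []
    for i in range(cfg.n_trees):
        t = Phylogeny(base.parent.copy(), base.length.copy(), list(base.labels),
                      root_age_ma=root_age)
        jit = np.exp(rng.normal(0.0, cfg.branch_jitter_sd, t.n_nodes))
        ln = t.length.copy()
        mask = np.arange(t.n_nodes) != t.root
        ln[mask] = ln[mask] * jit[mask]
        trees.append(Phylogeny(t.parent, ln, t.labels, root_age_ma=root_age))
    treeset = TreeSet(trees=trees, mcc=base)

    # habitat history and size evolution on the mcc tree
    Q = habitat_rate_matrix(cfg)
    tips_habitat, habitat_map = simulate_discrete(
        base, Q, HABITAT_STATES, "marine", seed=cfg.seed + 1
    )
    size_params = {"z0": cfg.z0, "sigma2": cfg.sigma2,
                   "lam_jump": cfg.lam_jump, "delta2": cfg.delta2}
    log_size, _hist = simulate_continuous(base, "PULSED", size_params, seed=cfg.seed + 2)

    # suborder = side of the root split (two principal clades)
    kids = base.children[base.root]
    desc = base.descendant_tips()
    side = np.zeros(base.n_tips, dtype=int)
    if len(kids) > 1:
        for pos in desc[kids[0]]:
            side[pos] = 1
    suborder = np.where(side == 1, "Eurypterina", "Stylonurina")

    labels = base.tip_labels
    traits = pd.DataFrame({
        "taxon": labels,
        "max_length_cm": np.exp(log_size),
        "log_size": log_size,
        "habitat": tips_habitat.reindex(labels).to_numpy(),
        "palaeolatitude_deg": rng.uniform(-45.0, 45.0, base.n_tips).round(2),
        "clade": suborder,
        "suborder": suborder,
    })

    margin = 5.0
    temp_curve = simulate_env_curve(
        (root_age + margin, max(end_age - margin, 0.0)), roughness=1.0,
        seed=cfg.seed + 3, base=26.0, amplitude=3.0, bounds=(12.0, 40.0))
    oxy_curve = simulate_env_curve(
        (root_age + margin, max(end_age - margin, 0.0)), roughness=1.0,
        seed=cfg.seed + 4, base=190.0, amplitude=25.0, trend=0.15, bounds=(100.0, 300.0))
    community = simulate_community(cfg.community_taxa, seed=cfg.seed + 5)
    return {
        "trees": treeset,
        "traits": traits,
        "habitat_map": habitat_map,
        "true_size_params": size_params,
        "temp_curve": temp_curve,
        "oxy_curve": oxy_curve,
        "community": community,
        "config": cfg,
    }
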