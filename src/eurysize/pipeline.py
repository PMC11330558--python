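"""Configuration-driven orchestration: simulate -> fit -> map -> rank -> report.

The pipeline consumes a YAML config naming the input files (trees, traits,
curves, community) and analysis settings, runs the stages in dependency
order and writes CSV/JSON outputs plus a reproducibility manifest into the
output directory.  Every stage is also callable directly from Python.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ecology, habitat, models, selection
from .envcurves import read_curve_csv
from .simulate import ScenarioConfig, eurypterid_scenario
from .tables import read_trait_table
from .trees import Phylogeny, TreeSet, prune_to_taxa, read_trees, write_trees

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "make_demo_data"]

ALL_MODELS = list(models.MODEL_NAMES)

LARGE_CM = 50.0
GIANT_CM = 100.0


class ConfigError(ValueError):
    """Raised when a run configuration fails validation; lists every issue."""


@dataclass
class RunConfig:
    """Settings for one full analysis run."""

    trees: str = ""
    mcc_tree: str = ""
    traits: str = ""
    temp_curve: str = ""
    oxy_curve: str = ""
    community: str = ""
    out_dir: str = "run_output"
    root_age_ma: float | None = None
    model_list: list = field(default_factory=lambda: list(ALL_MODELS))
    n_posterior_trees: int | None = None
    n_maps: int = 1000
    n_maps_summary: int = 200
    large_threshold_cm: float = LARGE_CM
    giant_threshold_cm: float = GIANT_CM
    crisis_age_ma: float = 372.0
    clade_column: str = "suborder"
    clade_filter: str | None = None   # e.g. "Eurypterina": rerun on that subtree only
    seed: int = 0
    n_restarts: int = 3
    rjmcmc_iterations: int = 0   # 0 skips the rjMCMC stage
    free_regime_dynamics: bool = False
    pgls_lambda: str = "fixed_1"
    n_perm: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        errors = []
        for key in ("trees", "traits"):
            p = getattr(self, key)
            if not p:
                errors.append(f"{key}: path required")
            elif not Path(p).exists():
                errors.append(f"{key}: file not found: {p}")
        for key in ("mcc_tree", "temp_curve", "oxy_curve", "community"):
            p = getattr(self, key)
            if p and not Path(p).exists():
                errors.append(f"{key}: file not found: {p}")
        bad = set(self.model_list) - set(ALL_MODELS)
        if bad:
            errors.append(f"unknown models: {sorted(bad)} (supported: {ALL_MODELS})")
        if self.large_threshold_cm <= 0 or self.giant_threshold_cm <= 0:
            errors.append("size thresholds must be positive")
        if self.n_maps < 1:
            errors.append("n_maps must be >= 1")
        needs_curve = {"ENV_OU_TEMP", "ENV_OU_OXY"} & set(self.model_list)
        if needs_curve and self.root_age_ma is None:
            errors.append("root_age_ma is required when environment-coupled models are fitted")
        if "ENV_OU_TEMP" in self.model_list and not self.temp_curve:
            errors.append("ENV_OU_TEMP requires temp_curve")
        if "ENV_OU_OXY" in self.model_list and not self.oxy_curve:
            errors.append("ENV_OU_OXY requires oxy_curve")
        if errors:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))


def run_pipeline(config: RunConfig, stages=("habitat", "fit", "rank", "ecology")) -> dict:
    """Execute the analysis described by ``config``; returns the results dict
    and writes every table plus a manifest under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ---- inputs
    treeset = read_trees(config.trees, root_age_ma=config.root_age_ma)
    if config.mcc_tree:
        mcc = read_trees(config.mcc_tree, root_age_ma=config.root_age_ma)[0]
    else:
        mcc = treeset[0]
    trees = list(treeset.trees)
    if config.n_posterior_trees:
        trees = trees[: config.n_posterior_trees]
    traits = read_trait_table(config.traits)
    traits = traits.set_index("taxon", drop=False)
    if config.clade_filter:
        col = config.clade_column
        if col not in traits.columns:
            raise ConfigError(f"clade_filter set but traits lack a {col!r} column")
        traits = traits[traits[col] == config.clade_filter]
        if len(traits) < 3:
            raise ConfigError(
                f"clade_filter {config.clade_filter!r} keeps {len(traits)} taxa (< 3)")
    keep = [t for t in mcc.tip_labels if t in traits.index]
    if len(keep) < mcc.n_tips:
        mcc = prune_to_taxa(mcc, keep)
        trees = [prune_to_taxa(t, keep) for t in trees]
    log_size = traits["log_size"]
    habitats = traits["habitat"]
    curves = {}
    if config.temp_curve:
        curves["ENV_OU_TEMP"] = read_curve_csv(config.temp_curve)
    if config.oxy_curve:
        curves["ENV_OU_OXY"] = read_curve_csv(config.oxy_curve)

    # ---- habitat stage: Mk selection, stochastic maps, colonizations
    maps_by_tree: dict[int, list] = {}
    if "habitat" in stages or any(m.startswith("OUM") for m in config.model_list):
        Q, structure, mk_table = habitat.best_mk(mcc, habitats, habitat.DEFAULT_STATES)
        mk_table.to_csv(out / "mk_model_selection.csv", index=False)
        results["mk_structure"] = structure
        results["mk_Q"] = Q
        maps = habitat.stochastic_map(
            mcc, habitats, Q, habitat.DEFAULT_STATES,
            n_maps=config.n_maps, seed=config.seed + 11,
        )
        results["maps"] = maps
        summ = habitat.summarize_maps(maps[: config.n_maps_summary])
        summ.ltt.to_csv(out / "habitat_ltt.csv", index=False)
        summ.node_freq.to_csv(out / "habitat_node_frequencies.csv", index=True)
        col = habitat.count_colonizations(maps, "continental")
        results["colonizations"] = col
        pd.DataFrame({"colonizations": col["counts"]}).to_csv(
            out / "continental_colonizations.csv", index=False)
        results["map_summary"] = summ
        if config.rjmcmc_iterations:
            rj = habitat.rjmcmc_mk(
                mcc, habitats, habitat.DEFAULT_STATES,
                n_iter=config.rjmcmc_iterations, seed=config.seed + 13,
            )
            results["rjmcmc"] = rj
            rj.structure_freq.rename("frequency").to_csv(out / "rjmcmc_structures.csv")
        # one painting per posterior tree, drawn under the selected Q
        for i, t in enumerate(trees):
            maps_by_tree[i] = habitat.stochastic_map(
                t, habitats, Q, habitat.DEFAULT_STATES, n_maps=1,
                seed=config.seed + 100 + i,
            )

    # ---- trait-model fitting across trees
    if "fit" in stages:
        rows = []
        fit_records = []
        for i, t in enumerate(trees):
            x = log_size.reindex(t.tip_labels).to_numpy()
            for name in config.model_list:
                kwargs = {}
                if name in ("ENV_OU_TEMP", "ENV_OU_OXY"):
                    kwargs = {"curve": curves[name], "root_age_ma": config.root_age_ma}
                elif name.startswith("OUM"):
                    base_map = maps_by_tree[i][0]
                    if name == "OUM3_HABITAT":
                        reg = habitat.paint_habitat_regimes(base_map, "three_peak")
                    elif name == "OUM2_HABITAT":
                        reg = habitat.paint_habitat_regimes(base_map, "two_peak")
                    else:
                        clades = _crisis_clades(t, traits, config)
                        reg = habitat.paint_crisis_regimes(
                            t, config.crisis_age_ma, clades[0], clades[1])
                    kwargs = {"regimes": reg,
                              "free_regime_dynamics": config.free_regime_dynamics}
                try:
                    fit = models.fit_model(
                        t, x, name, n_restarts=config.n_restarts,
                        seed=config.seed + 17, **kwargs)
                except ValueError:
                    continue
                rows.append({"tree": i, "model": name, "aicc": fit.aicc, "k": fit.k,
                             "lnL": fit.lnL, "converged": fit.converged,
                             **{f"p_{p}": v for p, v in fit.params.items()}})
                fit_records.append(fit)
        fits = pd.DataFrame(rows)
        fits.to_csv(out / "model_fits.csv", index=False)
        results["fits"] = fits

    # ---- ranking, origins, ancestral root
    if "rank" in stages and "fits" in results:
        rank = selection.rank_models(results["fits"])
        rank.to_csv(out / "model_ranking.csv")
        results["ranking"] = rank
        x_mcc = log_size.reindex(mcc.tip_labels).to_numpy()
        results["root"] = selection.ancestral_root(mcc, x_mcc)
        origin_rows = []
        for thr_name, thr_cm in (("large", config.large_threshold_cm),
                                 ("giant", config.giant_threshold_cm)):
            per_tree = [selection.count_size_origins(
                t, log_size.reindex(t.tip_labels).to_numpy(), np.log(thr_cm))
                for t in trees]
            mcc_count = selection.count_size_origins(mcc, x_mcc, np.log(thr_cm))
            origin_rows.append({
                "threshold": thr_name, "threshold_cm": thr_cm, "mcc": mcc_count,
                "min": int(np.min(per_tree)) if per_tree else mcc_count,
                "max": int(np.max(per_tree)) if per_tree else mcc_count,
                "median": float(np.median(per_tree)) if per_tree else mcc_count,
            })
        origins = pd.DataFrame(origin_rows)
        origins.to_csv(out / "size_origins.csv", index=False)
        results["origins"] = origins
        with open(out / "ancestral_root.json", "w") as fh:
            json.dump(results["root"], fh, indent=2)

    # ---- ecology stage
    if "ecology" in stages:
        if "palaeolatitude_deg" in traits.columns:
            pg_rows = []
            for i, t in enumerate(trees):
                try:
                    res = ecology.pgls(
                        t, log_size.reindex(t.tip_labels),
                        traits["palaeolatitude_deg"].reindex(t.tip_labels),
                        lambda_policy=config.pgls_lambda)
                except ValueError:
                    continue
                pg_rows.append({"tree": i, **{k: v for k, v in res.items() if k != "lnL"}})
            pg = pd.DataFrame(pg_rows)
            pg.to_csv(out / "pgls_latitude.csv", index=False)
            results["pgls"] = pg
        if config.community:
            community = pd.read_csv(config.community)
            eco = ecology.ecospace_table(community)
            eco.to_csv(out / "ecospace_records.csv", index=False)
            results["ecospace"] = eco
            if eco["size_group"].nunique() == 2:
                results["permanova"] = ecology.permutational_anova(
                    eco, n_perm=config.n_perm, seed=config.seed + 23)
                with open(out / "permanova.json", "w") as fh:
                    json.dump(results["permanova"], fh, indent=2)
            results["correlations"] = ecology.correlation_report(
                eco, n_perm=min(config.n_perm, 500), seed=config.seed + 29)
            results["correlations"].to_csv(out / "size_correlations.csv", index=False)

    _write_manifest(config, out)
    return results


def _crisis_clades(tree: Phylogeny, traits: pd.DataFrame, config: RunConfig):
    """Two surviving clades for the crisis painting: the post-crisis members
    of each value of the clade column (falling back to the two root
    subtrees)."""
    col = config.clade_column
    labels = [lb for lb in tree.tip_labels]
    if col in traits.columns and traits[col].nunique() >= 2:
        values = traits[col].reindex(labels)
        groups = [g for _, g in values.groupby(values)][:2]
        c1 = list(groups[0].index)
        c2 = list(groups[1].index)
    else:
        kids = tree.children[tree.root]
        desc = tree.descendant_tips()
        c1 = [labels[i] for i in desc[kids[0]]]
        c2 = [labels[i] for i in desc[kids[1]]] if len(kids) > 1 else []
    return c1, c2


def _write_manifest(config: RunConfig, out: Path) -> None:
    import eurysize

    cfg = asdict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "package_version": getattr(eurysize, "__version__", "unknown"),
        "numpy_version": np.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# ------------------------------------------------------------------ demo data


def make_demo_data(out_dir, seed: int = 0, config: ScenarioConfig | None = None) -> Path:
    """Write a self-contained synthetic scenario (trees, traits, curves,
    community and a ready-to-run YAML config) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = eurypterid_scenario(config=config, seed=seed)
    write_trees(sc["trees"], out / "posterior_trees.nwk")
    write_trees([sc["trees"].mcc], out / "mcc_tree.nwk")
    sc["traits"].to_csv(out / "traits.csv", index=False)
    for key, fname in (("temp_curve", "sea_surface_temperature.csv"),
                       ("oxy_curve", "dissolved_oxygen.csv")):
        curve = sc[key]
        pd.DataFrame({"age_ma": curve.ages, "value": curve.values}).to_csv(
            out / fname, index=False)
    sc["community"].to_csv(out / "community.csv", index=False)
    cfg = RunConfig(
        trees=str(out / "posterior_trees.nwk"),
        mcc_tree=str(out / "mcc_tree.nwk"),
        traits=str(out / "traits.csv"),
        temp_curve=str(out / "sea_surface_temperature.csv"),
        oxy_curve=str(out / "dissolved_oxygen.csv"),
        community=str(out / "community.csv"),
        out_dir=str(out / "results"),
        root_age_ma=sc["trees"].mcc.root_age_ma,
        crisis_age_ma=372.0,
        seed=seed,
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"seed": seed, "scenario": asdict(sc["config"])}, fh, indent=2)
    return out
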