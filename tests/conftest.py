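import numpy as np
import pytest

from eurysize.trees import Phylogeny


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2); root age 2 with the youngest tip at 0."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_tip():
    return Phylogeny.from_newick(
        "(((A:1.2,B:0.8):0.6,(C:0.9,D:1.4):0.3):0.5,(E:2.1,F:0.7):0.4);"
    )


def random_tree(n_tips: int, seed: int, birth: float = 0.3, death: float = 0.1,
                psi: float = 0.2, duration: float = 15.0) -> Phylogeny:
    """Small random fossil tree for property tests (deterministic per seed)."""
    from eurysize.simulate import simulate_fbd_tree

    t = simulate_fbd_tree(birth, death, psi, duration=duration, seed=seed,
                          min_tips=max(3, n_tips // 2))
    if t.n_tips > n_tips:
        from eurysize.trees import prune_to_taxa

        rng = np.random.default_rng(seed)
        keep = list(rng.choice(t.tip_labels, size=n_tips, replace=False))
        t = prune_to_taxa(t, keep)
    return t


@pytest.fixture(scope="session")
def scenario():
    """One small synthetic study scenario shared across tests."""
    from eurysize.simulate import ScenarioConfig, eurypterid_scenario

    cfg = ScenarioConfig(seed=42, n_trees=3)
    return eurypterid_scenario(config=cfg)
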