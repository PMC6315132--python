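import numpy as np
import pandas as pd
import pytest

import phylocomm as pc


@pytest.fixture
def three_tip_tree() -> pc.Phylogeny:
    """((A:1,B:1):1,C:2); — the worked micro-example tree."""
    return pc.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree() -> pc.Phylogeny:
    return pc.parse_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def yule_tree() -> pc.Phylogeny:
    return pc.simulate_tree(20, seed=101)


def random_community(tree_labels, n_plots, richness, rng, equal_weights=False):
    """Uniformly assembled plots with lognormal covers over a fixed pool."""
    pool = list(tree_labels)
    cover = pd.DataFrame(0.0, index=[f"p{i + 1:03d}" for i in range(n_plots)], columns=pool)
    for i in range(n_plots):
        sp = rng.choice(len(pool), size=richness, replace=False)
        vals = np.ones(richness) if equal_weights else rng.lognormal(0.0, 1.0, richness)
        cover.iloc[i, sp] = vals
    return pc.CommunityTable(cover=cover, ages=pd.Series(0.0, index=cover.index))


@pytest.fixture
def small_dataset():
    """A 20-species tree with BM traits and 6 uniform plots."""
    tree = pc.simulate_tree(20, seed=7)
    traits = pc.simulate_bm_traits(tree, seed=8)
    rng = np.random.default_rng(9)
    community = random_community(tree.tip_labels, 6, 8, rng)
    community.ages[:] = [4.0, 4.0, 27.0, 27.0, 203.0, 203.0]
    return tree, traits, community
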