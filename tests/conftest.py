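import numpy as np
import pandas as pd
import pytest

from fishdiv.tables import SurveyTable
from fishdiv.trees import Phylogeny


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    """Ultrametric 3-tip tree with pairwise distances AB=2, AC=BC=4."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def tiny_survey() -> SurveyTable:
    count = pd.DataFrame(
        [[3, 1, 0], [2, 0, 4]],
        index=["S1", "S2"], columns=["A", "B", "C"])
    biomass = pd.DataFrame(
        [[0.5, 0.2, 0.0], [0.4, 0.0, 1.2]],
        index=["S1", "S2"], columns=["A", "B", "C"])
    return SurveyTable(count, biomass)


def random_survey(rng: np.random.Generator, n_sites: int, species: list[str],
                  min_occ: int = 1) -> SurveyTable:
    """Random survey in which every site holds at least ``min_occ`` species."""
    n_sp = len(species)
    counts = np.zeros((n_sites, n_sp), dtype=int)
    for i in range(n_sites):
        k = int(rng.integers(min_occ, n_sp + 1))
        idx = rng.choice(n_sp, size=k, replace=False)
        counts[i, idx] = rng.integers(1, 40, size=k)
    sites = [f"S{i + 1}" for i in range(n_sites)]
    count = pd.DataFrame(counts, index=sites, columns=species)
    return SurveyTable(count, count * 0.05)


def random_tree(rng: np.random.Generator, n_tips: int) -> Phylogeny:
    """Random binary tree, exponential branch lengths (not ultrametric)."""
    labels = [f"t{i + 1}" for i in range(n_tips)]
    nodes = [f"{lab}:{rng.exponential(1.0):.6f}" for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(1.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return Phylogeny.from_newick(f"({nodes[0]},{nodes[1]});")
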