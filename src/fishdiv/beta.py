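"""Pairwise Sorensen beta-diversity partitioned into turnover and nestedness.

Both levels share one algebra.  For a site pair, let

* a = what the two communities share,
* b = what only the first holds,
* c = what only the second holds,

measured in species counts at the taxonomic level and in branch length at
the phylogenetic level (the PhyloSor construction: a is the length of
branches on both communities' spanning subtrees).  The Baselga partition
then gives

    beta_sor = (b + c) / (2a + b + c)            total dissimilarity
    beta_turn = min(b, c) / (a + min(b, c))      replacement (Simpson) part
    beta_nes = beta_sor - beta_turn              richness-difference part

computed from incidence (presence/absence) data.  The beta-deviation
statistic contrasts the two levels, beta_dev = (btax - bphy)/btax:
positive when compositional dissimilarity exceeds its phylogenetic
counterpart, i.e. communities swap close relatives.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import SurveyTable
from .trees import Phylogeny

__all__ = [
    "abc_taxonomic",
    "abc_phylogenetic",
    "sorensen_partition",
    "beta_matrices",
    "beta_summary",
    "beta_deviation",
    "compare_levels",
    "LevelComparison",
]


def abc_taxonomic(community_i, community_j) -> tuple[int, int, int]:
    """Shared / unique-to-i / unique-to-j species counts for a site pair."""
    si, sj = set(community_i), set(community_j)
    if not si or not sj:
        raise ValueError("beta-diversity undefined for an empty community")
    return len(si & sj), len(si - sj), len(sj - si)


def abc_phylogenetic(community_i, community_j, tree: Phylogeny,
                     include_root: bool = True) -> tuple[float, float, float]:
    """Branch-length (a, b, c): shared and unique branch length of the pair.

    Spanning subtrees include the root path by default, so that
    a + b = PD(i) and a + c = PD(j) under the matching PD convention.
    """
    if not len(list(community_i)) or not len(list(community_j)):
        raise ValueError("beta-diversity undefined for an empty community")
    mi = tree.community_edge_mask(community_i, include_root=include_root)
    mj = tree.community_edge_mask(community_j, include_root=include_root)
    lengths = tree.edge_lengths
    a = float(lengths[mi & mj].sum())
    b = float(lengths[mi & ~mj].sum())
    c = float(lengths[mj & ~mi].sum())
    return a, b, c


def sorensen_partition(a: float, b: float, c: float
                       ) -> tuple[float, float, float]:
    """(beta_sor, beta_turn, beta_nes) from the shared/unique components."""
    if min(a, b, c) < 0:
        raise ValueError("components must be non-negative")
    if a + b == 0 or a + c == 0:
        raise ValueError("a community with no content: beta undefined")
    denom = 2 * a + b + c
    beta_sor = (b + c) / denom
    m = min(b, c)
    beta_turn = m / (a + m) if (a + m) > 0 else 0.0
    beta_nes = beta_sor - beta_turn
    return beta_sor, beta_turn, beta_nes


def beta_matrices(survey: SurveyTable, tree: Phylogeny | None = None,
                  include_root: bool = True) -> pd.DataFrame:
    """All unordered site pairs x levels, long format.

    Columns: site_i, site_j, level (taxonomic / phylogenetic), sor, turn,
    nes.  Pairs involving a site with no species are emitted as NaN with a
    warning.  Phylogenetic rows require ``tree``.
    """
    if survey.n_sites < 2:
        raise ValueError("beta-diversity needs at least 2 sites")
    communities = {s: frozenset(survey.site_community(s)) for s in survey.sites}
    empty = [s for s, c in communities.items() if not c]
    if empty:
        warnings.warn(f"sites with no species; their pairs are NaN: {empty}",
                      stacklevel=2)
    levels = ["taxonomic"] + (["phylogenetic"] if tree is not None else [])
    rows = []
    for si, sj in itertools.combinations(survey.sites, 2):
        for level in levels:
            if si in empty or sj in empty:
                sor = turn = nes = float("nan")
            else:
                if level == "taxonomic":
                    a, b, c = abc_taxonomic(communities[si], communities[sj])
                else:
                    a, b, c = abc_phylogenetic(communities[si], communities[sj],
                                               tree, include_root=include_root)
                sor, turn, nes = sorensen_partition(a, b, c)
            rows.append({"site_i": si, "site_j": sj, "level": level,
                         "sor": sor, "turn": turn, "nes": nes})
    return pd.DataFrame(rows)


def beta_deviation(mean_beta_tax: float, mean_beta_phy: float) -> float:
    """(btax - bphy)/btax; NaN when taxonomic dissimilarity is zero."""
    if mean_beta_tax == 0:
        return float("nan")
    return (mean_beta_tax - mean_beta_phy) / mean_beta_tax


def beta_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-level means, turnover/nestedness shares (%) and beta deviation.

    Shares are ratios of means over pairs (not means of per-pair ratios) so
    turnover_share + nestedness_share = 100 exactly.  ``beta_dev`` is the
    taxonomic-vs-phylogenetic contrast on mean total beta, repeated on both
    rows for convenience.
    """
    out = []
    for level, grp in pairs.groupby("level", sort=False):
        ms, mt, mn = grp["sor"].mean(), grp["turn"].mean(), grp["nes"].mean()
        out.append({
            "level": level, "n_pairs": int(grp["sor"].notna().sum()),
            "mean_sor": ms, "mean_turn": mt, "mean_nes": mn,
            "turnover_share": 100.0 * mt / ms if ms > 0 else float("nan"),
            "nestedness_share": 100.0 * mn / ms if ms > 0 else float("nan"),
        })
    summary = pd.DataFrame(out).set_index("level")
    if {"taxonomic", "phylogenetic"} <= set(summary.index):
        summary["beta_dev"] = beta_deviation(
            summary.at["taxonomic", "mean_sor"],
            summary.at["phylogenetic", "mean_sor"])
    return summary


@dataclass
class LevelComparison:
    """Effect size of the phylogenetic-minus-taxonomic contrast on one component."""

    component: str
    cohens_d: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def compare_levels(pairs_tax, pairs_phy, component: str = "sor"
                   ) -> LevelComparison:
    """Cohen's d (phylogenetic minus taxonomic) with a normal-theory 95% CI.

    d < 0 means the taxonomic values run higher.  The p-value is Welch's
    two-sample t-test.  Accepts either the long beta_matrices frame
    (filtered by ``component``) or raw value vectors.
    """
    xt = _component_values(pairs_tax, component)
    xp = _component_values(pairs_phy, component)
    if len(xt) != len(xp):
        raise ValueError("levels must cover the same site pairs")
    if len(xt) < 2:
        return LevelComparison(component, *(float("nan"),) * 4, len(xt))
    n1, n2 = len(xp), len(xt)
    s_pool = math.sqrt(((n1 - 1) * np.var(xp, ddof=1)
                        + (n2 - 1) * np.var(xt, ddof=1)) / (n1 + n2 - 2))
    diff = float(np.mean(xp) - np.mean(xt))
    d = diff / s_pool if s_pool > 0 else math.copysign(math.inf, diff) if diff else 0.0
    se = math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2))) if math.isfinite(d) else float("nan")
    t = stats.ttest_ind(xp, xt, equal_var=False)
    return LevelComparison(component, d, d - 1.96 * se, d + 1.96 * se,
                           float(t.pvalue), n1)


def _component_values(pairs, component: str) -> np.ndarray:
    if isinstance(pairs, pd.DataFrame):
        vals = pairs[component].to_numpy(dtype=float)
    else:
        vals = np.asarray(pairs, dtype=float)
    return vals[~np.isnan(vals)]
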