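"""Synthetic reservoir surveys with controllable assembly structure.

The generator emulates a single-season gillnet/cage survey of a dammed
river: ~9 sites ordered by river distance from the dam, a pool of ~23 fish
species on an ultrametric tree, per-site counts and biomass, 11
environmental variables with monotone or saturating trends against
distance-to-dam, and river-path pairwise distances (optionally with a
tributary branch).

Community assembly is niche-based with two independent dials:

* ``gradient_strength`` narrows species' Gaussian response curves along
  the river axis, producing species replacement (turnover);
* ``nestedness_strength`` imposes ordered retention — species carry a
  persistence score and sites farther along the axis keep only the
  high-score species — producing subset (nestedness) structure.

A configurable fraction of "invader" species is forced present at every
site, mimicking widespread introduced species.  Optional Brownian motion
on the tree gives niche optima phylogenetic signal, letting phylogenetic
beta-structure track or decouple from the taxonomic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .tables import EnvironmentTable, SpatialLayout, SurveyTable
from .trees import Phylogeny

__all__ = [
    "ScenarioSpec",
    "simulate_phylogeny",
    "simulate_layout",
    "simulate_environment",
    "simulate_survey",
    "simulate_scenario",
    "DEFAULT_ENV_TRENDS",
]

#: per-variable (direction, shape, baseline, amplitude, noise SD) against
#: normalized dam distance; units follow the field campaign (WT degC, WD m,
#: turbidity NTU, oxygen-demand and nutrient variables mg/L, CHL.a ug/mL).
DEFAULT_ENV_TRENDS: dict[str, tuple[str, str, float, float, float]] = {
    "CODMn": ("up", "saturating", 1.0, 2.0, 0.15),
    "COD":   ("up", "linear", 5.0, 10.0, 0.8),
    "TN":    ("up", "linear", 1.0, 1.5, 0.12),
    "NTU":   ("up", "linear", 2.0, 6.0, 0.5),
    "SO4":   ("down", "saturating", 40.0, 40.0, 2.5),
    "WD":    ("down", "linear", 25.0, 35.0, 2.0),
    "WT":    ("none", "flat", 16.0, 0.0, 0.5),
    "pH":    ("none", "flat", 7.8, 0.0, 0.15),
    "TP":    ("none", "flat", 0.03, 0.0, 0.006),
    "NN":    ("none", "flat", 0.012, 0.0, 0.003),
    "CHL.a": ("none", "flat", 0.005, 0.0, 0.001),
}


@dataclass
class ScenarioSpec:
    """Knobs of the synthetic survey (defaults sized like the field campaign:
    9 sites, 23 species, ~11 species and ~135 individuals per site)."""

    n_sites: int = 9
    n_species: int = 23
    gradient_strength: float = 1.5     # >0 narrows niches -> turnover
    nestedness_strength: float = 0.8   # >0 ordered richness loss -> nestedness
    abundance_sigma: float = 1.0       # log-normal spread of species abundance
    invader_fraction: float = 2 / 23   # share of species present everywhere
    phylo_signal: float = 0.0          # 0 = optima independent of the tree
    mean_mass_kg: float = 0.044        # per-individual mass scale
    mass_sigma: float = 0.7
    site_abundance: float = 135.0      # target individuals per site
    river_length_km: float = 30.0
    tributary: bool = False
    env_trends: dict = field(default_factory=lambda: dict(DEFAULT_ENV_TRENDS))
    env_noise_scale: float = 1.0       # multiplies every variable's noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        if self.gradient_strength < 0 or self.nestedness_strength < 0:
            raise ValueError("strengths must be >= 0")
        if not 0.0 <= self.invader_fraction <= 1.0:
            raise ValueError("invader_fraction must be in [0, 1]")

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


class _Lineage:
    __slots__ = ("birth", "children", "end")

    def __init__(self, birth: float):
        self.birth = birth
        self.children: list["_Lineage"] | None = None
        self.end: float | None = None


def simulate_phylogeny(n_species: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree rescaled to height 1, tips sp001..spN.

    Lineages split at exponential waiting times (rate = number of active
    lineages); all surviving lineages are cut at the present, so the tree
    is ultrametric by construction and binary with n - 1 internal nodes.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    root = _Lineage(0.0)
    left, right = _Lineage(0.0), _Lineage(0.0)
    root.children = [left, right]
    active = [left, right]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active[k]
        parent.end = t
        c1, c2 = _Lineage(t), _Lineage(t)
        parent.children = [c1, c2]
        active[k] = c1
        active.append(c2)
    t_end = t + rng.exponential(1.0 / len(active))
    for lin in active:
        lin.end = t_end
    counter = [0]

    def newick(node: _Lineage) -> str:
        length = (node.end - node.birth) / t_end
        if node.children is None:
            counter[0] += 1
            return f"sp{counter[0]:03d}:{length:.12f}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{length:.12f}"

    root.end = 0.0
    inner = ",".join(newick(c) for c in root.children)
    return Phylogeny.from_newick(f"({inner});")


def simulate_layout(n_sites: int, river_length_km: float = 30.0, seed: int = 0,
                    tributary: bool = False) -> SpatialLayout:
    """Sites ordered upstream from the dam along the river axis.

    Positions are evenly spread with jitter, so dam distance increases with
    site number.  With ``tributary``, the last third of the sites sit on a
    branch leaving the main stem at the preceding site's position: pairwise
    river distances then run through the junction and are no longer plain
    differences of dam distances.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    frac = (np.arange(n_sites) + 0.5 + rng.uniform(-0.3, 0.3, n_sites)) / n_sites
    main_pos = np.sort(frac) * river_length_km
    sites = [f"S{i + 1}" for i in range(n_sites)]

    n_branch = n_sites // 3 if tributary else 0
    on_branch = np.zeros(n_sites, dtype=bool)
    dam = main_pos.copy()
    offset = np.zeros(n_sites)
    if n_branch:
        on_branch[-n_branch:] = True
        # the branch departs BELOW the upper main-stem sites, so pairs that
        # straddle the junction must travel down to it and back up
        j_idx = max(n_sites - 2 * n_branch - 1, 0)
        junction = main_pos[j_idx]
        offset[-n_branch:] = main_pos[-n_branch:] - junction
        dam[-n_branch:] = junction + offset[-n_branch:]
    else:
        junction = 0.0

    pair = np.zeros((n_sites, n_sites))
    for i in range(n_sites):
        for j in range(n_sites):
            if on_branch[i] == on_branch[j]:
                pair[i, j] = abs(dam[i] - dam[j])
            else:
                mi, bj = (i, j) if on_branch[j] else (j, i)
                pair[i, j] = abs(main_pos[mi] - junction) + offset[bj]
    return SpatialLayout(
        dam_distance=pd.Series(dam, index=sites, name="dam_km"),
        pair_distance=pd.DataFrame(pair, index=sites, columns=sites),
    )


def simulate_environment(spec: ScenarioSpec, layout: SpatialLayout,
                         seed: int | None = None) -> EnvironmentTable:
    """Environmental table with the configured trends against dam distance.

    Four variables increase away from the dam and two decrease (one of each
    saturating rather than linear); the rest are pure observation noise
    around their baseline.  Gaussian noise is added to every variable.
    """
    rng = np.random.default_rng(spec.seed + 7919 if seed is None else seed)
    x = layout.dam_distance.to_numpy()
    x = x / x.max() if x.max() > 0 else x
    cols = {}
    for name, (direction, shape, base, amp, noise_sd) in spec.env_trends.items():
        if shape == "saturating":
            trend = 1.0 - np.exp(-3.0 * x)
        elif shape == "linear":
            trend = x
        else:
            trend = np.zeros_like(x)
        if direction == "down":
            trend = 1.0 - trend
        elif direction == "none":
            trend = np.zeros_like(x)
        vals = base + amp * trend + rng.normal(0.0, noise_sd * spec.env_noise_scale,
                                               x.size)
        cols[name] = vals
    return EnvironmentTable(pd.DataFrame(cols, index=layout.sites))


def _niche_optima(spec: ScenarioSpec, tree: Phylogeny,
                  rng: np.random.Generator) -> np.ndarray:
    """Species optima on the [0, 1] river axis, optionally tree-correlated.

    With phylo_signal > 0, a Brownian-motion trait on the tree is blended
    with independent noise and mapped through the normal CDF, so close
    relatives get close optima while the marginal stays ~uniform.
    """
    n = tree.n_tips
    if spec.phylo_signal <= 0:
        return rng.uniform(0.0, 1.0, n)
    cov = _shared_path_cov(tree)
    bm = rng.multivariate_normal(np.zeros(n), cov + 1e-9 * np.eye(n))
    bm = (bm - bm.mean()) / (bm.std() + 1e-12)
    w = min(spec.phylo_signal, 1.0)
    mix = w * bm + np.sqrt(1.0 - w ** 2) * rng.normal(size=n)
    return norm.cdf(mix)


def _shared_path_cov(tree: Phylogeny) -> np.ndarray:
    """BM covariance: shared root-to-tip path length between tip pairs."""
    inc = tree.edge_below.astype(float)
    return inc.T @ np.diag(tree.edge_lengths) @ inc


def simulate_survey(spec: ScenarioSpec, tree: Phylogeny,
                    layout: SpatialLayout | None = None) -> SurveyTable:
    """Counts and biomass from niche filtering + ordered retention.

    Presence of species k at site i is Bernoulli with probability
    p_niche(i, k) * p_keep(i, k): a Gaussian response around the species
    optimum whose width shrinks with ``gradient_strength``, times a steep
    logistic retention gate comparing the species' persistence score with a
    site threshold that climbs along the axis with ``nestedness_strength``.
    Counts are Poisson around a log-normal species abundance scaled to hit
    ``site_abundance`` on average; biomass is count x log-normal body mass.
    """
    if tree.n_tips != spec.n_species:
        raise ValueError("tree tip count must equal n_species")
    rng = np.random.default_rng(spec.seed)
    if layout is None:
        layout = simulate_layout(spec.n_sites, spec.river_length_km,
                                 seed=spec.seed + 104729,
                                 tributary=spec.tributary)
    x = layout.dam_distance.to_numpy()
    x = x / x.max() if x.max() > 0 else x
    species = tree.tips
    n_sites, n_sp = len(x), len(species)

    optima = _niche_optima(spec, tree, rng)
    if spec.gradient_strength > 0:
        width = 0.35 / spec.gradient_strength
        p_niche = np.exp(-0.5 * ((x[:, None] - optima[None, :]) / width) ** 2)
    else:
        p_niche = np.ones((n_sites, n_sp))    # no niche filtering at all

    score = rng.uniform(0.0, 1.0, n_sp)         # persistence under retention
    nest_frac = spec.nestedness_strength / (1.0 + spec.nestedness_strength)
    threshold = nest_frac * x
    p_keep = 1.0 / (1.0 + np.exp(-12.0 * (score[None, :] - threshold[:, None])))

    presence = rng.random((n_sites, n_sp)) < p_niche * p_keep
    n_invaders = int(round(spec.invader_fraction * n_sp))
    if n_invaders:
        invaders = rng.choice(n_sp, size=n_invaders, replace=False)
        presence[:, invaders] = True

    # species abundance scale, log-normal across species, calibrated so the
    # expected per-site total matches spec.site_abundance
    raw = rng.lognormal(0.0, spec.abundance_sigma, n_sp)
    intensity = presence * p_niche.clip(0.25, None) * raw[None, :]
    row_mean = intensity.sum(axis=1).mean()
    if row_mean > 0:
        intensity *= spec.site_abundance / row_mean
    counts = np.where(presence, 1 + rng.poisson(intensity), 0)

    mass = rng.lognormal(np.log(spec.mean_mass_kg), spec.mass_sigma, n_sp)
    biomass = counts * mass[None, :]

    sites = layout.sites
    return SurveyTable(
        count=pd.DataFrame(counts, index=sites, columns=species),
        biomass=pd.DataFrame(biomass, index=sites, columns=species),
    )


def simulate_scenario(spec: ScenarioSpec
                      ) -> tuple[SurveyTable, Phylogeny, EnvironmentTable,
                                 SpatialLayout]:
    """All four inputs of the pipeline from one scenario seed."""
    tree = simulate_phylogeny(spec.n_species, seed=spec.seed + 15485863)
    layout = simulate_layout(spec.n_sites, spec.river_length_km,
                             seed=spec.seed + 104729, tributary=spec.tributary)
    env = simulate_environment(spec, layout)
    survey = simulate_survey(spec, tree, layout)
    return survey, tree, env, layout
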