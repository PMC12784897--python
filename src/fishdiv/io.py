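"""Readers and writers for the survey, tree, environment and spatial inputs.

The canonical survey format is a long CSV — one row per (site, species)
occurrence with ``site,species,count,biomass`` columns — because count and
biomass are paired per cell.  Wide count/biomass matrices are accepted for
convenience.  Trees are newick with branch lengths; the environment and
spatial tables are plain CSV with a header row, UTF-8 throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import EnvironmentTable, SpatialLayout, SurveyTable, ValidationError
from .trees import Phylogeny

__all__ = [
    "read_survey",
    "write_survey",
    "read_phylogeny",
    "read_environment",
    "read_spatial",
    "write_spatial",
    "write_environment",
    "align_inputs",
    "AlignedBundle",
]

log = logging.getLogger("fishdiv")


def read_survey(path: str, layout: str = "long",
                biomass_path: str | None = None) -> SurveyTable:
    """Load a survey table.

    ``layout='long'``: one CSV with columns site, species, count, biomass.
    ``layout='wide'``: ``path`` is the site x species count matrix and
    ``biomass_path`` the matching biomass matrix (zeros if omitted).
    """
    if layout == "long":
        df = pd.read_csv(path)
        required = {"site", "species", "count", "biomass"}
        if not required <= set(df.columns):
            raise ValidationError(f"long survey CSV needs columns {sorted(required)}")
        if df.duplicated(["site", "species"]).any():
            dups = df[df.duplicated(["site", "species"], keep=False)]
            raise ValidationError(
                "duplicate (site, species) rows: "
                f"{dups[['site', 'species']].values.tolist()[:5]}")
        count = df.pivot(index="site", columns="species", values="count").fillna(0)
        biomass = df.pivot(index="site", columns="species", values="biomass").fillna(0.0)
        # preserve first-appearance order of labels
        count = count.loc[df["site"].unique(), df["species"].unique()]
        biomass = biomass.loc[count.index, count.columns]
    elif layout == "wide":
        count = pd.read_csv(path, index_col=0)
        if biomass_path is not None:
            biomass = pd.read_csv(biomass_path, index_col=0)
        else:
            biomass = count * 0.0
    else:
        raise ValueError("layout must be 'long' or 'wide'")
    return SurveyTable(count=count, biomass=biomass.astype(float))


def write_survey(survey: SurveyTable, path: str) -> None:
    """Write the canonical long CSV (site, species, count, biomass)."""
    rows = []
    for site in survey.sites:
        for sp in survey.species:
            c = int(survey.count.at[site, sp])
            if c > 0:
                rows.append((site, sp, c, float(survey.biomass.at[site, sp])))
    pd.DataFrame(rows, columns=["site", "species", "count", "biomass"]) \
        .to_csv(path, index=False)


def read_phylogeny(path: str) -> Phylogeny:
    """Load a rooted newick tree; logs the ultrametricity check."""
    tree = Phylogeny.from_path(path)
    if tree.is_ultrametric():
        log.info("tree is ultrametric (height %.6g)", tree.height)
    else:
        log.warning("tree is NOT ultrametric (root-to-tip spread exceeds "
                    "1e-6 x height); metrics remain defined")
    return tree


def read_environment(path: str) -> EnvironmentTable:
    return EnvironmentTable(pd.read_csv(path, index_col=0))


def write_environment(env: EnvironmentTable, path: str) -> None:
    env.values.to_csv(path)


def read_spatial(dam_path: str, pair_path: str) -> SpatialLayout:
    """Dam distances (site, dam_km CSV) plus the square river-distance matrix."""
    dam = pd.read_csv(dam_path, index_col=0).iloc[:, 0]
    pair = pd.read_csv(pair_path, index_col=0)
    pair.columns = pair.columns.astype(dam.index.dtype)
    return SpatialLayout(dam_distance=dam, pair_distance=pair)


def write_spatial(layout: SpatialLayout, dam_path: str, pair_path: str) -> None:
    layout.dam_distance.rename("dam_km").to_frame().to_csv(dam_path)
    layout.pair_distance.to_csv(pair_path)


@dataclass
class AlignedBundle:
    survey: SurveyTable
    tree: Phylogeny
    env: EnvironmentTable
    space: SpatialLayout


def align_inputs(survey: SurveyTable, tree: Phylogeny, env: EnvironmentTable,
                 space: SpatialLayout, policy: str = "strict") -> AlignedBundle:
    """Make all inputs label-consistent.

    After alignment the site sets are identical everywhere and the survey
    species are a subset of the tree tips.  ``strict`` (default) errors on
    any mismatch, naming the offending labels — silently dropping species
    would change every phylogenetic quantity.  ``prune`` drops extra tree
    tips, survey species missing from the tree, and non-shared sites, each
    with a warning.  Idempotent: aligning an aligned bundle is a no-op.
    """
    if policy not in ("strict", "prune"):
        raise ValueError("policy must be 'strict' or 'prune'")
    s_sites = set(survey.sites)
    e_sites, p_sites = set(env.sites), set(space.sites)
    sp_survey, sp_tree = set(survey.species), set(tree.tips)

    if policy == "strict":
        problems = []
        if s_sites != e_sites:
            problems.append(f"survey/environment site mismatch: "
                            f"{sorted(s_sites ^ e_sites)}")
        if s_sites != p_sites:
            problems.append(f"survey/spatial site mismatch: "
                            f"{sorted(s_sites ^ p_sites)}")
        missing = sp_survey - sp_tree
        if missing:
            problems.append(f"survey species absent from tree: {sorted(missing)}")
        if problems:
            raise ValidationError("; ".join(problems))
        if sp_tree - sp_survey:
            tree = tree.prune_to(survey.species)
        env = EnvironmentTable(env.values.loc[survey.sites].copy())
        space = SpatialLayout(
            dam_distance=space.dam_distance.loc[survey.sites].copy(),
            pair_distance=space.pair_distance.loc[survey.sites,
                                                  survey.sites].copy(),
        )
        return AlignedBundle(survey, tree, env, space)

    shared_sites = [s for s in survey.sites if s in e_sites and s in p_sites]
    if set(shared_sites) != s_sites | e_sites | p_sites:
        warnings.warn(
            f"restricting to {len(shared_sites)} shared sites", stacklevel=2)
    missing = sorted(sp_survey - sp_tree)
    if missing:
        warnings.warn(f"dropping survey species absent from tree: {missing}",
                      stacklevel=2)
    keep_species = [sp for sp in survey.species if sp in sp_tree]
    survey = SurveyTable(
        count=survey.count.loc[shared_sites, keep_species].copy(),
        biomass=survey.biomass.loc[shared_sites, keep_species].copy(),
    )
    if set(tree.tips) != set(survey.species):
        tree = tree.prune_to(survey.species)
    env = EnvironmentTable(env.values.loc[shared_sites].copy())
    space = SpatialLayout(
        dam_distance=space.dam_distance.loc[shared_sites].copy(),
        pair_distance=space.pair_distance.loc[shared_sites, shared_sites].copy(),
    )
    return AlignedBundle(survey, tree, env, space)
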