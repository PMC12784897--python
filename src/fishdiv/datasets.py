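"""Bundled reference data: the Dongfeng Reservoir fish composition table.

The published survey tabulates, for each of the 23 species caught across
the 9 sites, the occurrence frequency (OF, % of sites), relative abundance
(RA, % of individuals) and relative biomass (RB, % of total biomass),
printed to 2 decimal places.  Those marginals are enough to evaluate the
index of relative importance and the dominance classification, and to
count the taxonomic composition (species / families / orders); the full
site x species matrix itself was not released.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .alpha_tax import iri_from_proportions

__all__ = ["load_reservoir_composition", "composition_summary", "reservoir_iri"]


def load_reservoir_composition() -> pd.DataFrame:
    """Species-level composition of the reservoir survey.

    Returns a frame indexed by species with order/family plus Fi, Ni, Wi
    converted from the printed percentages to proportions in [0, 1].
    """
    path = resources.files("fishdiv.data") / "dongfeng_composition.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    df = df.rename(columns={"of_pct": "Fi", "ra_pct": "Ni", "rb_pct": "Wi"})
    df[["Fi", "Ni", "Wi"]] = df[["Fi", "Ni", "Wi"]] / 100.0
    return df.set_index("species")


def composition_summary(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Counts of species, families and orders in a composition table."""
    if table is None:
        table = load_reservoir_composition()
    return {
        "n_species": int(table.index.nunique()),
        "n_families": int(table["family"].nunique()),
        "n_orders": int(table["order"].nunique()),
    }


def reservoir_iri(thresholds: tuple[float, float] = (500.0, 100.0)) -> pd.DataFrame:
    """IRI and dominance class recomputed from the printed proportions."""
    comp = load_reservoir_composition()
    return iri_from_proportions(comp[["Fi", "Ni", "Wi"]], thresholds)
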