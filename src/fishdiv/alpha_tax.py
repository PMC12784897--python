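"""Taxonomic alpha-diversity, dominance (IRI) and sampling completeness.

Richness and evenness follow the classic formulations: Margalef
D = (S - 1)/ln N, Shannon H' with natural logs, and Pielou J = H'/ln S.
Community divergence is the per-site Euclidean distance of the
Hellinger-transformed abundance profile from the community centroid.

Species dominance uses the index of relative importance,

    IRI = 10000 * Fi * (Ni + Wi),

with Fi the proportion of sites occupied, Ni the species' share of all
individuals and Wi its share of all biomass (all proportions in [0, 1]).
IRI > 500 marks a dominant species, values in [100, 500] common, and
below 100 rare.

Sampling completeness is reported two ways: the abundance-based coverage
estimator C-hat (Chao & Jost style, from singleton/doubleton counts) and
the exact hypergeometric rarefaction (species-accumulation) curve.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .tables import SurveyTable

__all__ = [
    "margalef",
    "shannon",
    "pielou",
    "hellinger_divergence",
    "alpha_table",
    "iri_score",
    "classify_iri",
    "iri_table",
    "iri_from_proportions",
    "sample_coverage",
    "rarefaction_curve",
]


def margalef(s: int, n: int) -> float:
    """Margalef richness (S - 1)/ln N; NaN for an empty sample."""
    if n == 0:
        return float("nan")
    if s <= 1:
        return 0.0
    if n == 1:
        raise ValueError("more species than individuals")
    return (s - 1) / np.log(n)


def shannon(abundances) -> float:
    """Shannon entropy H' (natural log), zeros ignored."""
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        return float("nan")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def pielou(abundances) -> float:
    """Pielou evenness J = H'/ln S in (0, 1]; NaN when fewer than 2 species."""
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    if x.size < 2:
        return float("nan")
    return shannon(x) / np.log(x.size)


def hellinger_divergence(survey: SurveyTable) -> pd.Series:
    """Distance of each site's Hellinger profile from the community centroid.

    The Hellinger transform is sqrt of within-site relative abundance, so
    the result depends only on composition, not on site totals.  Sites with
    no individuals get NaN with a warning.
    """
    counts = survey.count.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    out = np.full(len(totals), np.nan)
    ok = totals > 0
    if not ok.all():
        empty = [s for s, o in zip(survey.sites, ok) if not o]
        warnings.warn(f"sites with zero total count: {empty}", stacklevel=2)
    prof = np.sqrt(counts[ok] / totals[ok, None])
    centroid = prof.mean(axis=0)
    out[ok] = np.sqrt(((prof - centroid) ** 2).sum(axis=1))
    return pd.Series(out, index=survey.sites, name="hellinger_div")


def alpha_table(survey: SurveyTable) -> pd.DataFrame:
    """One row per site: S, N, Margalef, Shannon, Pielou, Hellinger divergence."""
    counts = survey.count
    hell = hellinger_divergence(survey)
    rows = []
    for site in survey.sites:
        row = counts.loc[site].to_numpy(dtype=float)
        s = int((row > 0).sum())
        n = int(row.sum())
        rows.append({
            "site": site,
            "S": s,
            "N": n,
            "margalef": margalef(s, n) if n > 0 else float("nan"),
            "shannon": shannon(row),
            "pielou": pielou(row),
            "hellinger_div": hell[site],
        })
    return pd.DataFrame(rows).set_index("site")


# -- dominance ------------------------------------------------------------

def iri_score(fi: float, ni: float, wi: float) -> float:
    """IRI = 10000 * Fi * (Ni + Wi), all inputs proportions in [0, 1]."""
    for name, v in (("Fi", fi), ("Ni", ni), ("Wi", wi)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
    return 10000.0 * fi * (ni + wi)


def classify_iri(value: float, thresholds: tuple[float, float] = (500.0, 100.0)) -> str:
    """dominant above the upper threshold (strict), common within, rare below."""
    hi, lo = thresholds
    if value > hi:
        return "dominant"
    if value >= lo:
        return "common"
    return "rare"


def iri_table(survey: SurveyTable,
              thresholds: tuple[float, float] = (500.0, 100.0)) -> pd.DataFrame:
    """Per-species Fi, Ni, Wi, IRI and dominance class, sorted by IRI descending."""
    counts = survey.count
    biomass = survey.biomass
    n_sites = survey.n_sites
    tot_n = counts.to_numpy().sum()
    tot_w = biomass.to_numpy().sum()
    if tot_w == 0 and tot_n > 0:
        warnings.warn("zero total biomass; Wi terms set to 0", stacklevel=2)
    fi = (counts > 0).sum(axis=0) / n_sites
    ni = counts.sum(axis=0) / tot_n if tot_n > 0 else counts.sum(axis=0) * 0.0
    wi = biomass.sum(axis=0) / tot_w if tot_w > 0 else biomass.sum(axis=0) * 0.0
    iri = 10000.0 * fi * (ni + wi)
    out = pd.DataFrame({
        "Fi": fi, "Ni": ni, "Wi": wi, "iri": iri,
        "class": [classify_iri(v, thresholds) for v in iri],
    })
    out.index.name = "species"
    return out.sort_values("iri", ascending=False)


def iri_from_proportions(table: pd.DataFrame,
                         thresholds: tuple[float, float] = (500.0, 100.0)
                         ) -> pd.DataFrame:
    """IRI from pre-tabulated proportions (columns Fi, Ni, Wi in [0, 1])."""
    iri = np.array([iri_score(r.Fi, r.Ni, r.Wi) for r in table.itertuples()])
    out = table.copy()
    out["iri"] = iri
    out["class"] = [classify_iri(v, thresholds) for v in iri]
    return out


# -- sampling completeness -------------------------------------------------

def sample_coverage(abundances) -> float:
    """Abundance-based coverage estimate from singletons/doubletons.

    C-hat = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2); 1.0 when there are
    no singletons, NaN for an empty sample.
    """
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    n = x.sum()
    if n == 0:
        return float("nan")
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    denom = (n - 1) * f1 + 2 * f2
    return float(1.0 - (f1 / n) * ((n - 1) * f1 / denom))


def rarefaction_curve(abundances, depths) -> np.ndarray:
    """Expected species richness at each subsample depth m (no extrapolation).

    E[S_m] = sum_k [1 - C(n - n_k, m)/C(n, m)], the exact hypergeometric
    expectation; evaluated in log space for numerical safety.
    """
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    n = int(x.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=int))
    if np.any(depths > n):
        raise ValueError(f"depth exceeds sample size n={n}")
    if np.any(depths < 1):
        raise ValueError("depths must be >= 1")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(depths.size, dtype=float)
    for i, m in enumerate(depths):
        terms = np.zeros(x.size)
        feasible = (n - x) >= m          # else the species is certainly drawn
        a = n - x[feasible]
        with np.errstate(divide="ignore"):
            terms[feasible] = np.exp(log_choose(a, m) - log_choose(n, m))
        out[i] = float((1.0 - terms).sum())
    return out
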