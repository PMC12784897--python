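"""Phylogenetic alpha-diversity and its standardized effect sizes.

Three per-site metrics:

* Faith PD — total branch length of the subtree spanning the community
  (root path included by default, so the full species pool recovers the
  whole tree and a single species still carries its root-ward history);
* MPD.abu — mean patristic distance over distinct species pairs, each pair
  weighted by the product of the two species' relative abundances;
* VPD.abu — the matching abundance-weighted variance of pairwise distances.

The null model is the tip-label shuffle ("taxa labels"): the community
matrix is untouched while species identities are permuted uniformly over
the pooled species list (every species observed anywhere in the survey),
re-dealing tree positions.  SES = (obs - null mean)/null SD, with a
rank-based p using the add-one rule, (count(null <= obs) + 1)/(n_perm + 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tables import SurveyTable
from .trees import Phylogeny

__all__ = ["faith_pd", "mpd_vpd_abu", "phylo_alpha_table", "ses_null"]

_METRICS = ("pd", "mpd_abu", "vpd_abu")


def faith_pd(community, tree: Phylogeny, include_root: bool = True) -> float:
    """Sum of branch lengths of the subtree spanning ``community``'s tips."""
    community = list(community)
    if not community:
        raise ValueError("empty community has no PD")
    mask = tree.community_edge_mask(community, include_root=include_root)
    return float(tree.edge_lengths[mask].sum())


def mpd_vpd_abu(abundances: dict | pd.Series, tree: Phylogeny
                ) -> tuple[float, float]:
    """Abundance-weighted mean and variance of pairwise patristic distances.

    Weights are f_i * f_j over distinct unordered pairs i < j (between-species
    pairs only; self-pairs excluded).  A single-species community has no
    pairs: both values are NaN.
    """
    if isinstance(abundances, dict):
        abundances = pd.Series(abundances)
    abundances = abundances[abundances > 0]
    labels = list(abundances.index)
    if len(labels) < 2:
        return float("nan"), float("nan")
    f = abundances.to_numpy(dtype=float)
    f = f / f.sum()
    d = tree.patristic_matrix(labels)
    # sum_{i<j} f_i f_j d_ij = f' D f / 2 (zero diagonal); pair weight total
    # sum_{i<j} f_i f_j = (1 - sum f^2)/2 — the 1/2's cancel in the ratios.
    wtot = 1.0 - float(f @ f)
    mpd = float(f @ d @ f) / wtot
    vpd = float(f @ (d ** 2) @ f) / wtot - mpd ** 2
    return mpd, max(vpd, 0.0)


def phylo_alpha_table(survey: SurveyTable, tree: Phylogeny,
                      include_root: bool = True) -> pd.DataFrame:
    """Observed PD, MPD.abu, VPD.abu per site."""
    rows = []
    for site in survey.sites:
        ab = survey.count.loc[site]
        ab = ab[ab > 0]
        if ab.empty:
            rows.append({"site": site, "pd": float("nan"),
                         "mpd_abu": float("nan"), "vpd_abu": float("nan")})
            continue
        mpd, vpd = mpd_vpd_abu(ab, tree)
        rows.append({"site": site,
                     "pd": faith_pd(ab.index, tree, include_root=include_root),
                     "mpd_abu": mpd, "vpd_abu": vpd})
    return pd.DataFrame(rows).set_index("site")


def ses_null(survey: SurveyTable, tree: Phylogeny, metric: str,
             n_perm: int = 999, seed: int = 0,
             include_root: bool = True) -> pd.DataFrame:
    """Standardized effect size of a phylogenetic alpha metric per site.

    Each permutation re-assigns the pooled species (those observed anywhere
    in the survey) to tree positions uniformly at random; community
    membership and abundances never move.  Columns: obs, null_mean,
    null_sd, ses, rank_p, n_perm.  SES is NaN (with a warning) where the
    metric is invariant under the shuffle (null SD = 0).
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)

    pool = [sp for sp in survey.species if survey.count[sp].sum() > 0]
    pool_tip_idx = tree.tip_indices(pool)          # tree position of each pool species
    npool = len(pool)
    counts = survey.count[pool].to_numpy(dtype=float)   # sites x pool
    present = counts > 0
    occupied = present.any(axis=1)

    # relative abundances per site over the pool ordering
    with np.errstate(invalid="ignore", divide="ignore"):
        f = counts / counts.sum(axis=1, keepdims=True)
    f = np.nan_to_num(f)

    d_pool = tree.patristic_matrix(pool)
    obs = _metric_values(tree, metric, pool_tip_idx, present, f, d_pool,
                         include_root)

    null = np.empty((n_perm, len(survey.sites)))
    for b in range(n_perm):
        perm = rng.permutation(npool)
        null[b] = _metric_values(tree, metric, pool_tip_idx[perm], present, f,
                                 d_pool[np.ix_(perm, perm)], include_root)

    null_mean = np.nanmean(null, axis=0)
    null_sd = np.nanstd(null, axis=0, ddof=1)
    tol = 1e-12 * np.maximum(1.0, np.abs(null_mean))
    degenerate = null_sd <= tol
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = (obs - null_mean) / null_sd
    ses[degenerate] = np.nan
    if degenerate[occupied].any():
        sites = [s for s, d, o in zip(survey.sites, degenerate, occupied) if d and o]
        warnings.warn(
            f"{metric} invariant under tip shuffle at sites {sites}; "
            "SES undefined (null SD = 0)", stacklevel=2)
    rank_p = ((null <= obs[None, :]).sum(axis=0) + 1) / (n_perm + 1)
    rank_p[degenerate] = np.nan      # quantile rank meaningless without a null

    out = pd.DataFrame({
        "metric": metric, "obs": obs, "null_mean": null_mean,
        "null_sd": null_sd, "ses": ses, "rank_p": rank_p, "n_perm": n_perm,
    }, index=pd.Index(survey.sites, name="site"))
    out.loc[~occupied, ["obs", "null_mean", "null_sd", "ses", "rank_p"]] = np.nan
    return out


def _metric_values(tree: Phylogeny, metric: str, tip_idx: np.ndarray,
                   present: np.ndarray, f: np.ndarray, d: np.ndarray,
                   include_root: bool = True) -> np.ndarray:
    """Metric for every site under one species -> tree-position assignment."""
    n_sites = present.shape[0]
    out = np.full(n_sites, np.nan)
    if metric == "pd":
        # occupancy over tree tips for all sites at once
        occ = np.zeros((tree.n_tips, n_sites))
        for s in range(n_sites):
            occ[tip_idx[present[s]], s] = 1.0
        below = tree.edge_below.astype(float) @ occ    # community tips under each edge
        spanned = below > 0
        if not include_root:
            spanned &= below < present.sum(axis=1)[None, :]
        vals = tree.edge_lengths @ spanned
        nz = present.any(axis=1)
        out[nz] = vals[nz]
        return out
    for s in range(n_sites):
        fs = f[s]
        k = int(present[s].sum())
        if k < 2:
            continue
        wtot = 1.0 - float(fs @ fs)
        mpd = float(fs @ d @ fs) / wtot
        if metric == "mpd_abu":
            out[s] = mpd
        else:
            out[s] = max(float(fs @ (d ** 2) @ fs) / wtot - mpd ** 2, 0.0)
    return out
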