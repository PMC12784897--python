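"""Driver attribution: what shapes alpha- and beta-diversity along the reservoir.

Environmental heterogeneity is the mean Euclidean distance of sites'
z-scored environmental profiles from their centroid (larger = more
heterogeneous habitat).  Alpha-diversity drivers are screened with Spearman
rank correlations, Benjamini-Hochberg adjusted within each diversity index.
Beta-diversity drivers are assessed two ways that complement each other:

* distance decay — OLS regression of each pairwise dissimilarity component
  on pairwise environmental distance or river distance, reporting slope,
  adjusted R2, a parametric p and an optional Mantel-style permutation p
  (pairwise responses are not independent, so the permutation p is the
  robustness check);
* hierarchical partitioning — the two-predictor average-shared-variance
  decomposition that splits the joint model's R2 into independent
  contributions of environment and space.

Smooth trends of single variables against distance-to-dam use a penalized
spline (GAM) with GCV smoothness selection; non-normal responses
(Shapiro-Wilk at 0.05) are log-transformed first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import EnvironmentTable

__all__ = [
    "HeterogeneityResult",
    "env_heterogeneity",
    "env_distance_matrix",
    "spearman_bh_screen",
    "DecayFit",
    "distance_decay",
    "HpResult",
    "hierarchical_partition",
    "TrendFit",
    "smooth_trend",
    "pair_vector",
]


def _zscore(env: EnvironmentTable) -> pd.DataFrame:
    env = env.nonconstant()
    v = env.values
    return (v - v.mean(axis=0)) / v.std(axis=0, ddof=1)


@dataclass
class HeterogeneityResult:
    per_site: pd.Series       # Euclidean distance to the centroid, z-space
    overall: float            # mean over sites


def env_heterogeneity(env: EnvironmentTable) -> HeterogeneityResult:
    """Distance of each site's standardized profile from the group centre."""
    z = _zscore(env)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    centroid = z.mean(axis=0)
    d = np.sqrt(((z - centroid) ** 2).sum(axis=1))
    d.name = "env_heterogeneity"
    return HeterogeneityResult(per_site=d, overall=float(d.mean()))


def env_distance_matrix(env: EnvironmentTable) -> pd.DataFrame:
    """Pairwise Euclidean distance between sites on z-scored variables."""
    z = _zscore(env)
    x = z.to_numpy()
    diff = x[:, None, :] - x[None, :, :]
    m = np.sqrt((diff ** 2).sum(axis=2))
    return pd.DataFrame(m, index=z.index, columns=z.index)


def spearman_bh_screen(alpha_table: pd.DataFrame,
                       drivers: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of every (diversity index, driver) pair with BH-adjusted p.

    One BH family per diversity index (adjustment across that index's
    drivers).  Constant columns yield NaN rho.  Requires >= 4 sites for the
    p-value to mean anything.
    """
    common = alpha_table.index.intersection(drivers.index)
    if len(common) < 4:
        raise ValueError("need at least 4 sites for the correlation screen")
    a = alpha_table.loc[common]
    d = drivers.loc[common]
    rows = []
    for index_name in a.columns:
        y = a[index_name].to_numpy(dtype=float)
        fam = []
        for drv in d.columns:
            x = d[drv].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 4 or np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
                fam.append({"index": index_name, "driver": drv,
                            "rho": float("nan"), "p": float("nan")})
                continue
            rho, p = stats.spearmanr(x[ok], y[ok])
            fam.append({"index": index_name, "driver": drv,
                        "rho": float(rho), "p": float(p)})
        pvals = np.array([r["p"] for r in fam])
        adj = np.full_like(pvals, np.nan)
        ok = ~np.isnan(pvals)
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        for r, pa in zip(fam, adj):
            r["p_adj"] = float(pa)
        rows.extend(fam)
    return pd.DataFrame(rows)


def pair_vector(matrix: pd.DataFrame, pairs: pd.DataFrame) -> np.ndarray:
    """Extract matrix entries for the (site_i, site_j) rows of a pair table."""
    return np.array([matrix.at[r.site_i, r.site_j] for r in pairs.itertuples()])


@dataclass
class DecayFit:
    response: str
    predictor: str
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p: float
    mantel_p: float | None
    n_pairs: int


def distance_decay(response: np.ndarray, predictor: np.ndarray,
                   response_name: str = "beta", predictor_name: str = "distance",
                   n_mantel: int = 0, seed: int = 0,
                   pair_index: pd.DataFrame | None = None) -> DecayFit:
    """OLS fit of a pairwise dissimilarity component on a pairwise distance.

    ``adj_r2 = 1 - (1 - R2)(n - 1)/(n - 2)``.  When ``n_mantel`` > 0 and
    ``pair_index`` (site_i/site_j labels per row) is given, a Mantel-style
    permutation p is computed by shuffling site labels of the predictor.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    y, x = y[ok], x[ok]
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a decay fit")
    if np.ptp(x) == 0:
        warnings.warn(f"zero-variance predictor {predictor_name}; fit refused",
                      stacklevel=2)
        return DecayFit(response_name, predictor_name, *(float("nan"),) * 5,
                        None, n)
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    mantel_p = None
    if n_mantel > 0 and pair_index is not None:
        mantel_p = _mantel_p(y, x, pair_index.loc[ok], n_mantel, seed)
    return DecayFit(response_name, predictor_name, float(res.slope),
                    float(res.intercept), float(r2), float(adj),
                    float(res.pvalue), mantel_p, n)


def _mantel_p(y: np.ndarray, x: np.ndarray, pair_index: pd.DataFrame,
              n_perm: int, seed: int) -> float:
    """Permutation p for the decay correlation under site-label shuffles."""
    rng = np.random.default_rng(seed)
    sites = sorted(set(pair_index["site_i"]) | set(pair_index["site_j"]))
    pos = {s: i for i, s in enumerate(sites)}
    n_sites = len(sites)
    xm = np.zeros((n_sites, n_sites))
    for (si, sj), xv in zip(pair_index[["site_i", "site_j"]].to_numpy(), x):
        xm[pos[si], pos[sj]] = xm[pos[sj], pos[si]] = xv
    ii = np.array([pos[s] for s in pair_index["site_i"]])
    jj = np.array([pos[s] for s in pair_index["site_j"]])
    obs = abs(np.corrcoef(x, y)[0, 1])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_sites)
        xp = xm[perm[ii], perm[jj]]
        if np.ptp(xp) == 0:
            continue
        if abs(np.corrcoef(xp, y)[0, 1]) >= obs - 1e-15:
            hits += 1
    return (hits + 1) / (n_perm + 1)


@dataclass
class HpResult:
    response: str
    contributions: dict[str, float]   # independent contribution, R2 units
    joint: float                      # shared (common) variance of the pair
    full_r2: float
    residual: float                   # 1 - full_r2


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return 1.0 - float((resid ** 2).sum()) / tss


def hierarchical_partition(y, x_env, x_spatial,
                           response_name: str = "beta",
                           names: tuple[str, str] = ("environment", "spatial")
                           ) -> HpResult:
    """Average-shared-variance split of the two-predictor model's R2.

    For predictors X1, X2 the independent contribution of X1 is
    ``R2(X1)/2 + (R2(X1,X2) - R2(X2))/2`` (and symmetrically for X2); the
    two contributions sum to the full-model R2 exactly.  ``joint`` is the
    classical common fraction R2(X1) + R2(X2) - R2(full).
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x_env, dtype=float)
    x2 = np.asarray(x_spatial, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x1) | np.isnan(x2))
    y, x1, x2 = y[ok], x1[ok], x2[ok]
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ValueError("both predictors must be non-constant")
    r = np.corrcoef(x1, x2)[0, 1]
    if abs(r) > 0.999:
        warnings.warn(f"predictors nearly collinear (r={r:.4f}); "
                      "partition is unstable", stacklevel=2)
    r2_1 = _ols_r2(y, x1[:, None])
    r2_2 = _ols_r2(y, x2[:, None])
    r2_full = _ols_r2(y, np.column_stack([x1, x2]))
    i1 = r2_1 / 2.0 + (r2_full - r2_2) / 2.0
    i2 = r2_2 / 2.0 + (r2_full - r2_1) / 2.0
    return HpResult(
        response=response_name,
        contributions={names[0]: i1, names[1]: i2},
        joint=r2_1 + r2_2 - r2_full,
        full_r2=r2_full,
        residual=1.0 - r2_full,
    )


@dataclass
class TrendFit:
    adj_r2: float
    p: float
    deviance_explained: float
    fitted: np.ndarray
    edf: float
    log_transformed: bool
    linear_fallback: bool


def smooth_trend(x, y, df: int = 5, normality_check: bool = True,
                 alpha_level: float = 0.05) -> TrendFit:
    """Penalized-spline (GAM) trend of y against distance-to-dam.

    The response is Shapiro-Wilk tested first; non-normal responses are
    log-transformed (after shifting when any value <= 0, with a warning).
    Smoothness is selected by generalized cross-validation.  Reports
    adjusted R2 (penalizing by the effective degrees of freedom), an
    approximate F-test p for the smooth, and the deviance explained.
    Fewer points than the basis needs -> straight-line fallback.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    logged = False
    if normality_check and np.ptp(y) > 0:
        if stats.shapiro(y).pvalue < alpha_level:
            shift = 0.0
            if y.min() <= 0:
                shift = -y.min() + 1e-6 * max(np.ptp(y), 1.0)
                warnings.warn("log transform after shifting non-positive values",
                              stacklevel=2)
            y = np.log(y + shift)
            logged = True
    if np.ptp(y) == 0:
        return TrendFit(0.0, 1.0, 0.0, np.full(n, y[0]), 1.0, logged, False)

    fallback = n < df + 2
    if fallback:
        warnings.warn("too few points for the spline basis; linear fit",
                      stacklevel=2)
        res = stats.linregress(x, y)
        fitted = res.intercept + res.slope * x
        r2 = res.rvalue ** 2
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        return TrendFit(float(adj), float(res.pvalue), float(r2), fitted,
                        2.0, logged, True)

    fitted, edf = _gcv_spline(x, y, df)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(((y - fitted) ** 2).sum())
    dev_expl = 1.0 - rss / tss
    resid_df = max(n - edf, 1.0)
    adj_r2 = 1.0 - (rss / resid_df) / (tss / (n - 1))
    num_df = max(edf - 1.0, 1e-8)
    fstat = ((tss - rss) / num_df) / (rss / resid_df) if rss > 0 else np.inf
    p = float(stats.f.sf(fstat, num_df, resid_df)) if np.isfinite(fstat) else 0.0
    return TrendFit(float(adj_r2), p, float(dev_expl), fitted, float(edf),
                    logged, False)


def _gcv_spline(x: np.ndarray, y: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Cubic B-spline ridge on second differences; GCV over a penalty grid.

    The penalty null space contains straight lines, so a perfectly linear
    signal is fit exactly at any smoothing level.
    """
    from statsmodels.gam.smooth_basis import BSplines

    bs = BSplines(x[:, None], df=[df], degree=[3], include_intercept=True)
    B = bs.basis                       # spans constants, so no extra intercept
    k = B.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)
    P = D.T @ D
    best = None
    for lam in np.logspace(-8, 6, 40):
        A = B.T @ B + lam * P + 1e-10 * np.eye(k)
        coef = np.linalg.solve(A, B.T @ y)
        H = B @ np.linalg.solve(A, B.T)
        edf = float(np.trace(H))
        fitted = B @ coef
        rss = float(((y - fitted) ** 2).sum())
        n = y.size
        # gamma > 1 inflates the dof charge, damping small-n undersmoothing
        denom = max(n - 1.4 * edf, 1e-6)
        gcv = n * rss / denom ** 2
        if best is None or gcv < best[0]:
            best = (gcv, fitted, edf)
    return best[1], best[2]
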