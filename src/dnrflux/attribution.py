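"""Attribution of ΔE₀,ASV variation to climate/vegetation/soil covariates.

Three complementary views on a site-year feature table: a PCA of the
standardized covariates (with per-variable contributions to the leading
components), general linear models of the response on the first two
component scores ranked by the small-sample Akaike criterion AICc, and a
random-forest permutation importance with covariates grouped into
climate/vegetation/soil families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

__all__ = [
    "VARIABLE_FAMILIES",
    "PCAResult",
    "pca_decompose",
    "glm_aicc_rank",
    "rf_importance",
    "impute_by_group",
]

#: Covariate families used to group importance shares.
VARIABLE_FAMILIES = {
    "climate": {
        "MAT", "Tair", "Tday", "Tnight", "Tmax", "Tmin", "DTR", "PAR", "VPD", "SPEI",
        "precip", "Tair_ASV", "Tday_ASV", "Tnight_ASV", "PAR_ASV", "VPD_ASV",
        "SPEI_ASV", "precip_ASV",
    },
    "vegetation": {
        "NDVI", "NDVI_ASV", "LAI", "LAI_ASV", "SIF", "LNC", "LPC", "LNP", "SLA", "LDMC",
    },
    "soil": {"SWC", "SOC"},
}


def family_of(name: str) -> str:
    for fam, names in VARIABLE_FAMILIES.items():
        if name in names:
            return fam
    return "climate" if name.lower().startswith(("t", "p", "vpd", "spei", "dtr")) else "vegetation"


def impute_by_group(table: pd.DataFrame, group_col: str = "biome") -> pd.DataFrame:
    """Fill missing covariates with per-group medians (overall median as a
    fallback for groups that are entirely missing)."""
    out = table.copy()
    num = out.select_dtypes("number").columns
    if group_col in out.columns:
        out[num] = out.groupby(group_col)[num].transform(lambda s: s.fillna(s.median()))
    out[num] = out[num].fillna(out[num].median())
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame  # site-year rows × Dim columns
    loadings: pd.DataFrame  # variables × Dim, orthonormal columns
    explained_pct: np.ndarray  # % of variance per component
    contributions: pd.DataFrame  # % contribution of each variable to each Dim
    average_contribution: float  # the 100/p reference line


def pca_decompose(table: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of the standardized covariates.

    Covariates are centered and scaled to unit variance; loadings are the
    orthonormal principal axes, and the contribution of variable j to
    component k is 100·loading² (summing to 100% per component), with
    100/p as the "average contribution" reference.
    """
    X = table.to_numpy(float)
    if len(table) < max(10, n_components):
        raise ValueError("need at least 10 rows (and more rows than components)")
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values; impute first")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = list(table.columns[sd == 0])
        raise ValueError(f"constant covariates cannot be standardized: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    dims = [f"Dim{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(pca.components_.T, index=table.columns, columns=dims)
    contrib = 100.0 * loadings**2
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=dims),
        loadings=loadings,
        explained_pct=100.0 * pca.explained_variance_ratio_,
        contributions=contrib,
        average_contribution=100.0 / table.shape[1],
    )


def aicc(loglik: float, n: int, k: int) -> float:
    """Second-order Akaike information criterion; k counts all estimated
    parameters including the residual variance."""
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def glm_aicc_rank(response: pd.Series, scores: pd.DataFrame) -> pd.DataFrame:
    """Rank linear models of the response on PCA scores by AICc.

    The candidate set is {Dim1 + Dim2, Dim1, Dim2}. Each row reports the
    AICc, R², overall-F p-value, and the coefficient (±SE) of each term;
    rows are sorted by ascending AICc (best first).
    """
    y = np.asarray(response, float)
    candidates = [["Dim1", "Dim2"], ["Dim1"], ["Dim2"]]
    rows = []
    for terms in candidates:
        X = sm.add_constant(scores[terms].to_numpy(float))
        fit = sm.OLS(y, X).fit()
        k = X.shape[1] + 1  # coefficients + residual variance
        row = {
            "model": " + ".join(terms),
            "aicc": aicc(fit.llf, len(y), k),
            "r2": fit.rsquared,
            "p": fit.f_pvalue,
        }
        for i, t in enumerate(terms, start=1):
            row[f"coef_{t}"] = fit.params[i]
            row[f"se_{t}"] = fit.bse[i]
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def rf_importance(
    table: pd.DataFrame,
    response_col: str = "asv_delta",
    seed: int = 0,
    n_estimators: int = 300,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Random-forest permutation importance of each covariate.

    A forest is fit to the response; each covariate is permuted in turn
    and the resulting increase in mean-squared error (averaged over
    ``n_repeats`` permutations) is its importance.  Importances are
    normalized to shares summing to 100% (negative chance-level values
    floored at 0) and annotated with the covariate family, so family
    shares can be summed directly.  Deterministic for fixed ``seed``.
    """
    if len(table) < 30:
        raise ValueError("need at least 30 rows")
    y = table[response_col].to_numpy(float)
    X = table.drop(columns=[response_col]).select_dtypes("number")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate importance: the response is constant")
    rf = RandomForestRegressor(
        n_estimators=n_estimators, min_samples_leaf=2, random_state=seed, n_jobs=1, oob_score=True
    )
    rf.fit(X.to_numpy(), y)
    perm = permutation_importance(
        rf, X.to_numpy(), y, n_repeats=n_repeats, random_state=seed, scoring="neg_mean_squared_error"
    )
    raw = perm.importances_mean
    clipped = np.maximum(raw, 0.0)
    total = clipped.sum()
    share = 100.0 * clipped / total if total > 0 else np.zeros_like(clipped)
    out = pd.DataFrame(
        {
            "variable": X.columns,
            "importance": raw,
            "importance_sd": perm.importances_std,
            "share_pct": share,
            "family": [family_of(c) for c in X.columns],
        }
    ).sort_values("importance", ascending=False).reset_index(drop=True)
    return out


def family_shares(importance: pd.DataFrame) -> pd.Series:
    """Aggregate normalized importance shares by covariate family (% of
    total; sums to 100 when any covariate is informative)."""
    return importance.groupby("family")["share_pct"].sum()
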