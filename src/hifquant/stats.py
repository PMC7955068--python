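"""Association statistics: Spearman screens, Empirical Brown's method for
combining dependent p-values, Benjamini–Hochberg correction, and
one-vs-rest group comparisons.

The per-cluster summary follows the screen → combine → correct pattern:
each feature is correlated with a molecular signature (Spearman, two-sided
t-approximation), feature p-values within a correlated cluster are merged
with the Empirical Brown's method (a covariance-aware generalization of
Fisher's method), and cluster-level p-values are FDR-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Machine-precision floor applied to p-values before taking logs.
P_FLOOR = 1e-30


def spearman_assoc(matrix: pd.DataFrame, signature: pd.Series) -> pd.DataFrame:
    """Per-feature Spearman ρ against a per-patient signature vector.

    Rows of ``matrix`` and the signature are aligned on patient id;
    two-sided p-values use the t-approximation on n − 2 degrees of
    freedom. Constant columns give NaN. Requires ≥ 5 paired observations.
    """
    common = matrix.index.intersection(signature.dropna().index)
    if len(common) < 5:
        raise ValueError(f"need at least 5 paired observations, got {len(common)}")
    x = matrix.loc[common]
    y = signature.loc[common].to_numpy(float)
    rho = np.full(x.shape[1], np.nan)
    pval = np.full(x.shape[1], np.nan)
    yr = sps.rankdata(y)
    for j, col in enumerate(x.columns):
        v = x[col].to_numpy(float)
        ok = np.isfinite(v)
        if ok.sum() < 5 or np.nanstd(v[ok]) == 0 or np.std(yr[ok]) == 0:
            continue
        r, p = sps.spearmanr(v[ok], y[ok])
        rho[j], pval[j] = r, p
    return pd.DataFrame({"rho": rho, "p": pval}, index=x.columns)


@dataclass
class BrownResult:
    """Empirical Brown combination of k dependent p-values."""

    statistic: float      # Fisher statistic Ψ = −2 Σ ln p_i
    scale: float          # c
    df: float             # f
    p_combined: float

    def __post_init__(self) -> None:
        assert 0.0 < self.p_combined <= 1.0


def empirical_browns(data: np.ndarray, pvals: np.ndarray,
                     two_sided: bool = True) -> BrownResult:
    """Combine dependent p-values given the underlying k × n data matrix.

    Each variable is rank-transformed with the mid-rank empirical CDF
    F̂ = (r − 0.5)/n; the empirical covariance of the transformed variables
    sets the scaled-χ² null: E = 2k, Var = 4k + 2 Σ_{i<j} cov_ij,
    f = 2E²/Var, c = Var/(2E), p = P(χ²_f > Ψ/c) with Ψ = −2 Σ ln p_i.
    With zero covariance this reduces to Fisher's method (f = 2k, c = 1).
    p-values are floored at 1e−30.

    With ``two_sided`` (the default) the transform is
    w = −2 ln(2·min(F̂, 1 − F̂)), which captures dependence between
    two-sided tests: perfectly anticorrelated variables then get
    covariance +4 (full dependence) instead of cancelling. The classical
    one-sided transform w = −2 ln(1 − F̂) is kept under
    ``two_sided=False``.
    """
    data = np.asarray(data, float)
    pvals = np.asarray(pvals, float)
    k, n = data.shape
    if k < 2:
        raise ValueError("need at least 2 variables to combine")
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    if len(pvals) != k:
        raise ValueError("one p-value per variable required")
    p = np.clip(pvals, P_FLOOR, 1.0)
    psi = float(-2.0 * np.log(p).sum())
    ranks = sps.rankdata(data, axis=1)          # mid-ranks within each variable
    cdf = (ranks - 0.5) / n
    if two_sided:
        w = -2.0 * np.log(2.0 * np.minimum(cdf, 1.0 - cdf))
    else:
        w = -2.0 * np.log(1.0 - cdf)
    cov = np.cov(w)                              # k × k, ddof=1
    off = cov[np.triu_indices(k, 1)]
    var = 4.0 * k + 2.0 * off.sum()
    e = 2.0 * k
    if var <= 0:
        var = 4.0 * k  # fall back to independence (Fisher)
    f = 2.0 * e ** 2 / var
    c = var / (2.0 * e)
    p_comb = float(sps.chi2.sf(psi / c, f))
    return BrownResult(statistic=psi, scale=c, df=f,
                       p_combined=max(p_comb, P_FLOOR))


def fishers_method(pvals: np.ndarray) -> float:
    """Fisher's combined probability test (independence reference)."""
    p = np.clip(np.asarray(pvals, float), P_FLOOR, 1.0)
    psi = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(psi, 2 * len(p)))


def bh_correct(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN inputs pass through as NaN and do not count toward the number of
    tests.
    """
    p = np.asarray(pvals, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def cluster_assoc_summary(report: pd.DataFrame, clusters,
                          matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster association summary.

    For every feature cluster: median |ρ| over members, Brown-combined p
    over member p-values (covariance estimated from the member columns of
    ``matrix``), and BH-adjusted q across clusters. Singleton clusters
    pass their member p through.
    """
    rows = []
    assignment = clusters.assignment if hasattr(clusters, "assignment") else clusters
    for cid in sorted(assignment.unique()):
        members = list(assignment.index[assignment == cid])
        sub = report.loc[members]
        usable = sub.dropna(subset=["rho", "p"])
        if usable.empty:
            rows.append({"cluster": cid, "n_members": len(members),
                         "median_abs_rho": np.nan, "p_combined": np.nan})
            continue
        med = float(usable["rho"].abs().median())
        if len(usable) == 1:
            p_comb = float(usable["p"].iloc[0])
        else:
            data = matrix[usable.index].to_numpy(float).T
            p_comb = empirical_browns(data, usable["p"].to_numpy()).p_combined
        rows.append({"cluster": cid, "n_members": len(members),
                     "median_abs_rho": med, "p_combined": p_comb})
    out = pd.DataFrame(rows).set_index("cluster")
    out["q"] = bh_correct(out["p_combined"].to_numpy())
    return out


def group_difference(matrix: pd.DataFrame, groups: pd.Series,
                     alternative: str = "greater") -> pd.DataFrame:
    """Per (group, feature): median Z-score within the group and a
    one-sided Mann–Whitney U test of the group against the pooled rest.

    ``matrix`` is expected to be pan-cohort z-scored. Groups with fewer
    than 3 members (or fewer than 3 in the rest) report NaN.
    """
    groups = groups.loc[matrix.index]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for g in sorted(groups.unique()):
        in_g = matrix.loc[groups == g]
        rest = matrix.loc[groups != g]
        for col in matrix.columns:
            a = in_g[col].dropna().to_numpy()
            b = rest[col].dropna().to_numpy()
            med = float(np.median(a)) if a.size else np.nan
            if a.size < 3 or b.size < 3 or (np.ptp(np.concatenate([a, b])) == 0):
                u, p = np.nan, np.nan
            else:
                u, p = sps.mannwhitneyu(a, b, alternative=alternative)
            rows.append({"group": g, "feature_id": col, "median_z": med,
                         "U": u, "p": p})
    return pd.DataFrame(rows)
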