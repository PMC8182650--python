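"""Dose-response clustering, behavior labeling, and expression association.

Dose-response AUGC profiles are hierarchically clustered with the
Chebyshev (L-infinity) metric and average linkage, which groups strains
by their worst-case disagreement across the dose grid and separates the
five canonical promoter behaviors: constitutive, constitutive-toxic,
nonfunctional, dependent-toxic, and inducer-dependent growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
import statsmodels.api as sm

__all__ = [
    "BehaviorProfile",
    "AssociationResult",
    "cluster_profiles",
    "label_behavior",
    "expression_association",
    "fit_expression_linear",
]

BEHAVIOR_LABELS = (
    "constitutive",
    "constitutive_toxic",
    "nonfunctional",
    "dependent_toxic",
    "dependent",
    "unclassified",
)


@dataclass
class BehaviorProfile:
    """Cluster assignments with per-cluster behavior labels."""

    assignments: pd.DataFrame      # strain_id, cluster, behavior
    cluster_means: pd.DataFrame    # cluster x dose mean profiles
    linkage: np.ndarray
    doses: np.ndarray


def _impute_by_nearest_dose(values: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells from the nearest measured dose of the same strain."""
    if not values.isna().any().any():
        return values
    doses = values.columns.to_numpy(dtype=float)
    out = values.copy()
    for idx, row in out.iterrows():
        nas = row.isna()
        if not nas.any():
            continue
        if nas.all():
            raise ValueError(f"strain {idx!r} has no measured doses")
        have = np.where(~nas.to_numpy())[0]
        for j in np.where(nas.to_numpy())[0]:
            out.iat[out.index.get_loc(idx), j] = row.iloc[
                have[np.argmin(np.abs(doses[have] - doses[j]))]
            ]
    return out


def cluster_profiles(
    values: pd.DataFrame,
    k: int = 5,
    metric: str = "chebyshev",
    linkage_method: str = "average",
) -> BehaviorProfile:
    """Agglomerative clustering of strains x doses AUGC profiles.

    The tree is cut at ``k`` clusters and cluster indices are relabeled in
    ascending order of the cluster-mean profile at the lowest dose, so the
    numbering is reproducible.  Strain input order never matters: rows are
    sorted by strain_id before distances are computed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(values):
        raise ValueError(f"k={k} exceeds {len(values)} strains")
    values = values.sort_index()
    values = _impute_by_nearest_dose(values)
    X = values.to_numpy(dtype=float)
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage_method)
    raw_labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    doses = values.columns.to_numpy(dtype=float)
    mean_at_0 = {
        c: X[raw_labels == c, 0].mean() for c in np.unique(raw_labels)
    }
    order = sorted(mean_at_0, key=lambda c: (mean_at_0[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([relabel[c] for c in raw_labels])

    means = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in sorted(set(labels))],
        index=sorted(set(labels)),
        columns=values.columns,
    )
    assignments = pd.DataFrame(
        {"strain_id": values.index, "cluster": labels}
    ).reset_index(drop=True)
    behaviors = label_behavior(means, doses)
    assignments["behavior"] = assignments["cluster"].map(behaviors)
    return BehaviorProfile(assignments, means, Z, doses)


def label_behavior(
    cluster_means: pd.DataFrame,
    doses: np.ndarray,
    low_threshold: float = 0.2,
    fall_threshold: float = 0.3,
) -> dict[int, str]:
    """Rule-based behavior labels from cluster mean profiles.

    ``low``  = below ``low_threshold`` of the reference scale (profiles are
    reference-scaled, so full growth is ~1); ``fall`` = the final dose sits
    more than ``fall_threshold`` below the profile peak.  Profiles matching
    no rule are labeled ``unclassified`` rather than silently forced.
    """
    labels: dict[int, str] = {}
    for c, row in cluster_means.iterrows():
        m = row.to_numpy(dtype=float)
        peak = m.max()
        if peak < low_threshold:
            labels[int(c)] = "nonfunctional"
            continue
        start_low = m[0] < low_threshold
        fall = (peak - m[-1]) / peak > fall_threshold
        rises = m.max() > m[0] + low_threshold / 2
        if start_low and fall:
            labels[int(c)] = "dependent_toxic"
        elif start_low and rises:
            labels[int(c)] = "dependent"
        elif not start_low and fall:
            labels[int(c)] = "constitutive_toxic"
        elif not start_low:
            labels[int(c)] = "constitutive"
        else:
            labels[int(c)] = "unclassified"
    return labels


@dataclass
class AssociationResult:
    """Association between native expression level and growth."""

    bin_edges: np.ndarray
    bin_stats: pd.DataFrame        # per-bin n, median AUGC
    ks_statistic: float
    ks_pvalue: float
    spearman_rho: float
    spearman_pvalue: float
    t_statistic: float
    t_pvalue: float


def expression_association(
    augc_values: pd.Series,
    expression: pd.Series,
    n_bins: int = 6,
    t_quantiles: tuple[float, float] = (0.1, 0.9),
) -> AssociationResult:
    """Test whether growth at a given dose depends on native expression.

    Strains are split into ``n_bins`` equal-count bins on log expression;
    a two-sample KS test compares the lowest and highest bins, Spearman's
    rho is computed on the unbinned pairs, and a two-sided t-test compares
    the bottom and top expression deciles (configurable quantiles).
    """
    df = pd.DataFrame({"augc": augc_values, "expr": expression}).dropna()
    if (df["expr"] <= 0).any():
        raise ValueError("expression must be positive for log binning")
    if len(df) < 10 * n_bins:
        raise ValueError(
            f"need >= {10 * n_bins} strains for {n_bins} bins of >= 10; got {len(df)}"
        )
    log_expr = np.log(df["expr"])
    bins, edges = pd.qcut(log_expr, q=n_bins, labels=False, retbins=True, duplicates="drop")
    df["bin"] = bins
    stats_df = df.groupby("bin")["augc"].agg(n="size", median="median").reset_index()
    low = df.loc[df["bin"] == df["bin"].min(), "augc"]
    high = df.loc[df["bin"] == df["bin"].max(), "augc"]
    ks = stats.ks_2samp(low, high)
    rho, rho_p = stats.spearmanr(df["expr"], df["augc"])
    qlo, qhi = np.quantile(log_expr, t_quantiles)
    g1 = df.loc[log_expr <= qlo, "augc"]
    g2 = df.loc[log_expr >= qhi, "augc"]
    t = stats.ttest_ind(g1, g2, equal_var=False)
    return AssociationResult(
        bin_edges=edges,
        bin_stats=stats_df,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        spearman_rho=float(rho),
        spearman_pvalue=float(rho_p),
        t_statistic=float(t.statistic),
        t_pvalue=float(t.pvalue),
    )


def fit_expression_linear(
    max_induced_tpm: pd.Series,
    native_tpm: pd.Series,
    cutoff: float = 250.0,
) -> dict:
    """OLS of maximum induced expression on native expression below a cutoff.

    Genes whose native expression is at or above ``cutoff`` TPM are excluded
    from the fit (induction saturates for highly expressed genes) and
    reported in the result.
    """
    df = pd.DataFrame({"y": max_induced_tpm, "x": native_tpm}).dropna()
    keep = df["x"] < cutoff
    excluded = df.index[~keep].tolist()
    sub = df[keep]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 genes below {cutoff} TPM; got {len(sub)}")
    model = sm.OLS(sub["y"], sm.add_constant(sub["x"])).fit()
    r2 = float(model.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0  # constant response: no variance to explain
    return {
        "slope": float(model.params["x"]),
        "intercept": float(model.params["const"]),
        "r_squared": r2,
        "n": int(len(sub)),
        "excluded_genes": excluded,
    }
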