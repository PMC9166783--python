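"""Response-subgroup discovery on the immuno-behavioural covariation plane.

Each treated subject is a point (cytokine canonical score, behavioural
canonical score). K-means on the discovery points partitions patients
into response groups; the number of clusters is chosen at the elbow of
the Hubert Gamma statistic (correlation between the pairwise-distance
matrix and the cluster co-membership structure). Validation patients are
mapped onto the discovery plane by nearest centroid, keeping cross-set
group definitions comparable. Groups are named best / medium / least by
mean behavioural-score improvement, so naming is invariant to k-means
label permutation.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .stats import SummaryStat, one_sample_t, hedges_g, kruskal_wallis, bh_adjust

__all__ = ["kmeans_fit", "select_k_hubert", "hubert_gamma", "PlaneClustering",
           "map_validation", "group_change_stats", "GROUP_NAMES"]

GROUP_NAMES = ["best", "medium", "least"]


def kmeans_fit(points, k: int, seed: Optional[int] = None,
               n_init: int = 50) -> Tuple[np.ndarray, np.ndarray, float]:
    """Lowest-inertia k-means over ``n_init`` greedy-spread restarts."""
    pts = np.asarray(points, dtype=float)
    if k < 1 or (k >= 2 and pts.shape[0] < k):
        raise ValueError("need n >= k >= 1")
    if np.unique(pts, axis=0).shape[0] < k:
        raise ValueError("fewer distinct points than clusters")
    if k == 1:
        centroid = pts.mean(axis=0, keepdims=True)
        inertia = float(((pts - centroid) ** 2).sum())
        return np.zeros(len(pts), dtype=int), centroid, inertia
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                random_state=seed).fit(pts)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def hubert_gamma(points, labels) -> float:
    """Hubert Gamma: Pearson correlation between pairwise Euclidean
    distances and the different-cluster indicator over all point pairs."""
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    d = pdist(pts)
    co = pdist(labels[:, None].astype(float), metric=lambda a, b: float(a[0] != b[0]))
    if d.std() == 0 or co.std() == 0:
        return 0.0
    return float(np.corrcoef(d, co)[0, 1])


def select_k_hubert(points, k_range: Sequence[int] = range(2, 9),
                    seed: Optional[int] = None,
                    n_init: int = 50) -> Tuple[int, pd.DataFrame]:
    """Choose k at the elbow (maximum second difference) of the Gamma scree.

    Returns (k, table of Gamma per k with the elbow diagnostics); the
    selection is flagged low-confidence when the winning second difference
    is under twice the median of the |second differences|, i.e. when no
    elbow dominates.
    """
    ks = sorted(k_range)
    pts = np.asarray(points, dtype=float)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if pts.shape[0] <= max(ks):
        raise ValueError("need n > max(k_range)")
    gamma = []
    for k in ks:
        labels, _, _ = kmeans_fit(pts, k, seed=seed, n_init=n_init)
        gamma.append(hubert_gamma(pts, labels))
    gamma = np.asarray(gamma)
    # elbow: marginal gain drops most after k -> maximize the drop
    second = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        second[i] = (gamma[i] - gamma[i - 1]) - (gamma[i + 1] - gamma[i])
    best = int(np.nanargmax(second))
    med = np.nanmedian(np.abs(second))
    low_conf = bool(second[best] < 2.0 * med) if med > 0 else False
    table = pd.DataFrame({"k": ks, "gamma": gamma, "second_difference": second})
    table.attrs["low_confidence"] = low_conf
    return ks[best], table


class PlaneClustering(BaseEstimator, ClusterMixin):
    """K-means response groups on the covariation plane, named by response.

    Parameters
    ----------
    k : number of clusters, or None to choose it by the Hubert elbow over
        ``k_range``.
    k_range, n_init, random_state : selection / restart controls.

    Attributes
    ----------
    k_ : chosen number of clusters.
    labels_ : named group per fitted subject ("best" > "medium" > "least"
        by mean behavioural score when k = 3; "group1".. otherwise).
    centroids_ : k x 2 array, rows ordered by descending behavioural mean.
    names_ : group name per centroid row.
    inertia_, hubert_table_, low_confidence_
    """

    def __init__(self, k: Optional[int] = None, k_range: Sequence[int] = range(2, 9),
                 n_init: int = 50, random_state: Optional[int] = None):
        self.k = k
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, points, y=None) -> "PlaneClustering":
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("expected n x 2 plane coordinates")
        if self.k is None:
            self.k_, self.hubert_table_ = select_k_hubert(
                pts, self.k_range, seed=self.random_state, n_init=self.n_init)
            self.low_confidence_ = self.hubert_table_.attrs["low_confidence"]
        else:
            self.k_ = int(self.k)
            self.hubert_table_ = None
            self.low_confidence_ = False
        raw_labels, centers, self.inertia_ = kmeans_fit(
            pts, self.k_, seed=self.random_state, n_init=self.n_init)
        # order centroids by mean behavioural improvement (plane y-axis);
        # the extremes are always named best / least so responder
        # labelings remain defined for any k
        order = np.argsort(-centers[:, 1])
        self.centroids_ = centers[order]
        if self.k_ == 3:
            self.names_ = list(GROUP_NAMES)
        elif self.k_ == 1:
            self.names_ = ["all"]
        else:
            self.names_ = (["best"] + [f"mid{i}" for i in range(1, self.k_ - 1)]
                           + ["least"])
        remap = {int(old): self.names_[new] for new, old in enumerate(order)}
        self.labels_ = np.array([remap[int(l)] for l in raw_labels])
        return self

    def predict(self, points) -> np.ndarray:
        """Nearest-centroid mapping of new points onto the fitted plane."""
        return map_validation(points, self.centroids_, self.names_)


def map_validation(points, centroids, names: Optional[Sequence[str]] = None) -> np.ndarray:
    """Assign each point to its nearest centroid (Euclidean); ties go to
    the lower-index centroid."""
    pts = np.asarray(points, dtype=float)
    cents = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != cents.shape[1]:
        raise ValueError(
            f"dimension mismatch: points {pts.shape} vs centroids {cents.shape}")
    d = ((pts[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    idx = d.argmin(axis=1)  # argmin takes the first (lowest-index) minimum
    if names is None:
        return idx
    names = list(names)
    return np.array([names[i] for i in idx])


def group_change_stats(changes: pd.DataFrame, labels: pd.Series,
                       group_order: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-group change statistics table.

    For every variable (column of ``changes``) and group: mean, SD, n,
    one-sample t (df = n - 1), Hedges g, p; across groups: Kruskal-Wallis
    H with df = #groups - 1. Benjamini-Hochberg FDR is applied within each
    statistic family (all one-sample p's; all Kruskal-Wallis p's).
    """
    changes = pd.DataFrame(changes)
    labels = pd.Series(labels).reindex(changes.index)
    if labels.isna().any():
        raise ValueError("every subject needs a group label")
    if group_order is not None:
        groups = list(group_order)
    else:
        def order_key(g):
            if g == "best":
                return (0, 0, "")
            if g == "medium":
                return (1, 0, "")
            if str(g).startswith("mid"):
                try:
                    return (1, int(str(g)[3:]), "")
                except ValueError:
                    return (1, 0, str(g))
            if g == "least":
                return (2, 0, "")
            return (3, 0, str(g))
        groups = sorted(set(labels), key=order_key)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = labels.value_counts()
    if (sizes.reindex(groups).fillna(0) < 3).any():
        raise ValueError("every group needs n >= 3")

    rows = []
    for var in changes.columns:
        row: Dict[str, object] = {"variable": var}
        series = changes[var]
        per_group = [series[labels == g].dropna().to_numpy() for g in groups]
        for g, vals in zip(groups, per_group):
            stat = SummaryStat(float(vals.mean()), float(vals.std(ddof=1)), len(vals))
            t_res = one_sample_t(stat)
            row[f"{g}_mean"] = stat.mean
            row[f"{g}_sd"] = stat.sd
            row[f"{g}_n"] = stat.n
            row[f"{g}_t"] = t_res.statistic
            row[f"{g}_df"] = t_res.df
            row[f"{g}_g"] = hedges_g(stat)
            row[f"{g}_p"] = t_res.p_value
        kw = kruskal_wallis(per_group)
        row["kw_H"] = kw.statistic
        row["kw_df"] = kw.df
        row["kw_p"] = kw.p_value
        rows.append(row)
    table = pd.DataFrame(rows).set_index("variable")

    # FDR within statistic families
    t_cols = [f"{g}_p" for g in groups]
    flat = table[t_cols].to_numpy().ravel()
    table_q = bh_adjust(flat).reshape(table[t_cols].shape)
    for j, g in enumerate(groups):
        table[f"{g}_q"] = table_q[:, j]
    table["kw_q"] = bh_adjust(table["kw_p"].to_numpy())
    return table
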