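"""Cytokine-panel preprocessing.

Fixed pipeline order: detection-limit filtering -> per-batch min-max +
log1p transform -> parametric empirical-Bayes batch adjustment (baseline
concentrations only; change scores are transformed but not
batch-adjusted). A PCA-based score quantifies batch separation before and
after adjustment.

All transforms are column-wise monotone, so rank statistics are
unaffected. The min-max step is undefined at log(0) if a plain log is
used; log1p keeps every transformed value inside [0, log 2] and is
monotone everywhere.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = ["lod_filter", "MinMaxLog", "ComBat", "pca_batch_check"]


def lod_filter(raw: pd.DataFrame, ranges: pd.DataFrame,
               theta: float = 0.0) -> Tuple[list, pd.DataFrame]:
    """Drop analytes with too many values below their lower detection limit.

    An analyte is dropped when the fraction of its measurements below the
    lower limit exceeds ``theta``. The default theta=0 drops an analyte on
    any sub-LOD measurement (blanket exclusion); a per-analyte fraction is
    available because assay practice varies.

    Returns (kept analyte names, column-filtered matrix).
    """
    lower = ranges.set_index("analyte")["lower"]
    missing = [c for c in raw.columns if c not in lower.index]
    if missing:
        raise ValueError(f"no detection range for analytes: {missing}")
    frac_below = (raw.lt(lower[raw.columns], axis=1)).mean(axis=0)
    kept = [c for c in raw.columns if frac_below[c] <= theta]
    if not kept:
        raise ValueError("all analytes fall below their detection limits")
    return kept, raw[kept]


class MinMaxLog(BaseEstimator, TransformerMixin):
    """Per-batch min-max rescaling to [0, 1] followed by log1p.

    The per-batch, per-column min and max are frozen at fit time so
    held-out samples from a known batch can be mapped with the training
    parameters. Batches unseen at fit time raise unless the transformer is
    refit.
    """

    def fit(self, X: pd.DataFrame, batches: Sequence) -> "MinMaxLog":
        X = pd.DataFrame(X)
        batches = np.asarray(batches)
        if len(batches) != len(X):
            raise ValueError("batches must align with rows of X")
        self.columns_ = list(X.columns)
        self.params_: Dict[str, Dict[str, Tuple[float, float]]] = {}
        for b in pd.unique(batches):
            sub = X[batches == b]
            per_col = {}
            for c in self.columns_:
                lo, hi = float(sub[c].min()), float(sub[c].max())
                if hi <= lo:
                    raise ValueError(
                        f"column {c!r} is constant within batch {b!r}")
                per_col[c] = (lo, hi)
            self.params_[str(b)] = per_col
        return self

    def transform(self, X: pd.DataFrame, batches: Sequence) -> pd.DataFrame:
        X = pd.DataFrame(X)
        batches = np.asarray(batches)
        out = pd.DataFrame(index=X.index, columns=self.columns_, dtype=float)
        for b in pd.unique(batches):
            key = str(b)
            if key not in self.params_:
                raise ValueError(f"batch {b!r} was not seen at fit time")
            rows = batches == b
            for c in self.columns_:
                lo, hi = self.params_[key][c]
                out.loc[rows, c] = np.log1p((X.loc[rows, c] - lo) / (hi - lo))
        return out

    def fit_transform(self, X: pd.DataFrame, batches: Sequence) -> pd.DataFrame:
        return self.fit(X, batches).transform(X, batches)


class ComBat(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per column, data are standardized against the least-squares grand mean
    and pooled variance; per-batch location effects get a normal prior and
    scale effects an inverse-gamma prior, with hyperparameters estimated
    by the method of moments across columns; the shrunken effects are
    removed and the data returned on the input scale. No biological
    covariates enter the design.

    Parameters
    ----------
    mean_only : adjust locations only (scale effects left untouched).
    """

    def __init__(self, mean_only: bool = False, max_iter: int = 200,
                 tol: float = 1e-6):
        self.mean_only = mean_only
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, batches: Sequence) -> "ComBat":
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        batches = np.asarray(batches).astype(str)
        levels = list(pd.unique(batches))
        counts = {b: int((batches == b).sum()) for b in levels}
        small = [b for b, c in counts.items() if c < 3]
        if len(levels) >= 2 and small:
            raise ValueError(f"batches with fewer than 3 samples: {small}")
        self.batches_ = levels
        self.single_batch_ = len(levels) < 2
        if self.single_batch_:
            return self

        data = X.to_numpy(dtype=float)
        n, p = data.shape
        design = np.column_stack([(batches == b).astype(float) for b in levels])
        n_i = design.sum(axis=0)
        beta = np.linalg.lstsq(design, data, rcond=None)[0]  # batch means
        grand = (n_i / n) @ beta
        resid = data - design @ beta
        var_pooled = (resid**2).sum(axis=0) / n
        if np.any(var_pooled <= 0):
            bad = [self.columns_[j] for j in np.where(var_pooled <= 0)[0]]
            raise ValueError(f"singular pooled variance in columns: {bad}")

        z = (data - grand) / np.sqrt(var_pooled)
        gamma_hat = np.vstack([z[batches == b].mean(axis=0) for b in levels])
        delta_hat = np.vstack([z[batches == b].var(axis=0, ddof=1)
                               for b in levels])

        gamma_bar = gamma_hat.mean(axis=1)
        tau2 = gamma_hat.var(axis=1, ddof=1)
        # inverse-gamma moments for the scale prior
        m = delta_hat.mean(axis=1)
        s2 = delta_hat.var(axis=1, ddof=1)
        lam = (2 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.ones_like(delta_hat)
        for i, b in enumerate(levels):
            zb = z[batches == b]
            nb = zb.shape[0]
            if self.mean_only:
                # posterior mean with unit scale
                g = ((nb * tau2[i] * gamma_hat[i] + gamma_bar[i])
                     / (nb * tau2[i] + 1.0))
                gamma_star[i] = g
                continue
            g_old = ((nb * tau2[i] * gamma_hat[i] + delta_hat[i] * gamma_bar[i])
                     / (nb * tau2[i] + delta_hat[i]))
            d_old = delta_hat[i].copy()
            for _ in range(self.max_iter):
                g_new = ((nb * tau2[i] * gamma_hat[i] + d_old * gamma_bar[i])
                         / (nb * tau2[i] + d_old))
                ss = ((zb - g_new) ** 2).sum(axis=0)
                d_new = (theta[i] + 0.5 * ss) / (nb / 2.0 + lam[i] - 1.0)
                change = max(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                             np.max(np.abs(d_new - d_old) / d_old))
                g_old, d_old = g_new, d_new
                if change < self.tol:
                    break
            gamma_star[i], delta_star[i] = g_old, d_old

        self.grand_mean_ = grand
        self.var_pooled_ = var_pooled
        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        return self

    def transform(self, X, batches: Sequence) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if self.single_batch_:
            return X.copy()
        batches = np.asarray(batches).astype(str)
        data = X.to_numpy(dtype=float)
        z = (data - self.grand_mean_) / np.sqrt(self.var_pooled_)
        out = np.empty_like(z)
        for i, b in enumerate(self.batches_):
            rows = batches == b
            if not rows.any():
                continue
            adj = (z[rows] - self.gamma_star_[i]) / np.sqrt(self.delta_star_[i])
            out[rows] = adj
        unknown = set(batches) - set(self.batches_)
        if unknown:
            raise ValueError(f"batches not seen at fit time: {sorted(unknown)}")
        out = out * np.sqrt(self.var_pooled_) + self.grand_mean_
        return pd.DataFrame(out, index=X.index, columns=self.columns_)

    def fit_transform(self, X, batches: Sequence) -> pd.DataFrame:
        return self.fit(X, batches).transform(X, batches)


def pca_batch_check(X, batches: Sequence, n_components: int = 2):
    """Batch-separation score on the leading principal components.

    Score = between-batch variance of the PC centroids divided by the
    total PC variance (a ratio in [0, 1]; 0 means indistinguishable batch
    centroids). Also returns the PC coordinates for plotting.
    """
    X = pd.DataFrame(X)
    batches = np.asarray(batches)
    if len(X) <= n_components:
        raise ValueError("need more samples than components")
    coords = PCA(n_components=n_components, random_state=0).fit_transform(
        X.to_numpy(dtype=float))
    grand = coords.mean(axis=0)
    total = ((coords - grand) ** 2).sum()
    if total <= 0:
        return 0.0, coords
    between = 0.0
    for b in pd.unique(batches):
        sub = coords[batches == b]
        between += sub.shape[0] * ((sub.mean(axis=0) - grand) ** 2).sum()
    return float(between / total), coords
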