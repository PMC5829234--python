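"""SIMPER: which covariates drive between-class dissimilarity.

Similarity-percentages analysis with a Euclidean distance measure. Squared
Euclidean distance decomposes additively over variables, so for every
cross-class pair of individuals (i in A, j in B) the contribution of
covariate v is ``(x_iv - x_jv)^2``; averaging over all cross pairs and
normalising gives each covariate's percent contribution to the A-vs-B
dissimilarity (the percentages sum to 100 per comparison). Besides all
pairwise class comparisons, a one-vs-rest summary per class is produced,
matching how single per-class percentages are usually reported.

Before SIMPER the raw covariates are dispersion-weighted — each covariate
divided by the average of its within-class variance-to-mean ratios, which
down-weights covariates that are erratic within classes — and then
``log(x + 1)`` transformed to tame extreme magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class DispersionWeighter(TransformerMixin, BaseEstimator):
    """Divide each covariate by its mean within-class index of dispersion,
    then apply ``log(x + 1)``.

    The index of dispersion of covariate v in class g is
    ``var_g(v) / mean_g(v)`` (sample variance, ``n - 1``); class indices are
    averaged with equal class weights. Degenerate indices — a class mean of
    zero, a single-member class, or zero within-class variance — contribute
    1 (no reweighting evidence). Requires non-negative values.

    Attributes
    ----------
    divisors_ : Series or ndarray of per-covariate divisors.
    """

    def fit(self, X, y):
        X_df = pd.DataFrame(X).astype(float)
        if (X_df.to_numpy() < 0).any():
            raise ValueError("dispersion weighting requires non-negative values")
        y = np.asarray(y)
        if len(y) != len(X_df):
            raise ValueError("labels must match rows")
        divisors = pd.Series(0.0, index=X_df.columns)
        classes = pd.unique(y)
        for g in classes:
            sub = X_df.loc[y == g]
            mean = sub.mean(axis=0)
            var = sub.var(axis=0, ddof=1) if len(sub) > 1 else pd.Series(0.0, index=X_df.columns)
            index = var / mean.replace(0.0, np.nan)
            index = index.fillna(1.0)
            index[index == 0.0] = 1.0
            divisors += index
        self.divisors_ = divisors / len(classes)
        self.n_features_in_ = X_df.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "divisors_")
        X_df = pd.DataFrame(X).astype(float)
        if (X_df.to_numpy() < 0).any():
            raise ValueError("dispersion weighting requires non-negative values")
        weighted = X_df / self.divisors_.to_numpy()
        return np.log1p(weighted.to_numpy())


def dispersion_weight(X: pd.DataFrame, labels) -> pd.DataFrame:
    """Dispersion-weight and ``log(x + 1)``-transform a raw covariate table."""
    X_df = pd.DataFrame(X)
    out = DispersionWeighter().fit(X_df, labels).transform(X_df)
    return pd.DataFrame(out, index=X_df.index, columns=X_df.columns)


@dataclass
class SimperResult:
    """Per-comparison covariate contributions to squared-Euclidean dissimilarity.

    ``pairwise`` maps an ordered class pair to a table with columns
    ``covariate``, ``mean_contribution`` (mean squared difference over all
    cross pairs), ``percent`` and ``cumulative_percent`` (descending by
    percent); ``one_vs_rest`` maps each class to the same table for that
    class against all others pooled. ``mean_distance`` holds the mean
    Euclidean distance over the cross pairs of each comparison.
    """

    pairwise: dict[tuple[str, str], pd.DataFrame]
    one_vs_rest: dict[str, pd.DataFrame]
    mean_distance: dict[str | tuple[str, str], float]

    def as_frame(self) -> pd.DataFrame:
        """All comparisons stacked into one long table."""
        rows = []
        for (a, b), tab in self.pairwise.items():
            t = tab.copy()
            t.insert(0, "comparison", f"{a}_vs_{b}")
            rows.append(t)
        for a, tab in self.one_vs_rest.items():
            t = tab.copy()
            t.insert(0, "comparison", f"{a}_vs_rest")
            rows.append(t)
        return pd.concat(rows, ignore_index=True)


def _contribution_table(XA: np.ndarray, XB: np.ndarray, columns) -> tuple[pd.DataFrame, float]:
    # mean over cross pairs of (a - b)^2, per covariate:
    #   E[a^2] + E[b^2] - 2 E[a] E[b]  (exact, no pair enumeration needed)
    mA, mB = XA.mean(axis=0), XB.mean(axis=0)
    sqA, sqB = (XA**2).mean(axis=0), (XB**2).mean(axis=0)
    contrib = sqA + sqB - 2.0 * mA * mB
    total = contrib.sum()
    percent = 100.0 * contrib / total if total > 0 else np.zeros_like(contrib)
    tab = pd.DataFrame(
        {"covariate": list(columns), "mean_contribution": contrib, "percent": percent}
    ).sort_values("percent", ascending=False, kind="mergesort").reset_index(drop=True)
    tab["cumulative_percent"] = tab["percent"].cumsum()
    # mean Euclidean distance needs the pairs; do it blockwise to bound memory
    mean_dist = _mean_euclidean(XA, XB)
    return tab, mean_dist


def _mean_euclidean(XA: np.ndarray, XB: np.ndarray, block: int = 512) -> float:
    total = 0.0
    for start in range(0, XA.shape[0], block):
        a = XA[start : start + block]
        d2 = ((a[:, None, :] - XB[None, :, :]) ** 2).sum(axis=2)
        total += np.sqrt(d2).sum()
    return float(total / (XA.shape[0] * XB.shape[0]))


def simper_euclidean(X, labels) -> SimperResult:
    """Euclidean SIMPER over all class pairs plus one-vs-rest summaries.

    ``X`` is the (typically dispersion-weighted, log-transformed) covariate
    table; ``labels`` assigns a class to every row. Requires at least two
    classes, each with at least one member.
    """
    X_df = pd.DataFrame(X).astype(float)
    y = np.asarray(labels)
    if len(y) != len(X_df):
        raise ValueError("labels must match rows")
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("SIMPER needs at least two classes")

    mats = {g: X_df.loc[y == g].to_numpy() for g in classes}
    pairwise: dict[tuple[str, str], pd.DataFrame] = {}
    one_vs_rest: dict[str, pd.DataFrame] = {}
    mean_distance: dict[str | tuple[str, str], float] = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            tab, md = _contribution_table(mats[a], mats[b], X_df.columns)
            pairwise[(a, b)] = tab
            mean_distance[(a, b)] = md
        rest = X_df.loc[y != a].to_numpy()
        tab, md = _contribution_table(mats[a], rest, X_df.columns)
        one_vs_rest[a] = tab
        mean_distance[a] = md
    return SimperResult(pairwise=pairwise, one_vs_rest=one_vs_rest, mean_distance=mean_distance)


class Simper(BaseEstimator):
    """Estimator wrapper: dispersion weighting + Euclidean SIMPER in one fit.

    ``fit(X, y)`` stores the weighted matrix and the :class:`SimperResult`
    in ``results_``; ``weighter_`` exposes the fitted divisors.
    """

    def __init__(self, dispersion_weighting: bool = True):
        self.dispersion_weighting = dispersion_weighting

    def fit(self, X, y):
        X_df = pd.DataFrame(X)
        if self.dispersion_weighting:
            self.weighter_ = DispersionWeighter().fit(X_df, y)
            Xw = pd.DataFrame(
                self.weighter_.transform(X_df), index=X_df.index, columns=X_df.columns
            )
        else:
            self.weighter_ = None
            Xw = X_df.astype(float)
        self.weighted_ = Xw
        self.results_ = simper_euclidean(Xw, y)
        return self
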