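"""Functional movement classes: k-means, gap-statistic model selection,
a-posteriori class naming, PCA coordinates and the tag-removal sensitivity
analysis.

The number of classes is chosen with the gap statistic: for each candidate
``k`` the log within-cluster dispersion ``log W_k`` of the data is compared
with its expectation under ``B`` reference datasets drawn uniformly over
each covariate's observed range,

    gap(k) = (1/B) sum_b log W*_kb  -  log W_k,

and ``k`` is selected by the one-standard-error rule: the smallest ``k``
with ``gap(k) >= gap(k+1) - s_{k+1}``, where
``s_k = sd_b(log W*_kb) * sqrt(1 + 1/B)``. A single compact cluster yields
``k = 1`` through the same rule at ``k = 1``.

When four classes are found they are named a posteriori from the cluster
means of the *raw* covariates: Roamers travel furthest (largest 99% distance
quantile), Occasionals wait longest between detections, Residents are
detected most, and the remaining class — frequently detected but with
intermediate long-distance movement — are the Irruptors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

from .metrics import COVARIATE_NAMES

CLASS_NAMES = ("Residents", "Occasionals", "Irruptors", "Roamers")


@dataclass
class KMeansFit:
    """A best-of-restarts k-means partition of the transformed covariates."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    W_k: float  # total within-cluster sum of squared distances
    n_init: int
    seed: int | None


@dataclass
class GapStatisticResult:
    """Gap curve and the selected number of clusters."""

    k_values: np.ndarray
    log_Wk: np.ndarray
    gap: np.ndarray
    s: np.ndarray  # reference-set standard error, sd_b * sqrt(1 + 1/B)
    B: int
    chosen_k: int
    seed: int | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_values, "log_W": self.log_Wk, "gap": self.gap, "s": self.s}
        )


@dataclass
class FMCAssignment:
    """Per-tag cluster labels and the cluster -> class-name mapping."""

    labels: pd.Series  # tag_id -> cluster index
    names: dict[int, str]  # cluster index -> class name

    @property
    def class_labels(self) -> pd.Series:
        """tag_id -> class name."""
        return self.labels.map(self.names)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tag_id": self.labels.index,
                "cluster": self.labels.to_numpy(),
                "class_name": self.class_labels.to_numpy(),
            }
        )


@dataclass
class PCAProjection:
    """Top-two principal-component coordinates of the transformed covariates."""

    coords: np.ndarray  # n x 2
    percent_variance: np.ndarray  # all components, sums to 100
    components: np.ndarray  # columns are eigenvectors, sign-fixed


def _total_ss(X: np.ndarray) -> float:
    return float(((X - X.mean(axis=0)) ** 2).sum())


def kmeans_fit(X, k: int, n_init: int = 25, seed: int | None = None) -> KMeansFit:
    """Best of ``n_init`` seeded Lloyd k-means runs (lowest W_k wins)."""
    X = check_array(X)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({X.shape[0]})")
    if k == 1:
        centroid = X.mean(axis=0, keepdims=True)
        return KMeansFit(
            k=1,
            labels=np.zeros(X.shape[0], dtype=np.int64),
            centroids=centroid,
            W_k=_total_ss(X),
            n_init=n_init,
            seed=seed,
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd").fit(X)
    return KMeansFit(
        k=k,
        labels=km.labels_.astype(np.int64),
        centroids=km.cluster_centers_,
        W_k=float(km.inertia_),
        n_init=n_init,
        seed=seed,
    )


def select_k(gap, s) -> int:
    """One-standard-error selection rule on a gap curve.

    Returns the smallest k (1-based) with ``gap[k] >= gap[k+1] - s[k+1]``;
    if the rule never fires, returns the largest k with a warning.
    """
    gap = np.asarray(gap, dtype=float)
    s = np.asarray(s, dtype=float)
    k_max = len(gap)
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            return i + 1
    warnings.warn(
        f"gap statistic: one-standard-error rule never fired; returning k_max={k_max}",
        stacklevel=2,
    )
    return k_max


def gap_statistic(
    X,
    k_max: int = 10,
    B: int = 50,
    n_init: int = 25,
    seed: int | None = None,
) -> GapStatisticResult:
    """Gap-statistic model selection over ``k = 1 .. k_max``.

    Reference datasets are drawn uniformly over each column's observed range
    (the simple reference distribution) and clustered under the same
    best-of-``n_init`` policy as the data. Selection uses the
    one-standard-error rule; if no ``k`` satisfies it, ``k_max`` is returned
    with a warning.
    """
    X = check_array(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if B < 10:
        raise ValueError("B must be >= 10 for a usable standard error")
    rng = np.random.default_rng(seed)
    # pre-drawn child seeds keep data fits and reference fits independent
    data_seeds = rng.integers(0, 2**31 - 1, size=k_max)
    ref_seeds = rng.integers(0, 2**31 - 1, size=(B, k_max))

    k_values = np.arange(1, k_max + 1)
    log_W = np.array(
        [np.log(kmeans_fit(X, k, n_init=n_init, seed=int(data_seeds[k - 1])).W_k)
         for k in k_values]
    )

    lo, hi = X.min(axis=0), X.max(axis=0)
    log_W_ref = np.empty((B, k_max))
    for b in range(B):
        Xb = rng.uniform(lo, hi, size=X.shape)
        for k in k_values:
            log_W_ref[b, k - 1] = np.log(
                kmeans_fit(Xb, k, n_init=n_init, seed=int(ref_seeds[b, k - 1])).W_k
            )

    gap = log_W_ref.mean(axis=0) - log_W
    s = log_W_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    chosen_k = select_k(gap, s)
    return GapStatisticResult(
        k_values=k_values, log_Wk=log_W, gap=gap, s=s, B=B, chosen_k=chosen_k, seed=seed
    )


class GapStatisticKMeans(ClusterMixin, BaseEstimator):
    """K-means whose cluster count is selected by the gap statistic.

    Parameters
    ----------
    k_max : int, default=10
        Largest cluster count considered.
    B : int, default=50
        Number of uniform reference datasets.
    n_init : int, default=25
        Random k-means restarts per (dataset, k); best W_k wins.
    random_state : int or None
        Seed for reference draws and k-means initialisation.

    Attributes
    ----------
    n_clusters_ : selected number of clusters.
    labels_ : cluster index per row of the fitted data.
    cluster_centers_ : centroids at the selected k.
    inertia_ : within-cluster sum of squares at the selected k.
    gap_result_ : the full :class:`GapStatisticResult` curve.
    """

    def __init__(self, k_max: int = 10, B: int = 50, n_init: int = 25,
                 random_state: int | None = None):
        self.k_max = k_max
        self.B = B
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        seeds = np.random.default_rng(self.random_state).integers(0, 2**31 - 1, size=2)
        self.gap_result_ = gap_statistic(
            X, k_max=self.k_max, B=self.B, n_init=self.n_init, seed=int(seeds[0])
        )
        self.n_clusters_ = self.gap_result_.chosen_k
        fit = kmeans_fit(X, self.n_clusters_, n_init=self.n_init, seed=int(seeds[1]))
        self.labels_ = fit.labels
        self.cluster_centers_ = fit.centroids
        self.inertia_ = fit.W_k
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def name_clusters(labels: pd.Series, raw_covariates: pd.DataFrame) -> FMCAssignment:
    """Name clusters a posteriori from raw-covariate cluster means (k = 4 only).

    Deterministic heuristic: Roamers take the largest mean ``q99_km``; of the
    rest, Occasionals the largest ``mean_gap_min``; of the remaining two,
    Residents the largest ``n_detections``; the last class are Irruptors.
    For any other k the classes keep numeric names ``class_1..class_k``.

    Raises ``ValueError`` on an exact tie in a deciding mean (manual naming
    is then required) or if ``labels`` and ``raw_covariates`` disagree on
    tags.
    """
    labels = labels.astype(int)
    if not labels.index.equals(raw_covariates.index):
        raw_covariates = raw_covariates.loc[labels.index]
    clusters = sorted(labels.unique())
    if len(clusters) != 4:
        names = {c: f"class_{i + 1}" for i, c in enumerate(clusters)}
        return FMCAssignment(labels=labels, names=names)

    means = raw_covariates.groupby(labels).mean()

    def take(pool: list[int], covariate: str) -> int:
        vals = means.loc[pool, covariate]
        top = vals.max()
        winners = vals.index[vals == top]
        if len(winners) > 1:
            raise ValueError(
                f"tie on mean {covariate} between clusters {list(winners)}; "
                "name clusters manually"
            )
        return int(winners[0])

    pool = list(clusters)
    names: dict[int, str] = {}
    roamer = take(pool, "q99_km")
    names[roamer] = "Roamers"
    pool.remove(roamer)
    occasional = take(pool, "mean_gap_min")
    names[occasional] = "Occasionals"
    pool.remove(occasional)
    resident = take(pool, "n_detections")
    names[resident] = "Residents"
    pool.remove(resident)
    names[pool[0]] = "Irruptors"
    return FMCAssignment(labels=labels, names=names)


@dataclass
class SensitivityResult:
    """Chosen-k stability under random tag removal."""

    removal_size: int
    chosen_ks: list[int]
    mean_k: float = field(init=False)

    def __post_init__(self):
        self.mean_k = float(np.mean(self.chosen_ks))


def sensitivity_analysis(
    X,
    removal_sizes: tuple[int, ...] = (1, 10, 100),
    iterations: int = 20,
    k_max: int = 10,
    B: int = 50,
    n_init: int = 25,
    seed: int | None = None,
) -> dict[int, SensitivityResult]:
    """Re-select k after randomly excluding tags, per removal size.

    Each iteration removes a uniform tag subset without replacement and
    re-runs the gap statistic; the per-size mean chosen k and the full
    per-iteration list are returned.
    """
    X = check_array(X)
    n = X.shape[0]
    if max(removal_sizes) >= n:
        raise ValueError(f"removal sizes must be < number of rows ({n})")
    rng = np.random.default_rng(seed)
    out: dict[int, SensitivityResult] = {}
    for size in removal_sizes:
        ks: list[int] = []
        for _ in range(iterations):
            drop = rng.choice(n, size=size, replace=False)
            keep = np.setdiff1d(np.arange(n), drop)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = gap_statistic(X[keep], k_max=k_max, B=B, n_init=n_init, seed=sub_seed)
            ks.append(res.chosen_k)
        out[size] = SensitivityResult(removal_size=size, chosen_ks=ks)
    return out


def best_match_accuracy(labels_a, labels_b) -> float:
    """Agreement between two labelings under the best bijective matching.

    Builds the contingency table and solves the assignment problem for the
    label pairing that maximises agreement; returns matched agreements as a
    fraction of all items. Used for truth-archetype recovery scoring and for
    Full-vs-subset cluster overlap.
    """
    from scipy.optimize import linear_sum_assignment

    a = pd.Series(labels_a).reset_index(drop=True)
    b = pd.Series(labels_b).reset_index(drop=True)
    if len(a) != len(b):
        raise ValueError("labelings must have equal length")
    table = pd.crosstab(a, b)
    rows, cols = linear_sum_assignment(-table.to_numpy())
    return float(table.to_numpy()[rows, cols].sum() / len(a))


def pca_project(X) -> PCAProjection:
    """Project rows on the top-two principal components.

    Eigendecomposition of the sample covariance of ``X`` (already
    centred/scaled upstream; re-centred here for safety). Percent variance
    per component is its eigenvalue as a share of the trace. Sign
    convention: the largest-magnitude loading of each component is positive.
    """
    X = check_array(X)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as columns ({p}) for PCA")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(p):
        lead = np.argmax(np.abs(evecs[:, j]))
        if evecs[lead, j] < 0:
            evecs[:, j] = -evecs[:, j]
    percent = 100.0 * evals / evals.sum()
    return PCAProjection(coords=Xc @ evecs[:, :2], percent_variance=percent, components=evecs)
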