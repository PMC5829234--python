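"""Per-tag movement covariates and the transform that feeds clustering.

Seven covariates summarise each tagged individual's detection history:

* ``n_installations`` — distinct installations with at least one detection;
* ``n_detections`` — total number of detections;
* ``mean_gap_min`` — mean time between consecutive detections, in minutes;
* ``q25_km``, ``q50_km``, ``q75_km``, ``q99_km`` — quantiles of the
  great-circle distance (km) between consecutive detections. The 99%
  quantile is used instead of the maximum so a single extreme hop does not
  dominate the upper tail.

Distances are computed from receiver coordinates (the detection locations)
in time order, with simultaneous detections tie-broken by receiver name.
Quantiles use linear interpolation between order statistics at positions
``1 + (n - 1) p`` — the R ``quantile`` type-7 convention, which is also
numpy's default — stated explicitly because quantile dialects differ.

Before clustering, every covariate is square-root transformed (to reduce
skew), column-centred, and divided by its sample standard deviation
(``n - 1`` denominator), giving each covariate equal leverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import sort_detections

EARTH_RADIUS_KM = 6371.0

#: Covariate column order used throughout the package.
COVARIATE_NAMES = [
    "n_installations",
    "n_detections",
    "mean_gap_min",
    "q25_km",
    "q50_km",
    "q75_km",
    "q99_km",
]

_QUANTILES = (0.25, 0.50, 0.75, 0.99)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in kilometres (haversine, Earth radius 6371 km).

    Accepts scalars or numpy-broadcastable arrays of decimal degrees.
    Symmetric in its two points; zero iff the points coincide.

    Raises ``ValueError`` for coordinates outside [-90, 90] x [-180, 180].
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any((lat < -90.0) | (lat > 90.0)):
            raise ValueError("latitude out of range [-90, 90]")
    for lon in (lon1, lon2):
        if np.any((lon < -180.0) | (lon > 180.0)):
            raise ValueError("longitude out of range [-180, 180]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _track_covariates(track: pd.DataFrame) -> dict[str, float]:
    ts = track["timestamp"].to_numpy(dtype="datetime64[s]")
    lat = track["latitude"].to_numpy(dtype=float)
    lon = track["longitude"].to_numpy(dtype=float)
    gaps_min = np.diff(ts).astype("timedelta64[s]").astype(float) / 60.0
    dists = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    q = np.quantile(dists, _QUANTILES)  # linear interpolation (type 7)
    return {
        "n_installations": float(track["installation_id"].nunique()),
        "n_detections": float(len(track)),
        "mean_gap_min": float(gaps_min.mean()),
        "q25_km": float(q[0]),
        "q50_km": float(q[1]),
        "q75_km": float(q[2]),
        "q99_km": float(q[3]),
    }


def compute_covariates(
    detections: pd.DataFrame,
    min_detections: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the seven movement covariates for every tag.

    Parameters
    ----------
    detections:
        QC-filtered detection table (internal layout, see :mod:`fmclass.io`).
    min_detections:
        Tags with fewer detections are excluded — the gap and distance
        covariates need at least two detections. Exclusions are returned,
        never silently dropped.

    Returns
    -------
    (covariates, excluded):
        ``covariates`` is indexed by ``tag_id`` with columns
        :data:`COVARIATE_NAMES`; ``excluded`` lists rejected tags with their
        detection count and a reason.
    """
    if min_detections < 2:
        raise ValueError("min_detections must be >= 2 (gaps and distances need two detections)")
    rows: dict[str, dict[str, float]] = {}
    excluded: list[tuple[str, int, str]] = []
    if not detections.empty:
        ordered = sort_detections(detections)
        for tag, track in ordered.groupby("tag_id", sort=True):
            if len(track) < min_detections:
                excluded.append(
                    (str(tag), len(track), f"fewer than {min_detections} detections")
                )
            else:
                rows[str(tag)] = _track_covariates(track)
    cov = pd.DataFrame.from_dict(rows, orient="index", columns=COVARIATE_NAMES)
    cov.index.name = "tag_id"
    exc = pd.DataFrame(excluded, columns=["tag_id", "n_detections", "reason"])
    return cov, exc


class SqrtStandardScaler(TransformerMixin, BaseEstimator):
    """Square-root transform followed by column centring and unit scaling.

    The square root reduces the strong right skew of count-like movement
    covariates; centring and scaling give every covariate the same leverage
    in Euclidean clustering. Scaling uses the sample standard deviation
    (``n - 1`` denominator).

    Attributes
    ----------
    mean_ : ndarray of shape (n_features,)
        Column means of the square-rooted data.
    scale_ : ndarray of shape (n_features,)
        Sample standard deviations of the square-rooted data.
    """

    def fit(self, X, y=None):
        names = getattr(X, "columns", None)
        X = check_array(X, ensure_min_samples=2)
        if np.any(X < 0):
            raise ValueError("covariates must be non-negative for the square-root transform")
        root = np.sqrt(X)
        self.mean_ = root.mean(axis=0)
        self.scale_ = root.std(axis=0, ddof=1)
        zero = np.flatnonzero(self.scale_ == 0.0)
        if zero.size:
            labels = [str(i) for i in zero] if names is None else [str(names[i]) for i in zero]
            raise ValueError(
                "zero-variance column(s) after square root, scaling undefined: "
                + ", ".join(labels)
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = check_array(X)
        if np.any(X < 0):
            raise ValueError("covariates must be non-negative for the square-root transform")
        return (np.sqrt(X) - self.mean_) / self.scale_


@dataclass
class CovariateMatrix:
    """Raw and transformed covariate matrices, with row (tag) labels."""

    tags: list[str]
    raw: pd.DataFrame
    transformed: pd.DataFrame
    scaler: SqrtStandardScaler = field(repr=False)

    @property
    def X(self) -> np.ndarray:
        """Transformed values as a float array (tags x covariates)."""
        return self.transformed.to_numpy(dtype=float)


def build_covariate_matrix(covariates: pd.DataFrame) -> CovariateMatrix:
    """Apply sqrt -> centre -> scale column-wise; keep the raw matrix alongside.

    ``covariates`` must hold at least two tags and only non-negative values.
    Raises ``ValueError`` naming the column if a covariate has zero variance
    after the square root (scaling would be undefined).
    """
    if len(covariates) < 2:
        raise ValueError("need at least two tags to centre and scale covariates")
    raw = covariates[COVARIATE_NAMES].astype(float)
    scaler = SqrtStandardScaler().fit(raw)
    transformed = pd.DataFrame(
        scaler.transform(raw), index=raw.index, columns=COVARIATE_NAMES
    )
    return CovariateMatrix(
        tags=[str(t) for t in raw.index], raw=raw, transformed=transformed, scaler=scaler
    )
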