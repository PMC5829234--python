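"""Detection and installation tables: CSV dialects, QC filtering, track building.

Acoustic-telemetry detection logs arrive as one CSV row per detection: a
transmitter (tag) heard by a named receiver that belongs to a named
installation, with the receiver's coordinates, a timestamp and a quality
control flag. Only detections whose QC flag marks them as valid (flags 1
and 2 by default) enter the analysis.

Internally detections are a :class:`pandas.DataFrame` with normalised
column names (:data:`DETECTION_FIELDS`), timestamps stored timezone-naive
at second resolution in UTC, and rows sorted deterministically by
``(tag_id, timestamp, receiver_id)`` when tracks are built.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical internal column order for a detection table.
DETECTION_FIELDS = [
    "tag_id",
    "timestamp",
    "receiver_id",
    "installation_id",
    "latitude",
    "longitude",
    "qc_flag",
    "species",
]

#: External CSV header -> internal column name.
CSV_TO_INTERNAL = {
    "transmitter_id": "tag_id",
    "detection_datetime": "timestamp",
    "receiver_name": "receiver_id",
    "installation_name": "installation_id",
    "latitude": "latitude",
    "longitude": "longitude",
    "QC_flag": "qc_flag",
    "species_common_name": "species",
}

MANDATORY_CSV_COLUMNS = [
    "transmitter_id",
    "detection_datetime",
    "receiver_name",
    "installation_name",
    "latitude",
    "longitude",
    "QC_flag",
]

#: QC flags accepted by default ("valid" and "probably valid" detections).
DEFAULT_QC_KEEP = frozenset({1, 2})


class SchemaError(ValueError):
    """A required column is missing from an input CSV."""


def read_detections(
    path: str | Path,
    qc_keep: Iterable[int] = DEFAULT_QC_KEEP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a detections CSV, QC-filter it and validate every row.

    Parameters
    ----------
    path:
        CSV file with at least the columns in :data:`MANDATORY_CSV_COLUMNS`.
        ``station_name`` and ``species_common_name`` are optional.
    qc_keep:
        QC flag values to retain (default ``{1, 2}``). Rows with other flags
        are filtered out silently — this is the intended QC filter, not a
        data error.

    Returns
    -------
    (detections, rejected):
        ``detections`` holds the retained rows in internal column layout
        (:data:`DETECTION_FIELDS`), timestamps as timezone-naive UTC at
        second resolution. ``rejected`` reports rows with unparseable
        timestamps or out-of-range coordinates, one row each with the
        source row number (0-based, excluding the header) and a reason —
        bad rows are reported, never silently dropped.

    Raises
    ------
    SchemaError
        If a mandatory column is missing (the message names the column).
    """
    path = Path(path)
    raw = pd.read_csv(
        path,
        dtype={"transmitter_id": str, "receiver_name": str, "installation_name": str},
        float_precision="round_trip",
    )
    for col in MANDATORY_CSV_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"detections CSV {path} is missing mandatory column {col!r}")
    if raw.empty:
        logger.warning("detections CSV %s contains no data rows", path)
        empty = _empty_detections()
        return empty, _empty_rejects()

    df = raw.rename(columns=CSV_TO_INTERNAL)
    if "species" not in df.columns:
        df["species"] = pd.NA

    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="mixed")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")

    bad_ts = ts.isna()
    bad_lat = lat.isna() | (lat < -90.0) | (lat > 90.0)
    bad_lon = lon.isna() | (lon < -180.0) | (lon > 180.0)

    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[bad_ts] = "unparseable timestamp"
    reasons[bad_lat & ~bad_ts] = "latitude out of range"
    reasons[bad_lon & ~bad_ts & ~bad_lat] = "longitude out of range"
    bad = bad_ts | bad_lat | bad_lon

    rejected = pd.DataFrame(
        {"row": df.index[bad].to_numpy(), "reason": reasons[bad].to_numpy()}
    )
    if len(rejected):
        logger.warning("rejected %d malformed detection rows from %s", len(rejected), path)

    df = df.loc[~bad].copy()
    df["timestamp"] = (
        ts.loc[~bad].dt.tz_convert("UTC").dt.tz_localize(None).dt.floor("s")
        .astype("datetime64[s]")
    )
    df["latitude"] = lat.loc[~bad]
    df["longitude"] = lon.loc[~bad]
    df["qc_flag"] = pd.to_numeric(df["qc_flag"], errors="coerce").astype("Int64")

    keep = df["qc_flag"].isin(set(qc_keep))
    df = df.loc[keep, DETECTION_FIELDS].reset_index(drop=True)
    df["qc_flag"] = df["qc_flag"].astype(np.int64)
    return df, rejected


def write_detections(detections: pd.DataFrame, path: str | Path) -> None:
    """Write a detection table in the exact CSV dialect ``read_detections`` consumes.

    Timestamps are serialised as ISO 8601 UTC with a ``Z`` suffix. Output is
    byte-stable for a fixed row order.
    """
    path = Path(path)
    out = pd.DataFrame(
        {
            "transmitter_id": detections.get("tag_id", pd.Series(dtype=str)),
            "detection_datetime": (
                detections["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
                if len(detections)
                else pd.Series(dtype=str)
            ),
            "receiver_name": detections.get("receiver_id", pd.Series(dtype=str)),
            "installation_name": detections.get("installation_id", pd.Series(dtype=str)),
            "latitude": detections.get("latitude", pd.Series(dtype=float)),
            "longitude": detections.get("longitude", pd.Series(dtype=float)),
            "QC_flag": detections.get("qc_flag", pd.Series(dtype=np.int64)),
            "species_common_name": detections.get("species", pd.Series(dtype=object)),
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_installations(path: str | Path) -> pd.DataFrame:
    """Read the installation membership table.

    One row per receiver: ``installation_name``, ``installation_type``
    (exactly ``IMOS`` or ``non-IMOS``) and ``receiver_name``. Every receiver
    must belong to exactly one installation and every installation must have
    a type.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    for col in ("installation_name", "installation_type", "receiver_name"):
        if col not in raw.columns:
            raise SchemaError(f"installations CSV {path} is missing mandatory column {col!r}")
    df = raw.rename(
        columns={
            "installation_name": "installation_id",
            "receiver_name": "receiver_id",
        }
    )[["installation_id", "installation_type", "receiver_id"]]
    bad_types = set(df["installation_type"].dropna().unique()) - {"IMOS", "non-IMOS"}
    if bad_types:
        raise SchemaError(
            f"installation_type must be 'IMOS' or 'non-IMOS'; found {sorted(bad_types)}"
        )
    dup = df["receiver_id"].duplicated()
    if dup.any():
        multi = df.loc[dup, "receiver_id"].unique()
        raise SchemaError(f"receivers assigned to more than one installation: {list(multi)[:5]}")
    types = df.groupby("installation_id")["installation_type"].nunique()
    if (types > 1).any():
        raise SchemaError(
            f"installations with conflicting types: {list(types.index[types > 1])}"
        )
    return df.reset_index(drop=True)


def write_installations(installations: pd.DataFrame, path: str | Path) -> None:
    """Write the installation membership table (inverse of ``read_installations``)."""
    out = installations.rename(
        columns={"installation_id": "installation_name", "receiver_id": "receiver_name"}
    )[["installation_name", "installation_type", "receiver_name"]]
    out.to_csv(path, index=False, lineterminator="\n")


def installation_types(installations: pd.DataFrame) -> pd.Series:
    """Map ``installation_id -> installation_type`` from the membership table."""
    return installations.drop_duplicates("installation_id").set_index("installation_id")[
        "installation_type"
    ]


def sort_detections(detections: pd.DataFrame) -> pd.DataFrame:
    """Deterministic detection order: (tag_id, timestamp, receiver_id).

    Simultaneous detections are tie-broken lexicographically by receiver so
    consecutive-detection distances are reproducible.
    """
    return detections.sort_values(
        ["tag_id", "timestamp", "receiver_id"], kind="mergesort"
    ).reset_index(drop=True)


def build_tracks(detections: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a detection table into per-tag, time-ordered tracks.

    Returns a map ``tag_id -> DataFrame`` where each frame is sorted by
    ``(timestamp, receiver_id)``. Duplicate rows are kept: detection counts
    are a clustering covariate, so deduplication would alter results. The
    track lengths sum to the input length.
    """
    if detections.empty:
        return {}
    ordered = sort_detections(detections)
    return {
        str(tag): group.reset_index(drop=True)
        for tag, group in ordered.groupby("tag_id", sort=True)
    }


def _empty_detections() -> pd.DataFrame:
    df = pd.DataFrame(columns=DETECTION_FIELDS)
    df["timestamp"] = pd.to_datetime(df["timestamp"]).astype("datetime64[s]")
    for col in ("latitude", "longitude"):
        df[col] = df[col].astype(float)
    df["qc_flag"] = df["qc_flag"].astype(np.int64)
    return df


def _empty_rejects() -> pd.DataFrame:
    return pd.DataFrame({"row": pd.Series(dtype=np.int64), "reason": pd.Series(dtype=object)})
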