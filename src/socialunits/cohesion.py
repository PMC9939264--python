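"""GPS subsampling and daily dyadic-distance cohesion summaries.

Positional fixes are subsampled to a common grid (one fix per individual per
interval, 5 min by default, bins aligned to the UTC epoch).  Cohesion of a
detected community is then measured from the tagged individuals assigned to
it: for every day, the distances between all pairs of tagged members at every
shared time bin are averaged into a daily value, and the per-window summary
reports the mean and maximum of those daily values.

Coordinates are planar projected metres; distance is Euclidean.  Only fixes
sharing the same time bin are paired — there is no interpolation between
fixes.  Sex filtering (the cohesion analysis uses philopatric males only, as
dispersing females would inflate within-unit distances) is the caller's
responsibility via ``gps_ids``.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import CommunityPartition

__all__ = [
    "GpsFix",
    "CohesionSummary",
    "load_gps",
    "write_gps",
    "fixes_to_frame",
    "frame_to_fixes",
    "subsample_fixes",
    "daily_pairwise_distances",
]

GPS_COLUMNS = ["individual_id", "timestamp", "easting_m", "northing_m"]


@dataclass(frozen=True)
class GpsFix:
    """One positional fix in projected planar coordinates (metres)."""

    individual: str
    timestamp: dt.datetime
    easting: float
    northing: float


@dataclass(frozen=True)
class CohesionSummary:
    """Per-unit, per-window summary of daily dyadic distances (metres)."""

    unit: str
    window_id: str
    mean_daily_distance: float
    max_daily_distance: float
    n_dyads: int
    n_days: int


def fixes_to_frame(fixes: list[GpsFix]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [f.individual for f in fixes],
            "timestamp": pd.to_datetime([f.timestamp for f in fixes], utc=True),
            "easting_m": [f.easting for f in fixes],
            "northing_m": [f.northing for f in fixes],
        }
    )


def frame_to_fixes(frame: pd.DataFrame) -> list[GpsFix]:
    return [
        GpsFix(row.individual_id, row.timestamp.to_pydatetime(), row.easting_m, row.northing_m)
        for row in frame.itertuples(index=False)
    ]


def _as_frame(fixes) -> pd.DataFrame:
    if isinstance(fixes, pd.DataFrame):
        frame = fixes.copy()
        missing = [c for c in GPS_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"GPS frame missing columns {missing}")
        frame["timestamp"] = pd.to_datetime(frame["timestamp"], utc=True)
        return frame
    return fixes_to_frame(list(fixes))


def load_gps(path: str | Path) -> pd.DataFrame:
    """Read GPS fixes from CSV (``individual_id,timestamp,easting_m,
    northing_m``, ISO-8601 UTC timestamps)."""
    frame = pd.read_csv(path, comment="#")
    return _as_frame(frame)


def write_gps(fixes, path: str | Path) -> None:
    frame = _as_frame(fixes)
    out = frame.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out[GPS_COLUMNS].to_csv(path, index=False)


def subsample_fixes(fixes, interval: int = 300) -> pd.DataFrame:
    """Keep one fix per individual per ``interval``-second bin.

    Bins are aligned to the UTC epoch; within each bin the earliest fix wins
    and its timestamp is replaced by the bin label (the bin start).
    Idempotent on already-gridded data.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    frame = _as_frame(fixes)
    if frame.empty:
        frame["timestamp"] = pd.to_datetime(frame.get("timestamp", []), utc=True)
        return frame[GPS_COLUMNS]
    epoch = frame["timestamp"].astype("int64") // 10**9
    frame = frame.assign(_bin=epoch // interval)
    frame = frame.sort_values(["individual_id", "timestamp"], kind="stable")
    first = frame.groupby(["individual_id", "_bin"], as_index=False).first()
    first["timestamp"] = pd.to_datetime(first["_bin"] * interval, unit="s", utc=True)
    first = first.sort_values(["individual_id", "timestamp"], kind="stable")
    return first[GPS_COLUMNS].reset_index(drop=True)


def daily_pairwise_distances(
    fixes,
    partition: CommunityPartition,
    gps_ids: set[str],
) -> list[CohesionSummary]:
    """Daily dyadic-distance summaries per community of a partition.

    ``fixes`` must already be subsampled to the common grid and restricted to
    the period of interest.  For each community with at least two tagged
    members, every dyad is paired at every shared time bin; the mean distance
    over all dyad-bin values of a day is that day's value, and the summary
    reports the mean and the maximum of the daily values.  Communities whose
    dyads share no time bin are omitted with a warning.
    """
    frame = _as_frame(fixes)
    tagged = gps_ids & set(partition.assignment)
    frame = frame[frame["individual_id"].isin(sorted(tagged))]
    summaries: list[CohesionSummary] = []
    for label, members in sorted(partition.communities().items()):
        tagged_members = sorted(members & tagged)
        if len(tagged_members) < 2:
            continue
        sub = frame[frame["individual_id"].isin(tagged_members)]
        pairs = sub.merge(sub, on="timestamp", suffixes=("_i", "_j"))
        pairs = pairs[pairs["individual_id_i"] < pairs["individual_id_j"]]
        if pairs.empty:
            warnings.warn(
                f"community {label}: no shared time bins among tagged members",
                stacklevel=2,
            )
            continue
        dist = np.hypot(
            pairs["easting_m_i"] - pairs["easting_m_j"],
            pairs["northing_m_i"] - pairs["northing_m_j"],
        )
        daily = dist.groupby(pairs["timestamp"].dt.normalize()).mean()
        n_dyads = pairs[["individual_id_i", "individual_id_j"]].drop_duplicates().shape[0]
        summaries.append(
            CohesionSummary(
                unit=label,
                window_id=partition.window_id,
                mean_daily_distance=float(daily.mean()),
                max_daily_distance=float(daily.max()),
                n_dyads=int(n_dyads),
                n_days=int(daily.shape[0]),
            )
        )
    return summaries
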