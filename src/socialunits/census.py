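"""Census observations, the standard filtering rules, and focal windows.

A census *record* is one field observation of an aggregation: the set of
identified individuals seen together, a count of unmarked birds, whether the
aggregation behaved as one cohesive set (``single``) or as several distinct
sets that happened to be co-located (``multiple``), and a completeness flag.

Social networks are built per *focal window*.  A window has a focal interval
(the period whose social structure is being estimated) and a wider sampling
interval (the census data actually used to build that window's network).  For
the sliding 1-month and 2-month bases the sampling interval extends one
calendar month on either side of the focal interval; the 8-month basis uses a
single window covering the whole study.

All date intervals are half-open ``[start, end)`` and aligned to calendar
months.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "CensusRecord",
    "FocalWindow",
    "ApproachConfig",
    "CensusFormatError",
    "load_census",
    "write_census",
    "filter_census",
    "retained_individuals",
    "make_windows",
    "WINDOW_BASES",
]

WINDOW_BASES = ("1-month", "2-month", "8-month")

CENSUS_COLUMNS = [
    "date",
    "session",
    "observation_id",
    "cohesion",
    "individual_ids",
    "n_unmarked",
    "complete",
]


class CensusFormatError(ValueError):
    """Raised when a census CSV does not match the expected schema."""


@dataclass(frozen=True)
class CensusRecord:
    """One observed aggregation from a morning or evening census."""

    date: dt.date
    session: str
    observation_id: str
    cohesion: str
    individual_ids: frozenset[str]
    n_unmarked: int = 0
    complete: bool = True

    def __post_init__(self) -> None:
        if self.session not in ("AM", "PM"):
            raise ValueError(f"session must be AM or PM, got {self.session!r}")
        if self.cohesion not in ("single", "multiple"):
            raise ValueError(
                f"cohesion must be 'single' or 'multiple', got {self.cohesion!r}"
            )
        if self.n_unmarked < 0:
            raise ValueError("n_unmarked must be >= 0")
        object.__setattr__(self, "individual_ids", frozenset(self.individual_ids))


@dataclass(frozen=True)
class FocalWindow:
    """A focal interval plus the sampling interval used to build its network.

    Both intervals are half-open; the sampling interval always contains the
    focal interval.
    """

    window_id: str
    focal_start: dt.date
    focal_end: dt.date
    sampling_start: dt.date
    sampling_end: dt.date

    def __post_init__(self) -> None:
        if not (self.sampling_start <= self.focal_start < self.focal_end <= self.sampling_end):
            raise ValueError(f"sampling interval must contain focal interval: {self}")

    def in_sampling(self, date: dt.date) -> bool:
        return self.sampling_start <= date < self.sampling_end

    def in_focal(self, date: dt.date) -> bool:
        return self.focal_start <= date < self.focal_end


@dataclass(frozen=True)
class ApproachConfig:
    """One cell of the approach grid: window basis x bootstrap x carryover.

    Parameters
    ----------
    basis:
        Window basis: ``"1-month"``, ``"2-month"`` or ``"8-month"``.
    bootstrap:
        Detect communities on a bootstrapped co-membership meta-network
        (100 replicates by default) instead of directly on the observed
        network.
    carryover:
        Link community identities across consecutive windows with the dynamic
        tracker.  Not applicable to the 8-month basis, which has a single
        sampling period.
    n_boot:
        Number of bootstrap replicates.
    edge_threshold:
        Association-index weights strictly below this value are zeroed before
        community detection (edges weaker than 0.5 carry little information
        about unit co-membership and destabilise the detection).
    min_obs:
        Minimum number of observations for an individual to be retained in a
        window; the default 3 removes individuals seen two or fewer times.
    walktrap_steps:
        Random-walk length of the community detection algorithm.
    seed:
        Seed from which all per-window and per-replicate randomness derives.
    """

    basis: str
    bootstrap: bool = False
    carryover: bool = False
    n_boot: int = 100
    edge_threshold: float = 0.5
    min_obs: int = 3
    walktrap_steps: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.basis not in WINDOW_BASES:
            raise ValueError(f"basis must be one of {WINDOW_BASES}, got {self.basis!r}")
        if self.basis == "8-month" and self.carryover:
            raise ValueError(
                "carryover tracking is not applicable to the 8-month basis "
                "(single sampling period)"
            )
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ValueError("edge_threshold must be in [0, 1]")
        if self.min_obs < 1:
            raise ValueError("min_obs must be >= 1")
        if self.walktrap_steps < 1:
            raise ValueError("walktrap_steps must be >= 1")

    @property
    def label(self) -> str:
        """Compact approach label, e.g. ``1-month+boot+carry``."""
        parts = [self.basis]
        if self.bootstrap:
            parts.append("boot")
        if self.carryover:
            parts.append("carry")
        return "+".join(parts)

    @property
    def method_tag(self) -> str:
        return (
            f"basis={self.basis};bootstrap={self.bootstrap};"
            f"carryover={self.carryover};n_boot={self.n_boot};"
            f"threshold={self.edge_threshold};min_obs={self.min_obs};"
            f"steps={self.walktrap_steps}"
        )


# ---------------------------------------------------------------------------
# I/O


def load_census(path: str | Path) -> list[CensusRecord]:
    """Read census records from CSV.

    Expected header: ``date,session,observation_id,cohesion,individual_ids,
    n_unmarked,complete`` with ISO dates, ``;``-delimited individual tokens
    and ``complete`` coded 0/1.  Lines starting with ``#`` are ignored.

    Raises
    ------
    CensusFormatError
        On a malformed row (reported with its row number) or a duplicate
        observation id.
    """
    try:
        frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CensusFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CENSUS_COLUMNS if c not in frame.columns]
    if missing:
        raise CensusFormatError(f"{path}: missing columns {missing}")

    records: list[CensusRecord] = []
    seen_ids: set[str] = set()
    errors: list[str] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            date = dt.date.fromisoformat(row.date)
            ids = frozenset(tok for tok in row.individual_ids.split(";") if tok)
            complete = {"0": False, "1": True}[row.complete]
            rec = CensusRecord(
                date=date,
                session=row.session,
                observation_id=row.observation_id,
                cohesion=row.cohesion,
                individual_ids=ids,
                n_unmarked=int(row.n_unmarked),
                complete=complete,
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {row_no}: {exc}")
            continue
        if rec.observation_id in seen_ids:
            errors.append(f"row {row_no}: duplicate observation_id {rec.observation_id!r}")
            continue
        seen_ids.add(rec.observation_id)
        records.append(rec)
    if errors:
        raise CensusFormatError(f"{path}: " + "; ".join(errors))
    return records


def write_census(records: list[CensusRecord], path: str | Path) -> None:
    """Write census records to the CSV schema read by :func:`load_census`."""
    rows = [
        {
            "date": r.date.isoformat(),
            "session": r.session,
            "observation_id": r.observation_id,
            "cohesion": r.cohesion,
            "individual_ids": ";".join(sorted(r.individual_ids)),
            "n_unmarked": r.n_unmarked,
            "complete": int(r.complete),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CENSUS_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering rules


def filter_census(records: list[CensusRecord]) -> list[CensusRecord]:
    """Keep only cohesive ('single') and complete observations, in order.

    Observations of multiple co-located sets mix distinct units in one row and
    incomplete censuses add noise to the network, so both are excluded from
    network construction.  Idempotent.
    """
    return [r for r in records if r.cohesion == "single" and r.complete]


def retained_individuals(
    records: list[CensusRecord], window: FocalWindow, min_obs: int = 3
) -> set[str]:
    """Individuals observed at least ``min_obs`` times in the window's
    sampling interval.

    Individuals seen two or fewer times carry too little information for a
    reliable network position, so the default keeps those seen three or more
    times.
    """
    counts: dict[str, int] = {}
    for rec in records:
        if window.in_sampling(rec.date):
            for ind in rec.individual_ids:
                counts[ind] = counts.get(ind, 0) + 1
    return {ind for ind, n in counts.items() if n >= min_obs}


# ---------------------------------------------------------------------------
# Window construction


def _month_start(date: dt.date) -> dt.date:
    return date.replace(day=1)


def _add_months(date: dt.date, months: int) -> dt.date:
    month_index = date.month - 1 + months
    year = date.year + month_index // 12
    return dt.date(year, month_index % 12 + 1, 1)


def _full_months(study_start: dt.date, study_end: dt.date) -> list[dt.date]:
    """Starts of calendar months fully contained in [study_start, study_end)."""
    first = _month_start(study_start)
    if first < study_start:
        first = _add_months(first, 1)
    months = []
    m = first
    while _add_months(m, 1) <= study_end:
        months.append(m)
        m = _add_months(m, 1)
    return months


def make_windows(
    study_start: dt.date, study_end: dt.date, basis: str
) -> list[FocalWindow]:
    """Build the focal windows of a basis over a study interval.

    1-month basis: one window per interior calendar month (every full month
    except the first and last), sampling the focal month plus one month on
    either side.  2-month basis: consecutive non-overlapping two-month focal
    blocks over the interior months, again sampled with a one-month margin.
    8-month basis: a single window whose focal and sampling intervals are the
    whole study.

    Raises
    ------
    ValueError
        If the study interval is too short for the requested basis.
    """
    if basis not in WINDOW_BASES:
        raise ValueError(f"basis must be one of {WINDOW_BASES}, got {basis!r}")
    if study_start >= study_end:
        raise ValueError("study_start must precede study_end")

    if basis == "8-month":
        return [
            FocalWindow(
                window_id="8m-full",
                focal_start=study_start,
                focal_end=study_end,
                sampling_start=study_start,
                sampling_end=study_end,
            )
        ]

    months = _full_months(study_start, study_end)
    interior = months[1:-1]
    block = 1 if basis == "1-month" else 2
    if len(interior) < block:
        raise ValueError(
            f"study interval [{study_start}, {study_end}) too short for {basis} basis"
        )
    windows: list[FocalWindow] = []
    prefix = "1m" if block == 1 else "2m"
    for i in range(0, len(interior) - block + 1, block):
        focal_start = interior[i]
        focal_end = _add_months(focal_start, block)
        windows.append(
            FocalWindow(
                window_id=f"{prefix}-{focal_start:%Y-%m}",
                focal_start=focal_start,
                focal_end=focal_end,
                sampling_start=_add_months(focal_start, -1),
                sampling_end=_add_months(focal_end, 1),
            )
        )
    return windows
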