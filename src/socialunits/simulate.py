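"""Ground-truthed synthetic multi-level societies with fission-fusion
dynamics, plus the census and GPS observation processes.

The generator emulates the grouping dynamics of a terrestrial multi-level
society: stable social units of a few tens of individuals persist for months;
units temporarily fission into subunits (days to weeks) whose membership is
re-drawn at every event; during designated windows, units can join into a
cohesive supergroup that later disbands back into the original units.  Latent
unit identity is never destroyed by either process — the ground truth against
which detection is scored is the latent unit of each individual on each day.

Observation processes mirror field protocols: a twice-daily census detects
each spatial cluster with some probability and records the identified
(marked) individuals present, counting unmarked ones; a subset of males
carries GPS tags producing one fix per interval during daylight, placed
around their cluster's centroid path.

All randomness flows from a single seed through a splittable generator, so
every simulation is exactly reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census import CensusRecord

__all__ = [
    "SocietyParams",
    "SimCluster",
    "SimEvent",
    "SyntheticTruth",
    "simulate_membership",
    "simulate_census",
    "simulate_gps",
    "simulate_society",
    "truth_frame",
    "events_frame",
]

#: random-walk step of a cluster centroid between consecutive fixes (m)
CENTROID_STEP_SD = 15.0
#: daylight hours during which GPS tags record
GPS_DAY_START_HOUR = 6
GPS_DAY_END_HOUR = 18


@dataclass(frozen=True)
class SocietyParams:
    """Parameters of the synthetic society and its observation processes.

    Rates are per-unit-per-day probabilities; distances are metres; the
    study interval is half-open ``[study_start, study_end)``.
    """

    n_units: int = 8
    unit_size_mean: int = 20
    study_start: dt.date = dt.date(2020, 9, 1)
    study_end: dt.date = dt.date(2021, 5, 1)
    fission_rate: float = 0.01
    fission_duration_mean: float = 7.0
    supergroup_windows: tuple[tuple[dt.date, dt.date], ...] = ()
    supergroup_join_prob: float = 0.8
    marked_fraction: float = 0.9
    census_detect_prob: float = 0.5
    individual_miss_prob: float = 0.2
    census_incomplete_prob: float = 0.02
    n_gps_males_per_unit: int = 2
    gps_interval: int = 300
    within_unit_spread: float = 50.0
    home_range_scale: float = 2000.0
    unit_spacing: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.unit_size_mean < 2:
            raise ValueError("unit_size_mean must be >= 2")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        for name in (
            "fission_rate",
            "supergroup_join_prob",
            "marked_fraction",
            "census_detect_prob",
            "individual_miss_prob",
            "census_incomplete_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.fission_duration_mean < 1.0:
            raise ValueError("fission_duration_mean must be >= 1 day")
        if self.gps_interval <= 0:
            raise ValueError("gps_interval must be positive")
        if self.n_gps_males_per_unit < 0:
            raise ValueError("n_gps_males_per_unit must be >= 0")
        for low, high in self.supergroup_windows:
            if low >= high:
                raise ValueError("supergroup windows must be non-empty intervals")

    def dates(self) -> list[dt.date]:
        n = (self.study_end - self.study_start).days
        return [self.study_start + dt.timedelta(days=i) for i in range(n)]


@dataclass(frozen=True)
class SimCluster:
    """One spatial cluster on one day: a cohesive set of co-moving birds.

    ``key`` identifies the cluster lineage across days (a unit's main
    cluster, a fission subunit, or a supergroup) so that GPS centroid paths
    are continuous.  ``units`` lists the latent units represented.
    """

    key: str
    members: frozenset[str]
    units: tuple[str, ...]


@dataclass(frozen=True)
class SimEvent:
    date: dt.date
    kind: str  # fission | fusion | supergroup_form | supergroup_disband
    units: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated society.

    ``daily_membership`` maps (date, individual) to the latent unit — the
    partition the detection pipeline is scored against.  ``clusters`` holds
    the day's spatial clusters (the objects the observation processes see),
    and ``colocated`` lists cluster-key pairs that are co-located but
    behaviourally distinct on that day (source of 'multiple' census records).
    """

    individuals: list[str]
    unit_of: dict[str, str]
    dates: list[dt.date]
    daily_membership: dict[tuple[dt.date, str], str]
    clusters: dict[dt.date, list[SimCluster]]
    colocated: dict[dt.date, list[tuple[str, str]]]
    event_log: list[SimEvent]
    marked: set[str]
    males: list[str]
    tagged: list[str]

    def membership_on(self, date: dt.date) -> dict[str, str]:
        return {ind: self.unit_of[ind] for ind in self.individuals}


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_membership(params: SocietyParams) -> SyntheticTruth:
    """Simulate daily cluster structure and latent unit membership.

    Fission draws a random 20-50% subset of a unit's current main cluster
    (membership is re-drawn at every event) for a geometric-distributed
    number of days with mean ``fission_duration_mean``.  During a supergroup
    window, each unit independently joins with ``supergroup_join_prob``; all
    joining units form one cohesive cluster while retaining latent identity,
    and their ongoing fissions end when the supergroup forms.
    """
    rng, _, _ = _spawn(params.seed, 3)

    unit_ids = [f"U{u + 1:02d}" for u in range(params.n_units)]
    individuals: list[str] = []
    unit_of: dict[str, str] = {}
    males: list[str] = []
    tagged: list[str] = []
    serial = 0
    for unit in unit_ids:
        size = 2 + int(rng.poisson(params.unit_size_mean - 2))
        members = [f"ID{serial + k:04d}" for k in range(size)]
        serial += size
        individuals.extend(members)
        for ind in members:
            unit_of[ind] = unit
        unit_males = members[0::2]
        males.extend(unit_males)
        if params.n_gps_males_per_unit > len(unit_males):
            raise ValueError(
                f"n_gps_males_per_unit={params.n_gps_males_per_unit} exceeds the "
                f"{len(unit_males)} males of unit {unit}"
            )
        tagged.extend(unit_males[: params.n_gps_males_per_unit])

    marked = {ind for ind in individuals if rng.random() < params.marked_fraction}
    unit_members = {u: [i for i in individuals if unit_of[i] == u] for u in unit_ids}

    dates = params.dates()
    daily_membership: dict[tuple[dt.date, str], str] = {}
    clusters: dict[dt.date, list[SimCluster]] = {}
    colocated: dict[dt.date, list[tuple[str, str]]] = {}
    event_log: list[SimEvent] = []

    # active fissions: unit -> list of (key, member frozenset, end_date)
    active_fissions: dict[str, list[tuple[str, frozenset[str], dt.date]]] = {
        u: [] for u in unit_ids
    }
    fission_serial = 0
    sg_windows = sorted(params.supergroup_windows)
    active_sg: tuple[str, set[str], dt.date] | None = None  # (key, joined units, end)

    for date in dates:
        for ind in individuals:
            daily_membership[(date, ind)] = unit_of[ind]

        # supergroup lifecycle
        if active_sg is not None and date >= active_sg[2]:
            event_log.append(
                SimEvent(date, "supergroup_disband", tuple(sorted(active_sg[1])))
            )
            active_sg = None
        if active_sg is None:
            for low, high in sg_windows:
                if low == date:
                    joined = {
                        u for u in unit_ids if rng.random() < params.supergroup_join_prob
                    }
                    if len(joined) >= 2:
                        for u in joined:
                            for key, mem, end in active_fissions[u]:
                                event_log.append(SimEvent(date, "fusion", (u,)))
                            active_fissions[u] = []
                        active_sg = (f"SG-{low.isoformat()}", joined, high)
                        event_log.append(
                            SimEvent(date, "supergroup_form", tuple(sorted(joined)))
                        )
                    break

        sg_units = active_sg[1] if active_sg is not None else set()

        # fission endings
        for unit in unit_ids:
            remaining = []
            for key, mem, end in active_fissions[unit]:
                if date >= end:
                    event_log.append(SimEvent(date, "fusion", (unit,)))
                else:
                    remaining.append((key, mem, end))
            active_fissions[unit] = remaining

        # fission starts
        new_pairs: list[tuple[str, str]] = []
        for unit in unit_ids:
            if unit in sg_units:
                continue
            away = set().union(*(m for _, m, _ in active_fissions[unit])) if active_fissions[unit] else set()
            main = [i for i in unit_members[unit] if i not in away]
            if len(main) < 4:
                continue
            if rng.random() < params.fission_rate:
                frac = rng.uniform(0.2, 0.5)
                k = min(max(1, int(round(frac * len(unit_members[unit])))), len(main) - 1)
                subset = frozenset(rng.choice(main, size=k, replace=False))
                duration = int(rng.geometric(1.0 / params.fission_duration_mean))
                key = f"{unit}:f{fission_serial}"
                fission_serial += 1
                active_fissions[unit].append(
                    (key, subset, date + dt.timedelta(days=duration))
                )
                event_log.append(SimEvent(date, "fission", (unit,)))
                new_pairs.append((unit, key))

        # assemble the day's clusters
        day_clusters: list[SimCluster] = []
        if active_sg is not None:
            sg_key, joined, _ = active_sg
            members = frozenset(
                i for u in sorted(joined) for i in unit_members[u]
            )
            day_clusters.append(SimCluster(sg_key, members, tuple(sorted(joined))))
        for unit in unit_ids:
            if unit in sg_units:
                continue
            away: set[str] = set()
            for key, mem, _ in active_fissions[unit]:
                day_clusters.append(SimCluster(key, mem, (unit,)))
                away |= mem
            main = frozenset(i for i in unit_members[unit] if i not in away)
            if main:
                day_clusters.append(SimCluster(unit, main, (unit,)))
        clusters[date] = day_clusters
        colocated[date] = list(new_pairs)

    return SyntheticTruth(
        individuals=individuals,
        unit_of=unit_of,
        dates=dates,
        daily_membership=daily_membership,
        clusters=clusters,
        colocated=colocated,
        event_log=event_log,
        marked=marked,
        males=males,
        tagged=tagged,
    )


def simulate_census(truth: SyntheticTruth, params: SocietyParams) -> list[CensusRecord]:
    """Generate twice-daily census records from the simulated clusters.

    Each cluster is detected independently per session with
    ``census_detect_prob``.  Detected members are identified when marked and
    not missed; unmarked members are counted but not identified.  A cohesive
    cluster (one unit, one subunit, or one supergroup) yields a 'single'
    record.  On the day a fission starts, the departing subunit and its main
    cluster are co-located while moving apart: if both are detected in the
    same session they are recorded as one 'multiple' observation.  A small
    fraction of records is flagged incomplete.
    """
    _, rng, _ = _spawn(params.seed, 3)
    records: list[CensusRecord] = []
    obs_serial = 0

    for date in truth.dates:
        pair_map = {a: b for a, b in truth.colocated.get(date, [])}
        for session in ("AM", "PM"):
            detected: dict[str, SimCluster] = {}
            for cluster in truth.clusters[date]:
                if rng.random() < params.census_detect_prob:
                    detected[cluster.key] = cluster
            consumed: set[str] = set()
            for key in sorted(detected):
                if key in consumed:
                    continue
                cluster = detected[key]
                partner = pair_map.get(key)
                merge_with = (
                    detected[partner]
                    if partner is not None and partner in detected
                    else None
                )
                if merge_with is not None:
                    members = cluster.members | merge_with.members
                    cohesion = "multiple"
                    consumed.add(partner)
                else:
                    members = cluster.members
                    cohesion = "single"
                identified = set()
                n_unmarked = 0
                for ind in sorted(members):
                    if ind not in truth.marked:
                        n_unmarked += 1
                    elif rng.random() >= params.individual_miss_prob:
                        identified.add(ind)
                if not identified:
                    continue
                complete = rng.random() >= params.census_incomplete_prob
                records.append(
                    CensusRecord(
                        date=date,
                        session=session,
                        observation_id=f"OBS{obs_serial:06d}",
                        cohesion=cohesion,
                        individual_ids=frozenset(identified),
                        n_unmarked=n_unmarked,
                        complete=complete,
                    )
                )
                obs_serial += 1
    return records


def _reflect(values: np.ndarray, low: float, high: float) -> np.ndarray:
    """Fold values into [low, high] by reflection at the boundaries."""
    if high <= low:
        return np.full_like(values, low)
    span = high - low
    folded = np.mod(values - low, 2 * span)
    folded = np.where(folded > span, 2 * span - folded, folded)
    return folded + low


def simulate_gps(truth: SyntheticTruth, params: SocietyParams) -> pd.DataFrame:
    """Generate gridded GPS fixes for the tagged males.

    Each cluster follows a reflected random walk inside its unit's square
    home range (side ``home_range_scale``, centres ``unit_spacing`` apart on
    a grid); every tagged member's fix is the cluster centroid plus isotropic
    Gaussian scatter of scale ``within_unit_spread``.  Fixes cover daylight
    hours at one per ``gps_interval`` seconds, aligned to the UTC epoch grid.
    """
    _, _, rng = _spawn(params.seed, 3)
    unit_ids = sorted({truth.unit_of[i] for i in truth.individuals})
    n_side = int(np.ceil(np.sqrt(len(unit_ids))))
    centres = {
        u: np.array(
            [(k % n_side) * params.unit_spacing, (k // n_side) * params.unit_spacing]
        )
        for k, u in enumerate(unit_ids)
    }
    tagged = set(truth.tagged)
    positions: dict[str, np.ndarray] = {}

    day_offsets = np.arange(
        GPS_DAY_START_HOUR * 3600, GPS_DAY_END_HOUR * 3600, params.gps_interval
    )
    n_fix = len(day_offsets)
    ids_out: list[str] = []
    times_out: list[np.ndarray] = []
    east_out: list[np.ndarray] = []
    north_out: list[np.ndarray] = []

    for date in truth.dates:
        day_epoch = int(
            dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc).timestamp()
        )
        epochs = day_epoch + day_offsets
        for cluster in sorted(truth.clusters[date], key=lambda c: c.key):
            members = sorted(m for m in cluster.members if m in tagged)
            home = centres[cluster.units[0]]
            if cluster.key not in positions:
                # subunits depart from their unit's current main cluster
                parent = cluster.units[0]
                positions[cluster.key] = positions.get(parent, home).copy()
            if not members:
                continue
            start = positions[cluster.key]
            steps = rng.normal(0.0, CENTROID_STEP_SD, size=(n_fix, 2))
            path = start + np.cumsum(steps, axis=0)
            half = params.home_range_scale / 2.0
            path[:, 0] = _reflect(path[:, 0], home[0] - half, home[0] + half)
            path[:, 1] = _reflect(path[:, 1], home[1] - half, home[1] + half)
            positions[cluster.key] = path[-1].copy()
            for ind in members:
                scatter = (
                    rng.normal(0.0, params.within_unit_spread, size=(n_fix, 2))
                    if params.within_unit_spread > 0
                    else np.zeros((n_fix, 2))
                )
                coords = path + scatter
                ids_out.append(ind)
                times_out.append(epochs)
                east_out.append(coords[:, 0])
                north_out.append(coords[:, 1])

    if not ids_out:
        return pd.DataFrame(
            {
                "individual_id": pd.Series(dtype=str),
                "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
                "easting_m": pd.Series(dtype=float),
                "northing_m": pd.Series(dtype=float),
            }
        )
    frame = pd.DataFrame(
        {
            "individual_id": np.repeat(ids_out, n_fix),
            "timestamp": pd.to_datetime(np.concatenate(times_out), unit="s", utc=True),
            "easting_m": np.concatenate(east_out),
            "northing_m": np.concatenate(north_out),
        }
    )
    return frame.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(
        drop=True
    )


def simulate_society(
    params: SocietyParams,
) -> tuple[SyntheticTruth, list[CensusRecord], pd.DataFrame]:
    """Convenience wrapper: membership, census and GPS in one call."""
    truth = simulate_membership(params)
    return truth, simulate_census(truth, params), simulate_gps(truth, params)


def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Daily latent membership as a tidy frame (date, individual_id,
    true_unit_id)."""
    rows = [
        {"date": date.isoformat(), "individual_id": ind, "true_unit_id": unit}
        for (date, ind), unit in sorted(truth.daily_membership.items())
    ]
    return pd.DataFrame(rows, columns=["date", "individual_id", "true_unit_id"])


def events_frame(truth: SyntheticTruth) -> pd.DataFrame:
    rows = [
        {"date": ev.date.isoformat(), "kind": ev.kind, "units": ";".join(ev.units)}
        for ev in truth.event_log
    ]
    return pd.DataFrame(rows, columns=["date", "kind", "units"])
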