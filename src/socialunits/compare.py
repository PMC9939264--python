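"""Running the approach grid and collecting tidy comparison tables.

An *approach* is one combination of window basis (1-month, 2-month or
8-month), bootstrapping (yes/no) and carryover membership tracking (yes/no;
not applicable to the single-window 8-month basis) — ten combinations in all.
Each approach is run end to end: windows are built, units detected per
window, identities optionally linked and interpolated across windows, and
stability and GPS cohesion summarised.  The exports are long-format tables
ready for model fitting in any statistics environment.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import pandas as pd

from .census import (
    ApproachConfig,
    CensusRecord,
    FocalWindow,
    filter_census,
    make_windows,
)
from .cohesion import CohesionSummary, daily_pairwise_distances, subsample_fixes, _as_frame
from .detect import CommunityPartition, detect_units
from .dynamics import (
    DynamicMembership,
    StabilityRecord,
    interpolate_missing,
    jaccard_stability,
    link_communities,
)

__all__ = [
    "ApproachResult",
    "ComparisonTables",
    "run_approach",
    "compare_approaches",
    "approach_grid",
]


@dataclass
class ApproachResult:
    """Everything one approach inferred from a dataset."""

    config: ApproachConfig
    windows: list[FocalWindow]
    partitions: list[CommunityPartition]
    dynamic: DynamicMembership | None
    stability: list[StabilityRecord] | None
    cohesion: list[CohesionSummary]
    unit_count: int
    individuals_included: int
    size_distribution: list[int]


@dataclass
class ComparisonTables:
    """Long per-unit table plus an approach-level roll-up."""

    units: pd.DataFrame
    approaches: pd.DataFrame


def _window_assignments(
    result_partitions: list[CommunityPartition],
    dynamic: DynamicMembership | None,
) -> list[CommunityPartition]:
    """Per-window partitions labelled with global unit ids when linked."""
    if dynamic is None:
        return result_partitions
    out = []
    for part in result_partitions:
        assignment = {
            ind: gid
            for (wid, ind), gid in dynamic.per_window.items()
            if wid == part.window_id
        }
        out.append(CommunityPartition(part.window_id, assignment, part.method_tag))
    return out


def run_approach(
    census: list[CensusRecord],
    gps,
    config: ApproachConfig,
    study_start: dt.date | None = None,
    study_end: dt.date | None = None,
    gps_ids: set[str] | None = None,
    gps_interval: int = 300,
) -> ApproachResult:
    """Run one approach end to end.

    ``census`` may be raw (the cohesion/completeness filter is applied
    here); ``gps`` is any fix collection accepted by the cohesion module and
    is subsampled to ``gps_interval``.  The study interval defaults to the
    calendar months spanned by the census data.  ``gps_ids`` restricts
    cohesion to a tagged subset (e.g. philopatric males); by default all
    individuals present in the GPS data are used.
    """
    filtered = filter_census(census)
    if not filtered:
        raise ValueError("no usable census records after filtering")
    if study_start is None:
        study_start = min(r.date for r in filtered).replace(day=1)
    if study_end is None:
        last = max(r.date for r in filtered)
        study_end = (last.replace(day=1) + dt.timedelta(days=32)).replace(day=1)

    windows = make_windows(study_start, study_end, config.basis)
    partitions = [detect_units(filtered, w, config) for w in windows]

    dynamic: DynamicMembership | None = None
    stability: list[StabilityRecord] | None = None
    if config.carryover:
        if len(partitions) >= 2:
            dynamic = link_communities(partitions)
            dynamic = interpolate_missing(dynamic, partitions)
        else:  # a single window: every community is its own global unit
            part = partitions[0]
            gids = {label: f"G{k:03d}" for k, label in enumerate(sorted(part.communities()))}
            dynamic = DynamicMembership(
                [part.window_id],
                {
                    (part.window_id, ind): gids[label]
                    for ind, label in part.assignment.items()
                },
                [],
            )
        stability = jaccard_stability(dynamic)

    fixes = subsample_fixes(_as_frame(gps), gps_interval) if gps is not None else None
    if gps_ids is None and fixes is not None:
        gps_ids = set(fixes["individual_id"].unique())

    cohesion: list[CohesionSummary] = []
    labelled = _window_assignments(partitions, dynamic)
    if fixes is not None and len(fixes):
        for window, part in zip(windows, labelled):
            mask = (fixes["timestamp"].dt.date >= window.focal_start) & (
                fixes["timestamp"].dt.date < window.focal_end
            )
            window_fixes = fixes[mask]
            if window_fixes.empty:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cohesion.extend(
                    daily_pairwise_distances(window_fixes, part, gps_ids or set())
                )

    if config.carryover and dynamic is not None:
        unit_count = len(dynamic.global_units)
        sizes = [
            len(members)
            for part in labelled
            for members in part.communities().values()
        ]
    else:
        unit_count = sum(len(p.communities()) for p in partitions)
        sizes = [
            len(members) for p in partitions for members in p.communities().values()
        ]
    individuals = {ind for p in partitions for ind in p.assignment}

    return ApproachResult(
        config=config,
        windows=windows,
        partitions=partitions,
        dynamic=dynamic,
        stability=stability,
        cohesion=cohesion,
        unit_count=unit_count,
        individuals_included=len(individuals),
        size_distribution=sorted(sizes),
    )


def compare_approaches(results: list[ApproachResult]) -> ComparisonTables:
    """Collect per-unit rows and an approach-level roll-up.

    The per-unit table has one row per (approach, window, unit) with its
    size, its Jaccard similarity to the next window (carryover approaches
    only) and its mean/max daily GPS distance where computed.  The roll-up
    reports unit counts, individuals included and size quartiles.
    """
    if not results:
        raise ValueError("compare_approaches requires at least one result")
    unit_rows = []
    approach_rows = []
    for res in results:
        label = res.config.label
        stab = {
            (r.window_t, r.global_unit): r.jaccard for r in (res.stability or [])
        }
        coh = {(c.window_id, c.unit): c for c in res.cohesion}
        labelled = _window_assignments(res.partitions, res.dynamic)
        for part in labelled:
            for unit, members in sorted(part.communities().items()):
                c = coh.get((part.window_id, unit))
                unit_rows.append(
                    {
                        "approach": label,
                        "window_id": part.window_id,
                        "unit_id": unit,
                        "size": len(members),
                        "jaccard_next": stab.get((part.window_id, unit)),
                        "mean_daily_distance_m": c.mean_daily_distance if c else None,
                        "max_daily_distance_m": c.max_daily_distance if c else None,
                    }
                )
        sizes = pd.Series(res.size_distribution, dtype=float)
        jac = pd.Series([r.jaccard for r in (res.stability or [])], dtype=float)
        dist = pd.Series(
            [c.mean_daily_distance for c in res.cohesion], dtype=float
        )
        approach_rows.append(
            {
                "approach": label,
                "basis": res.config.basis,
                "bootstrap": res.config.bootstrap,
                "carryover": res.config.carryover,
                "unit_count": res.unit_count,
                "individuals_included": res.individuals_included,
                "size_q25": sizes.quantile(0.25) if len(sizes) else None,
                "size_median": sizes.median() if len(sizes) else None,
                "size_q75": sizes.quantile(0.75) if len(sizes) else None,
                "mean_jaccard": jac.mean() if len(jac) else None,
                "mean_daily_distance_m": dist.mean() if len(dist) else None,
            }
        )
    return ComparisonTables(
        units=pd.DataFrame(unit_rows),
        approaches=pd.DataFrame(approach_rows),
    )


def approach_grid(
    n_boot: int = 100, seed: int = 0, **overrides
) -> list[ApproachConfig]:
    """The full ten-approach grid: {1,2}-month x bootstrap x carryover plus
    8-month x bootstrap."""
    configs = []
    for basis in ("1-month", "2-month"):
        for bootstrap in (True, False):
            for carryover in (False, True):
                configs.append(
                    ApproachConfig(
                        basis=basis,
                        bootstrap=bootstrap,
                        carryover=carryover,
                        n_boot=n_boot,
                        seed=seed,
                        **overrides,
                    )
                )
    for bootstrap in (True, False):
        configs.append(
            ApproachConfig(
                basis="8-month",
                bootstrap=bootstrap,
                carryover=False,
                n_boot=n_boot,
                seed=seed,
                **overrides,
            )
        )
    return configs
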