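"""Linking communities across windows into persistent social-unit identities.

Per-window community labels are arbitrary; to follow a unit through time the
communities of consecutive windows are matched by membership overlap.  A
community at window t+1 *continues* the global identity of the community at
window t with which it shares the most members, provided the overlap is a
mutual majority (strictly more than half of both communities).  Several
sources pouring their majorities into one target record a *merge*; one source
making up the majority of several targets records a *split*; merge and split
products, and unmatched communities, start fresh global identities
(*birth* / *death*).

Individuals missing from a single window but assigned to the same global unit
in the windows on either side are re-added by interpolation, and the temporal
stability of each unit is summarised by the Jaccard similarity of its member
sets in consecutive windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .detect import CommunityPartition

__all__ = [
    "LineageEvent",
    "DynamicMembership",
    "StabilityRecord",
    "link_communities",
    "interpolate_missing",
    "jaccard_stability",
    "membership_frame",
    "lineage_frame",
    "stability_frame",
]


@dataclass(frozen=True)
class LineageEvent:
    """One relation between communities of two consecutive windows."""

    from_window: str
    to_window: str
    relation: str  # continue | merge | split | birth | death
    source_units: tuple[str, ...]
    target_units: tuple[str, ...]


@dataclass
class DynamicMembership:
    """Global unit identities across an ordered sequence of windows."""

    window_ids: list[str]
    per_window: dict[tuple[str, str], str]  # (window_id, individual) -> global unit
    lineage: list[LineageEvent]
    interpolated: set[tuple[str, str]] = field(default_factory=set)

    @property
    def global_units(self) -> set[str]:
        return set(self.per_window.values())

    def members(self, window_id: str, unit: str) -> set[str]:
        return {
            ind
            for (wid, ind), gid in self.per_window.items()
            if wid == window_id and gid == unit
        }

    def units_in_window(self, window_id: str) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for (wid, ind), gid in self.per_window.items():
            if wid == window_id:
                out.setdefault(gid, set()).add(ind)
        return out


@dataclass(frozen=True)
class StabilityRecord:
    """Jaccard similarity of one unit's member sets in consecutive windows."""

    global_unit: str
    window_t: str
    window_t1: str
    jaccard: float


def _mutual_majority(overlap: int, size_a: int, size_b: int) -> bool:
    return 2 * overlap > size_a and 2 * overlap > size_b


def link_communities(partitions: list[CommunityPartition]) -> DynamicMembership:
    """Link per-window communities into global unit identities.

    ``partitions`` must be ordered by window.  Ties in the largest-overlap
    choice break toward the larger source community, then the
    lexicographically smaller source label.
    """
    if len(partitions) < 2:
        raise ValueError("linking requires at least 2 ordered partitions")

    window_ids = [p.window_id for p in partitions]
    per_window: dict[tuple[str, str], str] = {}
    lineage: list[LineageEvent] = []

    counter = 0

    def new_gid() -> str:
        nonlocal counter
        gid = f"G{counter:03d}"
        counter += 1
        return gid

    prev_comms = partitions[0].communities()
    prev_gids = {label: new_gid() for label in sorted(prev_comms)}
    for label, members in prev_comms.items():
        for ind in members:
            per_window[(window_ids[0], ind)] = prev_gids[label]

    for t in range(1, len(partitions)):
        curr_comms = partitions[t].communities()
        curr_gids: dict[str, str] = {}
        matched_sources: set[str] = set()
        matched_targets: set[str] = set()

        # continuation: mutual-majority best overlap
        for tgt in sorted(curr_comms):
            tgt_members = curr_comms[tgt]
            best_src, best_key = None, None
            for src in sorted(prev_comms):
                overlap = len(prev_comms[src] & tgt_members)
                if overlap == 0:
                    continue
                key = (overlap, len(prev_comms[src]), [-ord(c) for c in src])
                if best_key is None or key > best_key:
                    best_src, best_key = src, key
            if best_src is None:
                continue
            overlap = len(prev_comms[best_src] & tgt_members)
            if _mutual_majority(overlap, len(prev_comms[best_src]), len(tgt_members)):
                curr_gids[tgt] = prev_gids[best_src]
                matched_sources.add(best_src)
                matched_targets.add(tgt)
                lineage.append(
                    LineageEvent(
                        window_ids[t - 1],
                        window_ids[t],
                        "continue",
                        (prev_gids[best_src],),
                        (prev_gids[best_src],),
                    )
                )

        in_split_or_merge: set[str] = set()
        dead_sources = set(prev_comms) - matched_sources

        # merges: several sources send their majorities into one target
        for tgt in sorted(set(curr_comms) - matched_targets):
            sources = [
                src
                for src in sorted(dead_sources)
                if 2 * len(prev_comms[src] & curr_comms[tgt]) > len(prev_comms[src])
            ]
            if len(sources) >= 2:
                gid = new_gid()
                curr_gids[tgt] = gid
                in_split_or_merge.add(tgt)
                lineage.append(
                    LineageEvent(
                        window_ids[t - 1],
                        window_ids[t],
                        "merge",
                        tuple(prev_gids[s] for s in sources),
                        (gid,),
                    )
                )
                dead_sources -= set(sources)

        # splits: one source makes up the majority of several targets
        for src in sorted(dead_sources):
            targets = [
                tgt
                for tgt in sorted(set(curr_comms) - matched_targets)
                if tgt not in in_split_or_merge
                and 2 * len(prev_comms[src] & curr_comms[tgt]) > len(curr_comms[tgt])
            ]
            if len(targets) >= 2:
                gids = []
                for tgt in targets:
                    gid = new_gid()
                    curr_gids[tgt] = gid
                    in_split_or_merge.add(tgt)
                    gids.append(gid)
                lineage.append(
                    LineageEvent(
                        window_ids[t - 1],
                        window_ids[t],
                        "split",
                        (prev_gids[src],),
                        tuple(gids),
                    )
                )
                dead_sources.discard(src)

        # births and deaths
        for tgt in sorted(set(curr_comms) - set(curr_gids)):
            gid = new_gid()
            curr_gids[tgt] = gid
            lineage.append(
                LineageEvent(window_ids[t - 1], window_ids[t], "birth", (), (gid,))
            )
        for src in sorted(dead_sources):
            lineage.append(
                LineageEvent(
                    window_ids[t - 1], window_ids[t], "death", (prev_gids[src],), ()
                )
            )

        for label, members in curr_comms.items():
            for ind in members:
                per_window[(window_ids[t], ind)] = curr_gids[label]
        prev_comms, prev_gids = curr_comms, curr_gids

    return DynamicMembership(window_ids, per_window, lineage)


def interpolate_missing(
    dyn: DynamicMembership, partitions: list[CommunityPartition]
) -> DynamicMembership:
    """Re-add individuals missing from a single interior window.

    An individual absent from window t but assigned to the same global unit
    at both t-1 and t+1 is re-added to that unit at t and flagged as
    interpolated.  Longer gaps are treated as genuine absence.  Existing
    assignments are never changed; applying the operation twice equals
    applying it once.
    """
    per_window = dict(dyn.per_window)
    interpolated = set(dyn.interpolated)
    wids = dyn.window_ids
    for t in range(1, len(wids) - 1):
        present_t = {ind for (wid, ind) in dyn.per_window if wid == wids[t]}
        before = {
            ind: gid for (wid, ind), gid in dyn.per_window.items() if wid == wids[t - 1]
        }
        after = {
            ind: gid for (wid, ind), gid in dyn.per_window.items() if wid == wids[t + 1]
        }
        for ind, gid in before.items():
            if ind in present_t:
                continue
            if after.get(ind) == gid:
                per_window[(wids[t], ind)] = gid
                interpolated.add((wids[t], ind))
    return DynamicMembership(list(wids), per_window, list(dyn.lineage), interpolated)


def jaccard_stability(dyn: DynamicMembership) -> list[StabilityRecord]:
    """Jaccard similarity of member sets for units present in consecutive
    windows.

    J = |members_t intersection members_t+1| / |members_t union members_t+1|;
    interpolated members count as present.  Units absent from either window of
    a pair yield no record.
    """
    records: list[StabilityRecord] = []
    for t in range(len(dyn.window_ids) - 1):
        wid_t, wid_t1 = dyn.window_ids[t], dyn.window_ids[t + 1]
        units_t = dyn.units_in_window(wid_t)
        units_t1 = dyn.units_in_window(wid_t1)
        for gid in sorted(set(units_t) & set(units_t1)):
            inter = len(units_t[gid] & units_t1[gid])
            union = len(units_t[gid] | units_t1[gid])
            records.append(StabilityRecord(gid, wid_t, wid_t1, inter / union))
    return records


# ---------------------------------------------------------------------------
# Tidy exports


def membership_frame(
    dyn: DynamicMembership, partitions: list[CommunityPartition]
) -> pd.DataFrame:
    """Long table: window_id, individual_id, community_id, global_unit_id,
    interpolated."""
    local = {
        (p.window_id, ind): label
        for p in partitions
        for ind, label in p.assignment.items()
    }
    rows = [
        {
            "window_id": wid,
            "individual_id": ind,
            "community_id": local.get((wid, ind), ""),
            "global_unit_id": gid,
            "interpolated": int((wid, ind) in dyn.interpolated),
        }
        for (wid, ind), gid in sorted(dyn.per_window.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "window_id",
            "individual_id",
            "community_id",
            "global_unit_id",
            "interpolated",
        ],
    )


def lineage_frame(dyn: DynamicMembership) -> pd.DataFrame:
    rows = [
        {
            "from_window": ev.from_window,
            "to_window": ev.to_window,
            "relation": ev.relation,
            "source_units": ";".join(ev.source_units),
            "target_units": ";".join(ev.target_units),
        }
        for ev in dyn.lineage
    ]
    return pd.DataFrame(
        rows,
        columns=["from_window", "to_window", "relation", "source_units", "target_units"],
    )


def stability_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    rows = [
        {
            "global_unit_id": r.global_unit,
            "window_t": r.window_t,
            "window_t1": r.window_t1,
            "jaccard": r.jaccard,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["global_unit_id", "window_t", "window_t1", "jaccard"]
    )
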