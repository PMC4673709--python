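"""Convergent CNVs: interval-overlap clustering across populations.

Independent populations repeatedly duplicated or deleted the same
genomic regions.  This module finds those parallel events by interval
overlap among same-chromosome, same-type calls and reports each
cluster's maximal shared region ``[max of member starts, min of member
ends]`` with inclusive length — the arithmetic that reproduces the
printed shared-region sizes exactly.

Two clustering modes:

``common-intersection``
    maximal sets of calls whose common intersection is non-empty (for
    intervals these are exactly the maximal cliques of the overlap
    graph, i.e. point-covering sets);
``connected``
    connected components of the pairwise-overlap graph (members need
    not all share one point).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .catalog import CnvCall

__all__ = ["OverlapCluster", "overlap_clusters", "shared_region"]


@dataclass(frozen=True)
class OverlapCluster:
    """Same-chromosome, same-type calls that overlap one another."""

    calls: tuple[CnvCall, ...]
    chromosome: str
    kind: str
    shared_start: int | None
    shared_end: int | None

    @property
    def n_members(self) -> int:
        return len(self.calls)

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c.population for c in self.calls))

    @property
    def shared_length(self) -> int | None:
        if self.shared_start is None or self.shared_end is None:
            return None
        return self.shared_end - self.shared_start + 1


def shared_region(calls: Sequence[CnvCall] | OverlapCluster) -> tuple[int, int, int]:
    """Common intersection of calls: (start, end, inclusive length).

    ``start = max of member starts``, ``end = min of member ends``;
    raises ``ValueError`` when the intersection is empty.  A single call
    yields its own interval.
    """
    members = calls.calls if isinstance(calls, OverlapCluster) else tuple(calls)
    if not members:
        raise ValueError("cannot intersect an empty set of calls")
    start = max(c.start for c in members)
    end = min(c.end for c in members)
    if end < start:
        raise ValueError("calls have an empty common intersection")
    return start, end, end - start + 1


def _cluster(members: Sequence[CnvCall], chromosome: str, kind: str) -> OverlapCluster:
    try:
        start, end, _ = shared_region(members)
    except ValueError:
        start = end = None
    return OverlapCluster(
        calls=tuple(sorted(members, key=lambda c: (c.start, c.end, c.population))),
        chromosome=chromosome,
        kind=kind,
        shared_start=start,
        shared_end=end,
    )


def _intersection_clusters(members: list[CnvCall]) -> list[list[CnvCall]]:
    # For intervals, every maximal clique is the set of intervals covering
    # the minimum end coordinate of its members, so sweeping candidate
    # point-covering sets at each member's end and dropping subsets is exact.
    candidates = []
    for anchor in members:
        group = [c for c in members if c.start <= anchor.end <= c.end]
        candidates.append(group)
    unique: list[list[CnvCall]] = []
    seen: set[frozenset] = set()
    keyed = [frozenset(id(c) for c in group) for group in candidates]
    for group, key in zip(candidates, keyed):
        if key in seen:
            continue
        if any(key < other for other in keyed):
            continue
        seen.add(key)
        unique.append(group)
    return unique


def _connected_components(members: list[CnvCall]) -> list[list[CnvCall]]:
    members = sorted(members, key=lambda c: (c.start, c.end))
    components: list[list[CnvCall]] = []
    current: list[CnvCall] = []
    reach = None
    for call in members:
        if current and call.start <= reach:
            current.append(call)
            reach = max(reach, call.end)
        else:
            if current:
                components.append(current)
            current, reach = [call], call.end
    if current:
        components.append(current)
    return components


def overlap_clusters(
    calls: Iterable[CnvCall],
    kind: str | None = None,
    mode: str = "common-intersection",
    min_size: int = 2,
) -> list[OverlapCluster]:
    """Cluster same-chromosome, same-type calls by interval overlap.

    ``kind`` restricts to duplications or deletions (``None`` clusters
    each type separately; types are never mixed).  Clusters smaller than
    ``min_size`` are dropped, so two disjoint calls yield no cluster in
    the default mode.  Clusters are sorted by member count (largest
    first), then chromosome and shared start.
    """
    if mode not in ("common-intersection", "connected"):
        raise ValueError("mode must be 'common-intersection' or 'connected'")
    pool = [c for c in calls if kind is None or c.kind == kind]
    by_group: dict[tuple[str, str], list[CnvCall]] = {}
    for call in pool:
        by_group.setdefault((call.chromosome, call.kind), []).append(call)
    clusters = []
    for (chrom, cnv_kind), members in by_group.items():
        if mode == "common-intersection":
            groups = _intersection_clusters(members)
        else:
            groups = _connected_components(members)
        for group in groups:
            if len(group) >= min_size:
                clusters.append(_cluster(group, chrom, cnv_kind))
    clusters.sort(
        key=lambda cl: (-cl.n_members, cl.chromosome, cl.shared_start or 0)
    )
    return clusters
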