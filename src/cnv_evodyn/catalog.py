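"""CNV catalog records, span/feature arithmetic and breakpoint utilities.

Coordinates are 1-based inclusive throughout (WormBase style), so a
CNV's span is ``end - start + 1``; BED export converts to 0-based
half-open.  The average copy-number per haploid genome ``c`` converts
to a population frequency under a one-extra-copy model: ``q = c - 1``
for duplications and ``q = 1 - c`` for deletions, clipped to [0, 1]
(arrays occasionally report c slightly above 2 for fixed duplications).

The module also ships transcriptions of the study's printed CNV tables
(25 duplications, 25 deletions, and the single-worm PCR assay table) as
package data, plus utilities for repeat-mediated breakpoints: percent
identity of an aligned repeat pair and localization of the unequal
crossing-over point of a chimeric junction repeat between informative
sites.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .synthetic import BIOTYPES, GenomeModel

__all__ = [
    "CnvCall",
    "CatalogSummary",
    "RepeatPair",
    "AmbiguousBreakpointError",
    "span",
    "annotate",
    "frequency_from_copy",
    "summarize",
    "percent_identity",
    "infer_crossover_interval",
    "load_duplications",
    "load_deletions",
    "load_single_worm_table",
    "read_catalog_tsv",
    "write_catalog_tsv",
    "calls_from_frame",
    "calls_to_frame",
]

_DATA_SHA256 = {
    "table1_duplications.tsv": "7d5a50b7570a7517a877e40edc38ea424f2716bb8a00c61b9115cb6b0c3bebd1",
    "table2_deletions.tsv": "f2ddbc169b8d537fbb6ef65177659ab0683ae21ba2f5a39a42653ca36a2f0dc2",
    "table3_single_worm.tsv": "5fd61f87d879dcaba915b8df5a73a9350829b8f82950ae92400e68668a815e5e",
}


class AmbiguousBreakpointError(ValueError):
    """The chimera matches neither repeat at one or more informative sites."""

    def __init__(self, positions: Sequence[int]):
        self.positions = tuple(positions)
        super().__init__(
            f"chimera matches neither repeat at informative sites {self.positions}"
        )


@dataclass(frozen=True)
class CnvCall:
    """One duplication or deletion record in a population.

    ``feature_counts`` maps biotype to the number of overlapped
    features; ``None`` marks an unknown count.  ``copy_number`` is the
    population-average copies per haploid genome.
    """

    population: str
    chromosome: str
    start: int
    end: int
    kind: str  # "duplication" | "deletion"
    copy_number: float
    feature_counts: dict[str, int | None] = field(
        default_factory=lambda: {b: None for b in BIOTYPES}
    )
    breakpoint_resolved: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.kind not in ("duplication", "deletion"):
            raise ValueError(f"kind must be duplication or deletion, got {self.kind!r}")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        # a duplication with c < 1 is suspicious but not fatal; flag it
        if self.kind == "duplication" and self.copy_number < 1.0:
            if "copy_below_one" not in self.flags:
                object.__setattr__(self, "flags", self.flags + ("copy_below_one",))


def span(call: CnvCall) -> int:
    """Inclusive span in bp: ``end - start + 1``."""
    return call.end - call.start + 1


def annotate(call: CnvCall, genome: GenomeModel) -> dict[str, int]:
    """Count features overlapping the call by at least 1 bp, per biotype.

    Partial overlap counts (a gene partially deleted is still a deleted
    gene).  Raises ``KeyError`` for a chromosome absent from the genome.
    """
    if call.chromosome not in dict(genome.chromosomes):
        raise KeyError(f"unknown chromosome {call.chromosome!r}")
    tree = IntervalTree()
    for feat in genome.features:
        if feat.chromosome == call.chromosome:
            tree.addi(feat.start, feat.end + 1, feat.biotype)
    counts = {b: 0 for b in BIOTYPES}
    for hit in tree.overlap(call.start, call.end + 1):
        counts[hit.data] += 1
    return counts


def frequency_from_copy(call: CnvCall) -> float:
    """Population frequency implied by the average copy-number.

    Duplications: ``clip(c - 1, 0, 1)`` assuming carriers bear a single
    extra copy.  Deletions: ``clip(1 - c, 0, 1)``.
    """
    if call.kind == "duplication":
        q = call.copy_number - 1.0
    else:
        q = 1.0 - call.copy_number
    return float(np.clip(q, 0.0, 1.0))


@dataclass(frozen=True)
class CatalogSummary:
    """Summary statistics of a CNV catalog subset."""

    n_events: int
    n_populations: int
    span_median: float | None = None
    span_min: int | None = None
    span_max: int | None = None
    feature_stats: dict[str, tuple[float, int, int]] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_events == 0


def summarize(
    calls: Iterable[CnvCall], selector=None
) -> CatalogSummary:
    """Span and feature-content summary of a catalog subset.

    ``selector`` is an optional predicate over calls.  Medians average
    the two central order statistics for even counts.  Feature medians
    are computed per biotype over calls with a known count.  An empty
    subset returns the empty-summary sentinel (``summary.empty``).
    """
    subset = [c for c in calls if selector is None or selector(c)]
    if not subset:
        return CatalogSummary(n_events=0, n_populations=0)
    spans = np.array([span(c) for c in subset])
    feature_stats = {}
    for biotype in BIOTYPES:
        known = [
            c.feature_counts[biotype]
            for c in subset
            if c.feature_counts.get(biotype) is not None
        ]
        if known:
            arr = np.array(known)
            feature_stats[biotype] = (
                float(np.median(arr)),
                int(arr.min()),
                int(arr.max()),
            )
    return CatalogSummary(
        n_events=len(subset),
        n_populations=len({c.population for c in subset}),
        span_median=float(np.median(spans)),
        span_min=int(spans.min()),
        span_max=int(spans.max()),
        feature_stats=feature_stats,
    )


@dataclass(frozen=True)
class RepeatPair:
    """Two aligned homologous repeats flanking a CNV.

    ``informative_sites`` are the 1-based alignment positions at which
    the repeats differ — the positions that can localize an unequal
    crossing-over point.
    """

    upstream: str
    downstream: str

    def __post_init__(self) -> None:
        if not self.upstream or not self.downstream:
            raise ValueError("repeat sequences must be non-empty")
        if len(self.upstream) != len(self.downstream):
            raise ValueError("repeats must be equal length after alignment")

    @property
    def informative_sites(self) -> tuple[int, ...]:
        return tuple(
            i + 1
            for i, (a, b) in enumerate(zip(self.upstream, self.downstream))
            if a != b
        )


def percent_identity(pair: RepeatPair) -> float:
    """Percent of aligned positions at which the two repeats agree."""
    matches = sum(a == b for a, b in zip(pair.upstream, pair.downstream))
    return 100.0 * matches / len(pair.upstream)


def infer_crossover_interval(
    pair: RepeatPair, chimera: str
) -> tuple[int, int]:
    """Localize the unequal crossing-over point of a junction repeat.

    The chimeric repeat at the centre of a tandem duplication begins as
    a copy of the downstream repeat and ends as a copy of the upstream
    repeat.  The crossover must lie in the open interval between the
    last informative site matching the downstream repeat and the first
    subsequent informative site matching the upstream repeat.  Distinct
    chimeras whose intervals fall in different inter-site gaps arose
    from independent events.

    Returns the open interval ``(left, right)`` of 1-based alignment
    positions; ``left = 0`` when the chimera is upstream-type
    throughout, ``right = len + 1`` when downstream-type throughout.
    """
    if len(chimera) != len(pair.upstream):
        raise ValueError("chimera must align end-to-end with the repeat pair")
    sites = pair.informative_sites
    if not sites:
        raise ValueError("repeats are identical; no informative sites")
    states = []
    unmatched = []
    for pos in sites:
        base = chimera[pos - 1]
        if base == pair.downstream[pos - 1]:
            states.append("D")
        elif base == pair.upstream[pos - 1]:
            states.append("U")
        else:
            unmatched.append(pos)
    if unmatched:
        raise AmbiguousBreakpointError(unmatched)
    first_u = next((i for i, s in enumerate(states) if s == "U"), len(states))
    if any(s == "D" for s in states[first_u:]):
        raise ValueError(
            "chimera switches between repeats more than once; "
            "not a simple unequal crossing-over product"
        )
    left = sites[first_u - 1] if first_u > 0 else 0
    right = sites[first_u] if first_u < len(sites) else len(chimera) + 1
    return (left, right)


# ---------------------------------------------------------------------------
# packaged fixtures and catalog I/O

_CATALOG_COLUMNS = [
    "population",
    "chromosome",
    "start",
    "end",
    "type",
    "copy_number",
    *BIOTYPES,
    "breakpoint_resolved",
]


def _data_path(name: str):
    path = resources.files("cnv_evodyn") / "data" / name
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _DATA_SHA256[name]:
        raise RuntimeError(
            f"packaged fixture {name} is corrupted (sha256 {digest})"
        )
    return path


def _load_calls(name: str, kind: str) -> list[CnvCall]:
    with _data_path(name).open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    calls = []
    for row in table.itertuples():
        counts = {}
        for biotype in BIOTYPES:
            value = getattr(row, biotype)
            counts[biotype] = None if pd.isna(value) else int(value)
        flags = []
        if int(row.coordinate_adjusted):
            flags.append("coordinate_adjusted")
        calls.append(
            CnvCall(
                population=str(row.population),
                chromosome=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                kind=kind,
                copy_number=float(row.copy_number),
                feature_counts=counts,
                breakpoint_resolved=bool(int(row.breakpoint_resolved)),
                flags=tuple(flags),
            )
        )
    return calls


def load_duplications() -> list[CnvCall]:
    """The 25 printed duplication records (24 recovery populations + C2)."""
    return _load_calls("table1_duplications.tsv", "duplication")


def load_deletions() -> list[CnvCall]:
    """The 25 printed deletion records (18 recovery + 7 control)."""
    return _load_calls("table2_deletions.tsv", "deletion")


def load_printed_spans(kind: str) -> pd.DataFrame:
    """Printed span column alongside coordinates, for span verification."""
    name = (
        "table1_duplications.tsv" if kind == "duplication" else "table2_deletions.tsv"
    )
    with _data_path(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_single_worm_table() -> pd.DataFrame:
    """The printed single-worm PCR assay table, with consistency flags."""
    with _data_path("table3_single_worm.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def calls_to_frame(calls: Sequence[CnvCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "population": c.population,
            "chromosome": c.chromosome,
            "start": c.start,
            "end": c.end,
            "type": c.kind,
            "copy_number": c.copy_number,
            "breakpoint_resolved": int(c.breakpoint_resolved),
        }
        for biotype in BIOTYPES:
            row[biotype] = c.feature_counts.get(biotype)
        rows.append(row)
    return pd.DataFrame(rows, columns=_CATALOG_COLUMNS)


def calls_from_frame(frame: pd.DataFrame) -> list[CnvCall]:
    calls = []
    for row in frame.itertuples():
        counts = {}
        for biotype in BIOTYPES:
            value = getattr(row, biotype, None)
            counts[biotype] = None if value is None or pd.isna(value) else int(value)
        calls.append(
            CnvCall(
                population=str(row.population),
                chromosome=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                kind=str(row.type),
                copy_number=float(row.copy_number),
                feature_counts=counts,
                breakpoint_resolved=bool(
                    int(getattr(row, "breakpoint_resolved", 0) or 0)
                ),
            )
        )
    return calls


def read_catalog_tsv(path) -> list[CnvCall]:
    return calls_from_frame(pd.read_csv(path, sep="\t", comment="#"))


def write_catalog_tsv(calls: Sequence[CnvCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
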