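"""aCGH analysis: quantile normalization, bottom-up segmentation, CNV calls.

The segmentation is agglomerative: every probe starts as its own
segment, and the most similar pair of adjacent segments — the pair with
the largest Welch t-test p-value — is merged repeatedly until no
adjacent pair reaches the merge threshold ``p_merge``.  Surviving
segments are labeled amplified or deleted when they pass both a mean
filter (|mean log2 ratio| >= ``m_min``) and a one-sample t-test filter
(p <= ``p_class`` against 0), with a minimum probe count.  Calls carry
an inner interval (first to last internal probe) and an outer interval
extending to the adjacent flanking probes, between which the true
breakpoint must lie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ProbeProfile

__all__ = [
    "SegmentationParams",
    "Segment",
    "CghCall",
    "quantile_normalize",
    "segment",
    "classify",
    "to_calls",
    "calls_to_frame",
    "write_calls_tsv",
    "write_calls_bed",
]


@dataclass(frozen=True)
class SegmentationParams:
    """User-defined thresholds of the segmentation and classification."""

    p_merge: float = 1e-3
    m_min: float = 0.2
    p_class: float = 1e-3
    min_probes: int = 3

    def __post_init__(self) -> None:
        for name in ("p_merge", "p_class"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.m_min <= 0:
            raise ValueError("m_min must be positive")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass(frozen=True)
class Segment:
    """A run of adjacent probes with homogeneous log2 ratio."""

    chromosome: str
    start_index: int  # first probe index within the chromosome, inclusive
    end_index: int  # last probe index, inclusive
    n_probes: int
    mean: float
    variance: float  # unbiased; 0.0 for singleton segments
    label: str = "neutral"  # "neutral" | "amplified" | "deleted"


@dataclass(frozen=True)
class CghCall:
    """One CNV called from a classified segment."""

    chromosome: str
    inner_start: int
    inner_end: int
    outer_start: int
    outer_end: int
    kind: str  # "duplication" | "deletion"
    mean_log2: float
    copy_per_haploid: float
    frequency: float
    n_probes: int

    @property
    def span(self) -> int:
        """Minimum CNV span: the inner (probe-supported) length."""
        return self.inner_end - self.inner_start + 1


def quantile_normalize(profiles: Sequence[ProbeProfile]) -> list[ProbeProfile]:
    """Quantile-normalize log2 ratios across arrays.

    Each profile's sorted values are replaced by the across-profile mean
    order statistics; rank ties within a profile receive the average of
    the corresponding reference values.  A single profile is returned
    unchanged (normalizing one array against itself is the identity).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    if len(profiles) == 1:
        return [profiles[0]]
    first = profiles[0]
    for other in profiles[1:]:
        if not first.same_grid(other):
            raise ValueError("profiles must share an identical probe set")
    matrix = np.column_stack([p.flat_values() for p in profiles])
    reference = np.sort(matrix, axis=0).mean(axis=1)
    out = []
    for j, profile in enumerate(profiles):
        col = matrix[:, j]
        # average ranks handle ties: interpolate the reference at the midrank
        ranks = stats.rankdata(col, method="average") - 1.0
        normalized = np.interp(ranks, np.arange(reference.size), reference)
        out.append(profile.with_flat_values(normalized))
    return out


def _robust_noise_sd(values: np.ndarray) -> float:
    """Probe-to-probe noise scale: 1.4826 * MAD of first differences / sqrt(2).

    Used as the variance stand-in for singleton segments, whose sample
    variance is undefined.
    """
    if values.size < 2:
        return 0.0
    diffs = np.diff(values)
    return 1.4826 * float(np.median(np.abs(diffs))) / np.sqrt(2.0)


def _adjacent_pair_pvalues(
    n: np.ndarray, mean: np.ndarray, m2: np.ndarray, sd0: float
) -> np.ndarray:
    """Welch two-sample p-values for every adjacent segment pair.

    ``m2`` is the sum of squared deviations.  Sample variances of short
    segments are unreliable (and undefined for singletons), so every
    segment variance is floored at the global robust noise variance
    ``sd0**2``; this only increases p-values, so any pair left unmerged
    is also non-mergeable under the raw Welch test.  Degenerate pairs
    (zero pooled standard error) get p = 1 when the means agree exactly
    and p = 0 otherwise.
    """
    n1, n2 = n[:-1], n[1:]
    v1 = np.maximum(np.where(n1 > 1, m2[:-1] / np.maximum(n1 - 1, 1), 0.0), sd0**2)
    v2 = np.maximum(np.where(n2 > 1, m2[1:] / np.maximum(n2 - 1, 1), 0.0), sd0**2)
    se2 = v1 / n1 + v2 / n2
    dmean = mean[:-1] - mean[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(dmean) / np.sqrt(se2)
        d1 = np.maximum(n1 - 1, 1)
        d2 = np.maximum(n2 - 1, 1)
        df_num = se2**2
        df_den = (v1 / n1) ** 2 / d1 + (v2 / n2) ** 2 / d2
        df = np.where(df_den > 0, df_num / np.maximum(df_den, 1e-300), 1.0)
        p = 2.0 * stats.t.sf(t, np.maximum(df, 1.0))
    degenerate = se2 == 0.0
    p = np.where(degenerate, np.where(dmean == 0.0, 1.0, 0.0), p)
    return p


def segment(profile: ProbeProfile, params: SegmentationParams) -> list[Segment]:
    """Bottom-up agglomerative segmentation of one profile.

    Returns segments partitioning every chromosome in genomic order.
    Chromosomes without probes are skipped with a warning.
    """
    segments: list[Segment] = []
    for chrom in profile.chromosomes:
        values = profile.ratios(chrom)
        if values.size == 0:
            warnings.warn(f"chromosome {chrom} has no probes; skipped", stacklevel=2)
            continue
        segments.extend(_segment_chromosome(chrom, values, params))
    return segments


def _segment_chromosome(
    chrom: str, values: np.ndarray, params: SegmentationParams
) -> list[Segment]:
    sd0 = _robust_noise_sd(values)
    # per-segment running stats: probe count, mean, sum of squared deviations
    n = np.ones(values.size, dtype=np.int64)
    mean = values.astype(np.float64).copy()
    m2 = np.zeros(values.size)
    starts = np.arange(values.size)
    ends = np.arange(values.size)
    if n.size > 1:
        p = _adjacent_pair_pvalues(n, mean, m2, sd0)

    while n.size > 1:
        best = int(np.argmax(p))  # leftmost maximum: deterministic tie-break
        if p[best] < params.p_merge:
            break
        # merge segments best and best+1 (Chan parallel-variance update)
        na, nb = n[best], n[best + 1]
        delta = mean[best + 1] - mean[best]
        n_new = na + nb
        mean_new = mean[best] + delta * nb / n_new
        m2_new = m2[best] + m2[best + 1] + delta**2 * na * nb / n_new
        n[best], mean[best], m2[best] = n_new, mean_new, m2_new
        ends[best] = ends[best + 1]
        keep = np.arange(n.size) != best + 1
        n, mean, m2 = n[keep], mean[keep], m2[keep]
        starts, ends = starts[keep], ends[keep]
        # only the two pairs flanking the merged segment changed
        p = np.delete(p, best)
        for j in (best - 1, best):
            if 0 <= j < p.size:
                p[j] = _adjacent_pair_pvalues(
                    n[j : j + 2], mean[j : j + 2], m2[j : j + 2], sd0
                )[0]

    return [
        Segment(
            chromosome=chrom,
            start_index=int(starts[i]),
            end_index=int(ends[i]),
            n_probes=int(n[i]),
            mean=float(mean[i]),
            variance=float(m2[i] / (n[i] - 1)) if n[i] > 1 else 0.0,
        )
        for i in range(n.size)
    ]


def classify(
    segments: Sequence[Segment],
    profile: ProbeProfile,
    params: SegmentationParams,
) -> list[Segment]:
    """Label segments amplified/deleted via the mean and p-value filters.

    A segment is amplified when its mean log2 ratio is >= ``m_min``, a
    one-sample t-test against 0 gives p <= ``p_class`` and it has at
    least ``min_probes`` probes; deleted is symmetric with mean <=
    ``-m_min``; everything else is neutral.
    """
    labeled = []
    for seg in segments:
        label = "neutral"
        if seg.n_probes >= params.min_probes and abs(seg.mean) >= params.m_min:
            values = profile.ratios(seg.chromosome)[
                seg.start_index : seg.end_index + 1
            ]
            if seg.variance == 0.0:
                p = 0.0 if seg.mean != 0.0 else 1.0
            else:
                p = float(stats.ttest_1samp(values, 0.0).pvalue)
            if p <= params.p_class:
                label = "amplified" if seg.mean > 0 else "deleted"
        labeled.append(replace(seg, label=label))
    return labeled


def to_calls(
    segments: Sequence[Segment],
    profile: ProbeProfile,
    chromosome_lengths: dict[str, int] | None = None,
) -> list[CghCall]:
    """Convert amplified/deleted segments to CNV calls.

    The inner interval runs from the first to the last internal probe;
    the outer interval extends to (but excludes) the adjacent flanking
    probes, or to the chromosome ends when no flanking probe exists and
    ``chromosome_lengths`` supplies the bound.  The estimated
    copy-number per haploid is ``2**mean`` and the frequency follows the
    one-extra-copy model: ``c - 1`` for amplifications, ``1 - c`` for
    deletions, clipped to [0, 1].
    """
    calls = []
    for seg in segments:
        if seg.label == "neutral":
            continue
        pos = profile.positions(seg.chromosome)
        inner_start = int(pos[seg.start_index])
        inner_end = int(pos[seg.end_index])
        if seg.start_index > 0:
            outer_start = int(pos[seg.start_index - 1]) + 1
        else:
            outer_start = 1
        if seg.end_index < pos.size - 1:
            outer_end = int(pos[seg.end_index + 1]) - 1
        elif chromosome_lengths and seg.chromosome in chromosome_lengths:
            outer_end = int(chromosome_lengths[seg.chromosome])
        else:
            outer_end = inner_end
        c = float(2.0**seg.mean)
        if seg.label == "amplified":
            kind, freq = "duplication", float(np.clip(c - 1.0, 0.0, 1.0))
        else:
            kind, freq = "deletion", float(np.clip(1.0 - c, 0.0, 1.0))
        calls.append(
            CghCall(
                chromosome=seg.chromosome,
                inner_start=inner_start,
                inner_end=inner_end,
                outer_start=outer_start,
                outer_end=outer_end,
                kind=kind,
                mean_log2=seg.mean,
                copy_per_haploid=c,
                frequency=freq,
                n_probes=seg.n_probes,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[CghCall]) -> pd.DataFrame:
    cols = [
        "chromosome",
        "inner_start",
        "inner_end",
        "outer_start",
        "outer_end",
        "type",
        "mean_log2",
        "copy_per_haploid",
        "frequency",
        "n_probes",
    ]
    rows = [
        {
            "chromosome": c.chromosome,
            "inner_start": c.inner_start,
            "inner_end": c.inner_end,
            "outer_start": c.outer_start,
            "outer_end": c.outer_end,
            "type": c.kind,
            "mean_log2": c.mean_log2,
            "copy_per_haploid": c.copy_per_haploid,
            "frequency": c.frequency,
            "n_probes": c.n_probes,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=cols)


def write_calls_tsv(calls: Sequence[CghCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_calls_bed(calls: Sequence[CghCall], path) -> None:
    """BED6 of inner intervals (0-based half-open); score = 1000 * frequency."""
    with open(path, "w") as fh:
        for c in calls:
            score = int(round(1000 * c.frequency))
            fh.write(
                f"{c.chromosome}\t{c.inner_start - 1}\t{c.inner_end}\t"
                f"{c.kind}\t{score}\t.\n"
            )
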