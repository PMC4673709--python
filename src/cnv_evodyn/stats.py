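"""Comparative statistics for CNV catalogs.

The Wilcoxon two-sample rank-sum test (normal approximation with
midranks, tie-corrected variance and optional continuity correction) is
the test used to compare CNV span distributions between adapting and
mutation-accumulation populations; Pearson's r compares copy-number
estimates between assay methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

__all__ = ["RankTestResult", "wilcoxon_rank_sum", "pearson_r", "compare_spans"]


@dataclass(frozen=True)
class RankTestResult:
    """Rank-sum test of the first sample against the second."""

    z: float
    p_two_sided: float
    p_one_sided: float
    rank_sum: float
    n1: int
    n2: int
    tie_corrected: bool


def wilcoxon_rank_sum(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    continuity: bool = True,
) -> RankTestResult:
    """Two-sample Wilcoxon rank-sum test, normal approximation.

    Ties receive midranks and the variance of the rank-sum W is
    tie-corrected:

        Var[W] = n1 n2 / 12 * (N + 1 - sum(t^3 - t) / (N (N - 1)))

    where t runs over tie-group sizes.  Z is signed: negative when the
    first sample ranks low.  A continuity correction of 1/2 toward zero
    is applied by default.  All-identical pooled data raise
    ``ValueError`` (degenerate variance).
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = sstats.rankdata(pooled, method="average")
    w = float(ranks[:n1].sum())
    expect = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise ValueError("degenerate rank variance: pooled data are all identical")
    diff = w - expect
    cc = 0.5 if continuity and diff != 0 else 0.0
    z = (diff - math.copysign(cc, diff)) / math.sqrt(var)
    p_two = min(1.0, 2.0 * float(sstats.norm.sf(abs(z))))
    p_one = float(sstats.norm.sf(abs(z)))
    return RankTestResult(
        z=z,
        p_two_sided=p_two,
        p_one_sided=p_one,
        rank_sum=w,
        n1=n1,
        n2=n2,
        tie_corrected=bool(tie_counts.size < n),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; requires length >= 3 and variance > 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    return float(sstats.pearsonr(x, y).statistic)


def compare_spans(
    spans_a: Sequence[float], spans_b: Sequence[float]
) -> dict[str, float]:
    """Span-distribution comparison: medians and the rank-sum test."""
    result = wilcoxon_rank_sum(spans_a, spans_b)
    return {
        "n_a": len(spans_a),
        "n_b": len(spans_b),
        "median_a": float(np.median(np.asarray(spans_a, dtype=float))),
        "median_b": float(np.median(np.asarray(spans_b, dtype=float))),
        "z": result.z,
        "p_two_sided": result.p_two_sided,
        "p_one_sided": result.p_one_sided,
    }
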