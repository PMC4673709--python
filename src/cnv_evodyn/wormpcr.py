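"""CNV frequency estimation from single-worm PCR presence/absence counts.

Only adult males are assayed (outcrossing females carry nonclonal
eggs).  For X-linked loci males are hemizygous, so the positive
fraction is a direct estimate of the rearrangement frequency.  For
autosomal loci the positive fraction counts carriers (homozygous or
heterozygous) and the frequency is recovered under Hardy-Weinberg as
``1 - sqrt(fraction of non-carriers)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "WormCount",
    "FrequencyEstimate",
    "estimate_frequency",
    "frequency_ci",
    "read_worm_counts_tsv",
    "write_worm_estimates_tsv",
]


@dataclass(frozen=True)
class WormCount:
    """One population x generation single-worm PCR assay."""

    population: str
    generation: int
    n_sampled: int
    n_positive: int
    chromosome_class: str  # "autosome" | "X"
    cnv_type: str  # "duplication" | "deletion"

    def __post_init__(self) -> None:
        if self.n_sampled <= 0:
            raise ValueError("n_sampled must be positive")
        if not 0 <= self.n_positive <= self.n_sampled:
            raise ValueError("n_positive must lie in [0, n_sampled]")
        if self.chromosome_class not in ("autosome", "X"):
            raise ValueError("chromosome_class must be 'autosome' or 'X'")
        if self.cnv_type not in ("duplication", "deletion"):
            raise ValueError("cnv_type must be 'duplication' or 'deletion'")


@dataclass(frozen=True)
class FrequencyEstimate:
    """Rearrangement frequency and implied average copy-number per haploid."""

    frequency: float
    copy_number: float
    ci_low: float
    ci_high: float
    n_sampled: int
    n_positive: int
    cnv_type: str


def _carrier_to_allele(fraction: float, chromosome_class: str) -> float:
    if chromosome_class == "X":
        return fraction
    return 1.0 - math.sqrt(1.0 - fraction)


def _copy_from_frequency(q: float, cnv_type: str) -> float:
    return 1.0 + q if cnv_type == "duplication" else 1.0 - q


def estimate_frequency(
    count: WormCount, decimals: int | None = 2
) -> FrequencyEstimate:
    """Point estimate of the rearrangement frequency and copy-number.

    Boundary counts need no special handling: 0 positives give q = 0 and
    all-positive gives q = 1, exactly as the direct arithmetic yields.
    ``decimals`` rounds the reported values (default 2, matching the
    precision the assay tables are printed at); pass ``None`` for raw
    values.
    """
    fraction = count.n_positive / count.n_sampled
    q = _carrier_to_allele(fraction, count.chromosome_class)
    c = _copy_from_frequency(q, count.cnv_type)
    lo, hi = frequency_ci(count)
    if decimals is not None:
        q, c = round(q, decimals), round(c, decimals)
    return FrequencyEstimate(
        frequency=q,
        copy_number=c,
        ci_low=lo,
        ci_high=hi,
        n_sampled=count.n_sampled,
        n_positive=count.n_positive,
        cnv_type=count.cnv_type,
    )


def frequency_ci(count: WormCount, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval on the positive fraction, mapped to q.

    The exact binomial bounds on the carrier fraction are pushed through
    the same carrier-to-allele transform as the point estimate (the
    transform is monotone, so the interval maps directly).  ``level = 0``
    collapses to the point estimate.
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    n, k = count.n_sampled, count.n_positive
    if level == 0.0:
        f_lo = f_hi = k / n
    else:
        alpha = 1.0 - level
        f_lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        f_hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (
        _carrier_to_allele(f_lo, count.chromosome_class),
        _carrier_to_allele(f_hi, count.chromosome_class),
    )


def read_worm_counts_tsv(path) -> list[WormCount]:
    """Read counts from a TSV mirroring the assay-table columns."""
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {
        "population",
        "generation",
        "n_sampled",
        "n_positive",
        "chromosome_class",
        "cnv_type",
    }
    if not required.issubset(table.columns):
        raise ValueError(f"worm-count table needs columns {sorted(required)}")
    return [
        WormCount(
            population=str(row.population),
            generation=int(row.generation),
            n_sampled=int(row.n_sampled),
            n_positive=int(row.n_positive),
            chromosome_class=str(row.chromosome_class),
            cnv_type=str(row.cnv_type),
        )
        for row in table.itertuples()
    ]


def write_worm_estimates_tsv(counts, path, decimals: int | None = 2) -> None:
    """Estimate every count and write a TSV with q, c and the 95 % CI."""
    rows = []
    for count in counts:
        est = estimate_frequency(count, decimals=decimals)
        rows.append(
            {
                "population": count.population,
                "generation": count.generation,
                "n_sampled": count.n_sampled,
                "n_positive": count.n_positive,
                "chromosome_class": count.chromosome_class,
                "cnv_type": count.cnv_type,
                "frequency": est.frequency,
                "copy_number": est.copy_number,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
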