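"""Synthetic data generation with known ground truth.

Every input the analysis pipeline consumes can be generated here:
genomes with annotated features, pooled-sample aCGH probe profiles,
qPCR Ct tables and dilution series, single-worm PCR counts, and
Wright-Fisher allele-frequency trajectories.

The pooled-DNA observation model: a CNV segregating at frequency ``q``
per haploid genome (carriers bearing one extra copy by default) shifts
the population-average copy-number per haploid to ``1 + q`` for a
duplication and ``1 - q`` for a deletion, hence the expected probe
log2 ratio inside the CNV is ``log2(1 + q)`` or ``log2(1 - q)``;
probes outside CNVs have expectation 0.  Gaussian noise of standard
deviation ``probe_sd`` is added per probe.  Probes over a fixed
deletion (``q = 1``) are clamped at a configurable floor, mimicking the
finite background intensity of real arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .popgen import PopGenParams, wright_fisher_trajectories
from .profiles import ProbeProfile

__all__ = [
    "BIOTYPES",
    "Feature",
    "GenomeModel",
    "CnvSpec",
    "PopulationCnvConfig",
    "NoiseModel",
    "make_genome",
    "simulate_acgh",
    "simulate_qpcr",
    "simulate_dilution_series",
    "simulate_worm_sample",
    "simulate_wright_fisher",
    "read_features_gff3",
]

BIOTYPES = (
    "protein_coding",
    "trna",
    "pirna",
    "ncrna",
    "pseudogene",
    "transposon",
)

#: default biotype sampling weights, loosely reflecting genome composition
_BIOTYPE_WEIGHTS = (0.70, 0.08, 0.08, 0.06, 0.05, 0.03)

_CHROM_NAMES = ("I", "II", "III", "IV", "V", "X")


@dataclass(frozen=True)
class Feature:
    """One annotated genomic feature (1-based inclusive coordinates)."""

    chromosome: str
    start: int
    end: int
    biotype: str
    feature_id: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid feature interval {self.start}-{self.end}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")


@dataclass(frozen=True)
class GenomeModel:
    """A toy genome: chromosome sizes, a regular probe grid, and features."""

    chromosomes: tuple[tuple[str, int], ...]
    probe_spacing: int
    features: tuple[Feature, ...] = ()

    def __post_init__(self) -> None:
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be positive")
        lengths = dict(self.chromosomes)
        if any(length < 1 for length in lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for feat in self.features:
            if feat.chromosome not in lengths:
                raise ValueError(f"feature on unknown chromosome {feat.chromosome}")
            if feat.end > lengths[feat.chromosome]:
                raise ValueError(
                    f"feature {feat.feature_id} extends past chromosome end"
                )

    def chromosome_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def probe_positions(self, chrom: str) -> np.ndarray:
        """Probe grid: spacing, 2*spacing, ... up to the chromosome end."""
        length = self.chromosome_length(chrom)
        return np.arange(self.probe_spacing, length + 1, self.probe_spacing,
                         dtype=np.int64)

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, length in self.chromosomes:
                fh.write(f"##sequence-region {name} 1 {length}\n")
            for feat in self.features:
                attrs = f"ID={feat.feature_id};biotype={feat.biotype}"
                fh.write(
                    f"{feat.chromosome}\tcnv_evodyn\tgene\t{feat.start}\t"
                    f"{feat.end}\t.\t+\t.\t{attrs}\n"
                )

    def to_bed(self, path) -> None:
        """BED6 plus a seventh biotype column (0-based half-open)."""
        with open(path, "w") as fh:
            for feat in self.features:
                fh.write(
                    f"{feat.chromosome}\t{feat.start - 1}\t{feat.end}\t"
                    f"{feat.feature_id}\t0\t+\t{feat.biotype}\n"
                )


def read_features_gff3(path) -> tuple[Feature, ...]:
    """Read features back from a GFF3 with ``biotype`` attributes."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            feats.append(
                Feature(
                    chromosome=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    biotype=attrs.get("biotype", "protein_coding"),
                    feature_id=attrs.get("ID", f"feat{len(feats)}"),
                )
            )
    return tuple(feats)


@dataclass(frozen=True)
class CnvSpec:
    """One CNV segregating in a population."""

    chromosome: str
    start: int
    end: int
    kind: str  # "duplication" | "deletion"
    frequency: float
    extra_copies: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("duplication", "deletion"):
            raise ValueError(f"kind must be duplication or deletion, got {self.kind!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.extra_copies < 1:
            raise ValueError("extra_copies must be >= 1")

    @property
    def copy_number(self) -> float:
        """Population-average copies per haploid genome."""
        if self.kind == "duplication":
            return 1.0 + self.frequency * self.extra_copies
        return 1.0 - self.frequency


@dataclass(frozen=True)
class PopulationCnvConfig:
    """The set of CNVs segregating in one population.

    CNVs must not overlap one another: the pooled observation model has
    no way to attribute signal on a shared interval, and in the real
    populations CNVs never co-occur on one interval.
    """

    cnvs: tuple[CnvSpec, ...] = ()

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[CnvSpec]] = {}
        for cnv in self.cnvs:
            by_chrom.setdefault(cnv.chromosome, []).append(cnv)
        for chrom, cnvs in by_chrom.items():
            cnvs = sorted(cnvs, key=lambda c: c.start)
            for left, right in zip(cnvs, cnvs[1:]):
                if right.start <= left.end:
                    raise ValueError(
                        f"overlapping CNVs on {chrom}: "
                        f"{left.start}-{left.end} and {right.start}-{right.end}"
                    )


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings shared by the generators."""

    probe_sd: float = 0.25
    ct_sd: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.probe_sd < 0 or self.ct_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def make_genome(
    n_chromosomes: int,
    chrom_length: int,
    probe_spacing: int,
    n_features: int,
    seed=None,
) -> GenomeModel:
    """Build a genome with equal-length chromosomes and random features."""
    if n_chromosomes < 1 or chrom_length < 1 or probe_spacing < 1 or n_features < 0:
        raise ValueError("counts and lengths must be positive")
    names = [
        _CHROM_NAMES[i] if i < len(_CHROM_NAMES) else f"chr{i + 1}"
        for i in range(n_chromosomes)
    ]
    rng = np.random.default_rng(seed)
    feats = []
    for i in range(n_features):
        chrom = names[int(rng.integers(n_chromosomes))]
        length = int(rng.integers(200, max(201, min(5000, chrom_length))))
        start = int(rng.integers(1, max(2, chrom_length - length)))
        biotype = str(rng.choice(BIOTYPES, p=_BIOTYPE_WEIGHTS))
        feats.append(
            Feature(chrom, start, start + length - 1, biotype, f"feat{i:04d}")
        )
    return GenomeModel(
        chromosomes=tuple((name, chrom_length) for name in names),
        probe_spacing=probe_spacing,
        features=tuple(feats),
    )


def simulate_acgh(
    genome: GenomeModel,
    config: PopulationCnvConfig,
    noise: NoiseModel,
    floor: float = -8.0,
) -> ProbeProfile:
    """Simulate one pooled-DNA aCGH profile.

    Probes inside a duplication at frequency ``q`` have expected log2
    ratio ``log2(1 + q * extra_copies)``; inside a deletion,
    ``log2(1 - q)`` (clamped at ``floor`` for a fixed deletion); outside
    CNVs, 0.  Gaussian noise with ``noise.probe_sd`` is added.
    """
    rng = np.random.default_rng(noise.seed)
    data = {}
    for chrom, _ in genome.chromosomes:
        pos = genome.probe_positions(chrom)
        expected = np.zeros(pos.size)
        for cnv in config.cnvs:
            if cnv.chromosome != chrom:
                continue
            inside = (pos >= cnv.start) & (pos <= cnv.end)
            c = cnv.copy_number
            expected[inside] = math.log2(c) if c > 0 else floor
        vals = expected + rng.normal(0.0, noise.probe_sd, size=pos.size)
        data[chrom] = (pos, vals)
    return ProbeProfile(data)


def simulate_qpcr(
    true_ratio: float,
    efficiency_ref: float,
    efficiency_test: float,
    n_replicates: int = 3,
    noise: NoiseModel = NoiseModel(ct_sd=0.0),
    ct_reference: float = 20.0,
    primer_offset: float = 2.0,
):
    """Generate a four-group Ct run whose underlying copy ratio is known.

    Groups follow the plate layout of the difference-of-differences
    quantification: reference DNA with reference primers (RR'),
    reference DNA with test primers (RT'), test DNA with reference
    primers (TR') and test DNA with test primers (TT').  The expected
    ddCt of the run equals ``-log_{1+E_test}(true_ratio)``; per-replicate
    Gaussian noise of ``noise.ct_sd`` cycles is added.
    """
    from .qpcr import CtRun  # local import avoids a module cycle

    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    for eff in (efficiency_ref, efficiency_test):
        if not 0.0 < eff <= 1.0:
            raise ValueError("efficiencies must lie in (0, 1]")
    if n_replicates < 2:
        raise ValueError("need at least two replicates per group")
    rng = np.random.default_rng(noise.seed)
    rr_mean = ct_reference
    rt_mean = ct_reference + primer_offset
    tr_mean = rr_mean  # the reference locus is single-copy in both templates
    tt_mean = rt_mean - math.log(true_ratio) / math.log(1.0 + efficiency_test)

    def group(mean: float) -> np.ndarray:
        return mean + rng.normal(0.0, noise.ct_sd, size=n_replicates)

    return CtRun(
        rr=group(rr_mean),
        rt=group(rt_mean),
        tr=group(tr_mean),
        tt=group(tt_mean),
        efficiency=efficiency_test,
    )


def simulate_dilution_series(
    efficiency: float,
    n_points: int = 5,
    ct_top: float = 15.0,
    step_log10: float = 1.0,
    noise: NoiseModel = NoiseModel(ct_sd=0.0),
):
    """Dilution-series (log10 concentration, Ct) pairs at a known efficiency.

    The theoretical standard-curve slope is ``-1 / log10(1 + E)``
    (-3.32 cycles per decade at perfect doubling).
    """
    from .qpcr import DilutionSeries

    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must lie in (0, 1]")
    if n_points < 3:
        raise ValueError("need at least three dilution points")
    rng = np.random.default_rng(noise.seed)
    slope = -1.0 / math.log10(1.0 + efficiency)
    log10_conc = -step_log10 * np.arange(n_points)
    ct = ct_top + slope * log10_conc + rng.normal(0.0, noise.ct_sd, n_points)
    return DilutionSeries(log10_conc=log10_conc, ct=ct)


def simulate_worm_sample(
    q: float,
    n: int,
    chromosome_class: str,
    cnv_type: str,
    seed=None,
    population: str = "sim",
    generation: int = 0,
):
    """Binomial single-worm PCR counts for ``n`` sampled males.

    Autosomal loci: a male is positive when he carries the rearrangement
    on either homolog, probability ``1 - (1 - q)**2`` under
    Hardy-Weinberg.  X-linked loci: males are hemizygous, so a male is
    positive with probability ``q``.
    """
    from .wormpcr import WormCount

    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be positive")
    if chromosome_class not in ("autosome", "X"):
        raise ValueError("chromosome_class must be 'autosome' or 'X'")
    p_positive = q if chromosome_class == "X" else 1.0 - (1.0 - q) ** 2
    rng = np.random.default_rng(seed)
    k = int(rng.binomial(n, p_positive))
    return WormCount(
        population=population,
        generation=generation,
        n_sampled=n,
        n_positive=k,
        chromosome_class=chromosome_class,
        cnv_type=cnv_type,
    )


def simulate_wright_fisher(
    params: PopGenParams,
    generations: int,
    n_reps: int,
    seed=None,
) -> np.ndarray:
    """Wright-Fisher trajectories; shared engine with :mod:`.popgen`."""
    return wright_fisher_trajectories(params, generations, n_reps, seed=seed)
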