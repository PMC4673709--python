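"""End-to-end orchestration: simulate, segment, call, estimate, interpret.

A :class:`RunConfig` (YAML-serializable) declares a genome, the CNVs
segregating in each population with their frequencies at each sampled
generation (either stated explicitly or driven by a Wright-Fisher
trajectory), noise levels and analysis thresholds.
:func:`run_pipeline` then generates pooled aCGH profiles, segments and
calls CNVs, estimates frequencies by simulated qPCR and single-worm
PCR, clusters convergent calls across populations, and attaches a
drift-compatibility p-value to every CNV — a synthetic analogue of the
study's full analysis chain with ground truth known.

All randomness flows from one root seed through named substreams
(stage, population, generation, CNV), so re-running a config reproduces
every output bit-for-bit and stages can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import convergence, popgen, qpcr, segmentation, synthetic, wormpcr

__all__ = [
    "GenomeSpec",
    "CnvPlan",
    "PopulationPlan",
    "RunConfig",
    "PipelineResult",
    "PipelineError",
    "Fixtures",
    "run_pipeline",
    "load_fixtures",
]

log = logging.getLogger("cnv_evodyn.pipeline")

_STAGE_ACGH, _STAGE_WORM, _STAGE_QPCR, _STAGE_WF, _STAGE_NEUTRAL = range(5)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def _substream(root_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(int(root_seed), spawn_key=tuple(int(k) for k in key))
    )


def _substream_seed(root_seed: int, *key: int) -> int:
    # a 31-bit seed derived from the named substream, for APIs taking ints
    return int(_substream(root_seed, *key).integers(2**31))


@dataclass(frozen=True)
class GenomeSpec:
    n_chromosomes: int = 1
    chrom_length: int = 200_000
    probe_spacing: int = 2_000
    n_features: int = 0


@dataclass(frozen=True)
class CnvPlan:
    """One CNV in one population, with its frequency over time.

    Either ``frequency_by_generation`` maps sampled generation to the
    true frequency, or ``trajectory`` holds Wright-Fisher parameters
    (``ne``, ``p0``, optional ``s``) from which frequencies at the
    sampled generations are simulated.
    """

    chromosome: str
    start: int
    end: int
    kind: str
    frequency_by_generation: dict[int, float] | None = None
    trajectory: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if (self.frequency_by_generation is None) == (self.trajectory is None):
            raise ValueError(
                "exactly one of frequency_by_generation or trajectory is required"
            )


@dataclass(frozen=True)
class PopulationPlan:
    name: str
    cnvs: tuple[CnvPlan, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    genome: GenomeSpec = GenomeSpec()
    generations: tuple[int, ...] = (80, 140, 208)
    populations: tuple[PopulationPlan, ...] = ()
    probe_sd: float = 0.25
    ct_sd: float = 0.15
    segmentation: segmentation.SegmentationParams = segmentation.SegmentationParams()
    worms_per_sample: int = 30
    qpcr_efficiency: float = 0.9
    qpcr_replicates: int = 3
    qpcr_bootstrap: int = 10_000
    neutral_ne: int = 1_000
    neutral_reps: int = 2_000

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        genome = GenomeSpec(**raw.pop("genome", {}))
        seg = segmentation.SegmentationParams(**raw.pop("segmentation", {}))
        pops = []
        for pop in raw.pop("populations", []):
            cnvs = []
            for cnv in pop.get("cnvs", []):
                cnv = dict(cnv)
                fbg = cnv.pop("frequency_by_generation", None)
                if fbg is not None:
                    fbg = {int(k): float(v) for k, v in fbg.items()}
                cnvs.append(CnvPlan(frequency_by_generation=fbg, **cnv))
            pops.append(PopulationPlan(name=str(pop["name"]), cnvs=tuple(cnvs)))
        generations = tuple(int(g) for g in raw.pop("generations", (80, 140, 208)))
        return cls(
            genome=genome,
            segmentation=seg,
            populations=tuple(pops),
            generations=generations,
            **raw,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    trajectories: pd.DataFrame
    convergence: pd.DataFrame
    neutrality: pd.DataFrame
    summary: dict


def _planned_frequencies(
    plan: CnvPlan, generations: Sequence[int], root_seed: int, pop_idx: int, cnv_idx: int
) -> dict[int, float]:
    if plan.frequency_by_generation is not None:
        missing = [g for g in generations if g not in plan.frequency_by_generation]
        if missing:
            raise PipelineError(
                "plan", f"no frequency stated for generations {missing}"
            )
        return {g: float(plan.frequency_by_generation[g]) for g in generations}
    traj = dict(plan.trajectory)
    params = popgen.PopGenParams(
        ne=int(traj.get("ne", 1000)),
        p0=float(traj.get("p0", 1.0 / (2 * int(traj.get("ne", 1000))))),
        s=float(traj.get("s", 0.0)),
    )
    horizon = max(generations)
    seed = _substream_seed(root_seed, _STAGE_WF, pop_idx, cnv_idx)
    path = popgen.wright_fisher_trajectories(params, horizon, 1, seed=seed)[0]
    return {g: float(path[g]) for g in generations}


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full synthetic analysis chain for a run configuration."""
    t0 = time.perf_counter()
    genome = synthetic.make_genome(
        config.genome.n_chromosomes,
        config.genome.chrom_length,
        config.genome.probe_spacing,
        config.genome.n_features,
        seed=_substream_seed(config.seed, 99),
    )
    chrom_lengths = dict(genome.chromosomes)

    call_rows: list[dict] = []
    traj_rows: list[dict] = []
    final_calls: list[cat.CnvCall] = []
    final_gen = max(config.generations)

    for pop_idx, pop in enumerate(config.populations):
        freqs = [
            _planned_frequencies(plan, config.generations, config.seed, pop_idx, i)
            for i, plan in enumerate(pop.cnvs)
        ]
        for gen_idx, generation in enumerate(config.generations):
            specs = tuple(
                synthetic.CnvSpec(
                    chromosome=plan.chromosome,
                    start=plan.start,
                    end=plan.end,
                    kind=plan.kind,
                    frequency=freqs[i][generation],
                )
                for i, plan in enumerate(pop.cnvs)
            )
            try:
                cnv_config = synthetic.PopulationCnvConfig(cnvs=specs)
            except ValueError as exc:
                raise PipelineError("simulate", f"{pop.name}: {exc}") from exc
            noise = synthetic.NoiseModel(
                probe_sd=config.probe_sd,
                ct_sd=config.ct_sd,
                seed=_substream_seed(config.seed, _STAGE_ACGH, pop_idx, gen_idx),
            )
            profile = synthetic.simulate_acgh(genome, cnv_config, noise)
            segs = segmentation.segment(profile, config.segmentation)
            segs = segmentation.classify(segs, profile, config.segmentation)
            calls = segmentation.to_calls(segs, profile, chrom_lengths)
            log.info(
                "population %s generation %d: %d calls (%.2fs)",
                pop.name, generation, len(calls), time.perf_counter() - t0,
            )
            for call in calls:
                call_rows.append(
                    {
                        "population": pop.name,
                        "generation": generation,
                        "chromosome": call.chromosome,
                        "inner_start": call.inner_start,
                        "inner_end": call.inner_end,
                        "outer_start": call.outer_start,
                        "outer_end": call.outer_end,
                        "type": call.kind,
                        "mean_log2": call.mean_log2,
                        "copy_per_haploid": call.copy_per_haploid,
                        "frequency": call.frequency,
                    }
                )
                if generation == final_gen:
                    final_calls.append(
                        cat.CnvCall(
                            population=pop.name,
                            chromosome=call.chromosome,
                            start=call.inner_start,
                            end=call.inner_end,
                            kind=call.kind,
                            copy_number=call.copy_per_haploid,
                        )
                    )
            for cnv_idx, plan in enumerate(pop.cnvs):
                q_true = freqs[cnv_idx][generation]
                matched = _match_call(calls, plan)
                chrom_class = "X" if plan.chromosome == "X" else "autosome"
                worm = synthetic.simulate_worm_sample(
                    q_true,
                    config.worms_per_sample,
                    chrom_class,
                    plan.kind,
                    seed=_substream_seed(
                        config.seed, _STAGE_WORM, pop_idx, gen_idx, cnv_idx
                    ),
                    population=pop.name,
                    generation=generation,
                )
                worm_est = wormpcr.estimate_frequency(worm, decimals=None)
                true_copy = 1.0 + q_true if plan.kind == "duplication" else 1.0 - q_true
                qpcr_row: dict[str, float] = {}
                if true_copy > 0:
                    run = synthetic.simulate_qpcr(
                        true_copy,
                        config.qpcr_efficiency,
                        config.qpcr_efficiency,
                        n_replicates=config.qpcr_replicates,
                        noise=synthetic.NoiseModel(
                            ct_sd=config.ct_sd,
                            seed=_substream_seed(
                                config.seed, _STAGE_QPCR, pop_idx, gen_idx, cnv_idx
                            ),
                        ),
                    )
                    est = qpcr.bootstrap_ci(
                        run,
                        iterations=config.qpcr_bootstrap,
                        seed=_substream_seed(
                            config.seed, _STAGE_QPCR, pop_idx, gen_idx, cnv_idx, 1
                        ),
                    )
                    qpcr_row = {
                        "copy_qpcr": est.point,
                        "qpcr_ci_low": est.ci_low,
                        "qpcr_ci_high": est.ci_high,
                    }
                traj_rows.append(
                    {
                        "population": pop.name,
                        "generation": generation,
                        "chromosome": plan.chromosome,
                        "start": plan.start,
                        "end": plan.end,
                        "type": plan.kind,
                        "frequency_true": q_true,
                        "frequency_acgh": matched.frequency if matched else np.nan,
                        "frequency_worm": worm_est.frequency,
                        "worm_ci_low": worm_est.ci_low,
                        "worm_ci_high": worm_est.ci_high,
                        **qpcr_row,
                    }
                )

    clusters = convergence.overlap_clusters(final_calls)
    cluster_rows = [
        {
            "chromosome": cl.chromosome,
            "type": cl.kind,
            "n_members": cl.n_members,
            "populations": ",".join(cl.populations),
            "shared_start": cl.shared_start,
            "shared_end": cl.shared_end,
            "shared_length": cl.shared_length,
        }
        for cl in clusters
    ]

    neutral_rows = []
    for pop_idx, pop in enumerate(config.populations):
        for cnv_idx, plan in enumerate(pop.cnvs):
            observed = [
                r
                for r in traj_rows
                if r["population"] == pop.name
                and r["start"] == plan.start
                and r["generation"] == final_gen
            ]
            if not observed:
                continue
            q_obs = observed[0]["frequency_worm"]
            if not np.isfinite(q_obs) or q_obs <= 0:
                continue
            test = popgen.neutral_trajectory_pvalue(
                config.neutral_ne,
                1.0 / (2 * config.neutral_ne),
                final_gen,
                q_obs,
                n_reps=config.neutral_reps,
                seed=_substream_seed(
                    config.seed, _STAGE_NEUTRAL, pop_idx, cnv_idx
                ),
            )
            neutral_rows.append(
                {
                    "population": pop.name,
                    "chromosome": plan.chromosome,
                    "start": plan.start,
                    "end": plan.end,
                    "type": plan.kind,
                    "observed_frequency": q_obs,
                    "neutral_probability": test.probability,
                    "std_error": test.std_error,
                    "n_reps": test.n_reps,
                }
            )

    result = PipelineResult(
        calls=pd.DataFrame(call_rows),
        trajectories=pd.DataFrame(traj_rows),
        convergence=pd.DataFrame(cluster_rows),
        neutrality=pd.DataFrame(neutral_rows),
        summary={
            "seed": config.seed,
            "n_populations": len(config.populations),
            "generations": list(config.generations),
            "n_calls": len(call_rows),
            "n_convergence_clusters": len(cluster_rows),
            "n_neutrality_tests": len(neutral_rows),
        },
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        result.trajectories.to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
        result.convergence.to_csv(outdir / "convergence.tsv", sep="\t", index=False)
        result.neutrality.to_csv(outdir / "neutrality.tsv", sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=2, sort_keys=True)
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return result


def _match_call(calls, plan: CnvPlan):
    """The called CNV (same chromosome/type) overlapping the planned one."""
    for call in calls:
        if (
            call.chromosome == plan.chromosome
            and call.kind == plan.kind
            and call.inner_start <= plan.end
            and plan.start <= call.inner_end
        ):
            return call
    return None


@dataclass(frozen=True)
class Fixtures:
    """The packaged transcriptions of the study's printed tables."""

    duplications: tuple[cat.CnvCall, ...]
    deletions: tuple[cat.CnvCall, ...]
    single_worm: pd.DataFrame

    @property
    def single_worm_ok(self) -> pd.DataFrame:
        """Rows whose printed counts and frequency are internally consistent."""
        return self.single_worm[self.single_worm["flag"] == "ok"]

    @property
    def single_worm_flagged(self) -> pd.DataFrame:
        return self.single_worm[self.single_worm["flag"] != "ok"]


def load_fixtures() -> Fixtures:
    """Load the packaged catalog and assay tables (checksum-verified)."""
    return Fixtures(
        duplications=tuple(cat.load_duplications()),
        deletions=tuple(cat.load_deletions()),
        single_worm=cat.load_single_worm_table(),
    )
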