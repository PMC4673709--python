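"""Drift-versus-selection arithmetic for CNV trajectories.

The quantitative population-genetic toolkit used to interpret observed
CNV frequency trajectories: the full-sib inbreeding recursion, the
diffusion-theory expectation of 4Ne generations to fixation of a new
neutral mutation (conditional on fixation), recurrent mutation-pressure
frequency dynamics with and without loss, and a Monte-Carlo
Wright-Fisher test of whether an observed frequency is compatible with
neutral drift alone.

The Wright-Fisher engine lives here and is shared with the synthetic
data generator.  It uses a genic (haploid) selection update
``p' = p(1+s)/(1+ps)``; diploid dominance is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PopGenParams",
    "NeutralTrajectoryTest",
    "ConditionalFixation",
    "fullsib_inbreeding",
    "fullsib_inbreeding_series",
    "neutral_fixation_time",
    "mutation_input_frequency",
    "wright_fisher_trajectories",
    "conditional_fixation_time",
    "neutral_trajectory_pvalue",
]


@dataclass(frozen=True)
class PopGenParams:
    """Parameters of a Wright-Fisher population carrying a CNV allele.

    Attributes
    ----------
    ne : effective population size (diploid individuals).
    mu : per-generation rate at which non-carrier haplotypes gain the CNV.
    delta : per-generation rate at which carrier haplotypes lose the CNV.
    s : genic selection coefficient of the CNV allele.
    p0 : initial allele frequency.
    """

    ne: int
    p0: float
    mu: float = 0.0
    delta: float = 0.0
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.ne < 1:
            raise ValueError("ne must be >= 1")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        for name in ("mu", "delta"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.s <= -1.0:
            raise ValueError("s must exceed -1")


def fullsib_inbreeding(t: int) -> float:
    """Inbreeding coefficient after ``t`` generations of full-sib mating.

    Follows the classical recursion F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4
    starting from an outbred pair (F_0 = F_{-1} = 0).  Fifteen
    generations give F = 0.961, i.e. a 96.1 % reduction in
    heterozygosity relative to a random-mating population with the same
    allele frequencies.
    """
    return float(fullsib_inbreeding_series(t)[-1])


def fullsib_inbreeding_series(t: int) -> np.ndarray:
    """F_0 .. F_t under repeated full-sib mating (length ``t + 1``)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    series = np.zeros(t + 1)
    prev2 = prev1 = 0.0
    for gen in range(1, t + 1):
        cur = (1.0 + 2.0 * prev1 + prev2) / 4.0
        series[gen] = cur
        prev2, prev1 = prev1, cur
    return series


def neutral_fixation_time(ne: float) -> float:
    """Mean generations to fixation of a new neutral mutation, given fixation.

    The diffusion-theory expectation is 4Ne generations.  The
    unconditional absorption time (which is dominated by rapid losses)
    is deliberately not what this returns.
    """
    if ne < 1:
        raise ValueError("ne must be >= 1")
    return 4.0 * float(ne)


def mutation_input_frequency(mu: float, t: int, delta: float = 0.0) -> float:
    """Expected CNV frequency after ``t`` generations of mutation pressure.

    With gain rate ``mu`` and no loss the frequency is
    ``1 - (1 - mu)**t``; with loss rate ``delta`` the per-generation
    update ``p <- p + mu (1 - p) - delta p`` is iterated, approaching the
    equilibrium ``mu / (mu + delta)``.
    """
    if not 0.0 <= mu <= 1.0 or not 0.0 <= delta <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    if t < 0:
        raise ValueError("t must be non-negative")
    if delta == 0.0:
        return 1.0 - (1.0 - mu) ** t
    p = 0.0
    for _ in range(int(t)):
        p = p + mu * (1.0 - p) - delta * p
    return p


def wright_fisher_trajectories(
    params: PopGenParams,
    generations: int,
    n_reps: int,
    seed=None,
) -> np.ndarray:
    """Forward-simulate allele-frequency trajectories.

    Each generation the frequency is updated deterministically for
    recurrent gain/loss and genic selection, then the next generation's
    allele count is drawn from Binomial(2 Ne, p').  With ``mu = delta =
    0`` the boundaries 0 and 1 are absorbing.

    Returns an array of shape ``(n_reps, generations + 1)`` whose first
    column is ``p0``.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    two_ne = 2 * int(params.ne)
    out = np.empty((n_reps, generations + 1))
    p = np.full(n_reps, float(params.p0))
    out[:, 0] = p
    for gen in range(1, generations + 1):
        q = p
        if params.mu or params.delta:
            q = q + params.mu * (1.0 - q) - params.delta * q
        if params.s:
            q = q * (1.0 + params.s) / (1.0 + q * params.s)
        p = rng.binomial(two_ne, np.clip(q, 0.0, 1.0)) / two_ne
        out[:, gen] = p
    return out


@dataclass(frozen=True)
class ConditionalFixation:
    """Monte-Carlo summary of neutral fixation behaviour."""

    mean_time: float
    n_fixed: int
    n_lost: int
    n_unresolved: int

    @property
    def fixation_fraction(self) -> float:
        total = self.n_fixed + self.n_lost + self.n_unresolved
        return self.n_fixed / total if total else float("nan")


def conditional_fixation_time(
    ne: int,
    p0: float,
    n_reps: int,
    seed=None,
    max_generations: int | None = None,
    s: float = 0.0,
) -> ConditionalFixation:
    """Simulate to absorption; mean fixation time among fixed replicates.

    Replicates still segregating after ``max_generations`` (default
    ``100 * ne``) are counted as unresolved and excluded from the mean.
    """
    if max_generations is None:
        max_generations = 100 * int(ne)
    rng = np.random.default_rng(seed)
    two_ne = 2 * int(ne)
    p = np.full(n_reps, float(p0))
    active = np.arange(n_reps)
    fix_times = np.zeros(n_reps, dtype=np.int64)
    fixed = np.zeros(n_reps, dtype=bool)
    lost = np.zeros(n_reps, dtype=bool)
    for gen in range(1, max_generations + 1):
        if active.size == 0:
            break
        q = p[active]
        if s:
            q = q * (1.0 + s) / (1.0 + q * s)
        draws = rng.binomial(two_ne, q) / two_ne
        p[active] = draws
        hit_one = draws == 1.0
        hit_zero = draws == 0.0
        idx_fix = active[hit_one]
        fixed[idx_fix] = True
        fix_times[idx_fix] = gen
        lost[active[hit_zero]] = True
        active = active[~(hit_one | hit_zero)]
    n_fixed = int(fixed.sum())
    mean_time = float(fix_times[fixed].mean()) if n_fixed else float("nan")
    return ConditionalFixation(
        mean_time=mean_time,
        n_fixed=n_fixed,
        n_lost=int(lost.sum()),
        n_unresolved=int(active.size),
    )


@dataclass(frozen=True)
class NeutralTrajectoryTest:
    """P(frequency >= observed at generation t | neutral drift)."""

    probability: float
    std_error: float
    n_reps: int
    n_exceed: int


def neutral_trajectory_pvalue(
    ne: int,
    p0: float,
    t: int,
    q_observed: float,
    n_reps: int = 10_000,
    seed=None,
) -> NeutralTrajectoryTest:
    """Drift-compatibility of an observed CNV frequency.

    Monte-Carlo estimate of the probability that a neutral allele
    starting at ``p0`` reaches a frequency of at least ``q_observed`` by
    generation ``t`` in a Wright-Fisher population of size ``ne``, with
    the binomial standard error of the estimate.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000 for a stable estimate")
    if not 0.0 <= q_observed <= 1.0:
        raise ValueError("q_observed must lie in [0, 1]")
    if q_observed == 0.0:
        return NeutralTrajectoryTest(1.0, 0.0, n_reps, n_reps)
    params = PopGenParams(ne=ne, p0=p0)
    traj = wright_fisher_trajectories(params, t, n_reps, seed=seed)
    n_exceed = int(np.count_nonzero(traj[:, -1] >= q_observed))
    prob = n_exceed / n_reps
    se = float(np.sqrt(prob * (1.0 - prob) / n_reps))
    return NeutralTrajectoryTest(prob, se, n_reps, n_exceed)
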