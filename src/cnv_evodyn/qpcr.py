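"""Relative copy-number from qPCR by the difference-of-differences Ct method.

A run consists of four groups of technical replicates — reference DNA
with reference primers (RR'), reference DNA with test primers (RT'),
test DNA with reference primers (TR') and test DNA with test primers
(TT').  With group means substituted,

    ddCt = (TT' - TR') - (RT' - RR')
    copy ratio = (1 + E) ** (-ddCt)

where the amplification efficiency E of the reference is calibrated
from a dilution-series standard curve on the same plate.  Confidence
intervals come from a percentile bootstrap that resamples individual
Ct values within each group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtRun",
    "DilutionSeries",
    "CopyEstimate",
    "CalibrationError",
    "efficiency_from_dilution",
    "copy_ratio",
    "bootstrap_ci",
    "read_ct_csv",
    "read_dilution_csv",
]

_GROUPS = ("RR", "RT", "TR", "TT")


class CalibrationError(ValueError):
    """The dilution series cannot yield a plausible efficiency."""


@dataclass(frozen=True)
class CtRun:
    """Four groups of Ct replicates plus the plate's reference efficiency."""

    rr: np.ndarray
    rt: np.ndarray
    tr: np.ndarray
    tt: np.ndarray
    efficiency: float

    def __post_init__(self) -> None:
        for name in ("rr", "rt", "tr", "tt"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            object.__setattr__(self, name, arr)
            if arr.size == 0:
                raise ValueError(f"group {name.upper()}' is empty")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"group {name.upper()}' has non-finite or non-positive Ct")
        if not 0.0 < self.efficiency <= 1.1:
            raise ValueError("efficiency must lie in (0, 1.1]")

    @property
    def groups(self) -> dict[str, np.ndarray]:
        return {"RR": self.rr, "RT": self.rt, "TR": self.tr, "TT": self.tt}

    @property
    def ddct(self) -> float:
        """(mean TT' - mean TR') - (mean RT' - mean RR')."""
        return float(
            (self.tt.mean() - self.tr.mean()) - (self.rt.mean() - self.rr.mean())
        )


@dataclass(frozen=True)
class DilutionSeries:
    """Standard-curve points: (log10 relative concentration, Ct)."""

    log10_conc: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.log10_conc, dtype=np.float64)
        ct = np.asarray(self.ct, dtype=np.float64)
        object.__setattr__(self, "log10_conc", conc)
        object.__setattr__(self, "ct", ct)
        if conc.size < 3 or conc.size != ct.size:
            raise ValueError("need >= 3 (concentration, Ct) pairs")
        if np.any(np.diff(conc) >= 0):
            raise ValueError("concentrations must be strictly decreasing")


@dataclass(frozen=True)
class CopyEstimate:
    """Point estimate and bootstrap CI of the relative copy-number."""

    point: float
    ci_low: float
    ci_high: float
    iterations: int
    seed: int | None


def efficiency_from_dilution(series: DilutionSeries) -> float:
    """Amplification efficiency from the standard-curve slope.

    Least-squares slope ``b`` of Ct on log10 concentration gives
    ``E = 10**(-1/b) - 1``; perfect doubling corresponds to
    b = -3.3219.  Slopes that are positive or implausibly shallow
    (|b| < 0.1) raise :class:`CalibrationError`; efficiencies slightly
    above 1 are clipped to 1.1 with a warning.
    """
    fit = stats.linregress(series.log10_conc, series.ct)
    slope = float(fit.slope)
    if slope >= 0 or abs(slope) < 0.1:
        raise CalibrationError(
            f"standard-curve slope {slope:.3f} is not a plausible qPCR calibration"
        )
    eff = 10.0 ** (-1.0 / slope) - 1.0
    if eff > 1.0 + 1e-9:
        warnings.warn(
            f"calibrated efficiency {eff:.3f} exceeds 1 (perfect doubling); "
            "clipping to 1.1",
            stacklevel=2,
        )
        eff = min(eff, 1.1)
    return eff


def copy_ratio(run: CtRun) -> float:
    """Mean copy-number of the test locus relative to the reference."""
    return float((1.0 + run.efficiency) ** (-run.ddct))


def bootstrap_ci(
    run: CtRun,
    iterations: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
) -> CopyEstimate:
    """Percentile bootstrap CI of the copy ratio.

    Each iteration resamples Ct values with replacement within each of
    the four groups independently (preserving group sizes), recomputes
    the copy ratio, and the CI is read off the 2.5 % and 97.5 %
    quantiles (for the default 95 % level) of the sorted bootstrap
    ratios.
    """
    if any(g.size < 2 for g in run.groups.values()):
        raise ValueError("bootstrap needs >= 2 replicates in every group")
    if iterations < 100:
        warnings.warn(
            f"{iterations} bootstrap iterations is too few for stable quantiles",
            stacklevel=2,
        )
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    def resampled_means(group: np.ndarray) -> np.ndarray:
        idx = rng.integers(0, group.size, size=(iterations, group.size))
        return group[idx].mean(axis=1)

    ddct = (resampled_means(run.tt) - resampled_means(run.tr)) - (
        resampled_means(run.rt) - resampled_means(run.rr)
    )
    ratios = (1.0 + run.efficiency) ** (-ddct)
    alpha = 100.0 * (1.0 - level) / 2.0
    low, high = np.percentile(ratios, [alpha, 100.0 - alpha])
    return CopyEstimate(
        point=copy_ratio(run),
        ci_low=float(low),
        ci_high=float(high),
        iterations=iterations,
        seed=seed,
    )


def read_ct_csv(path, efficiency: float) -> dict[str, CtRun]:
    """Read runs from a CSV with columns run_id, group, ct.

    Groups are RR, RT, TR, TT (primes implied).  Returns one
    :class:`CtRun` per run_id, all sharing the supplied efficiency.
    """
    table = pd.read_csv(path)
    required = {"run_id", "group", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    runs = {}
    for run_id, grp in table.groupby("run_id", sort=False):
        cts = {g: grp.loc[grp["group"] == g, "ct"].to_numpy() for g in _GROUPS}
        missing = [g for g, arr in cts.items() if arr.size == 0]
        if missing:
            raise ValueError(f"run {run_id}: missing groups {missing}")
        runs[str(run_id)] = CtRun(
            rr=cts["RR"], rt=cts["RT"], tr=cts["TR"], tt=cts["TT"],
            efficiency=efficiency,
        )
    return runs


def write_ct_csv(runs: dict[str, CtRun], path) -> None:
    rows = [
        {"run_id": run_id, "group": g, "ct": float(ct)}
        for run_id, run in runs.items()
        for g, cts in run.groups.items()
        for ct in cts
    ]
    pd.DataFrame(rows, columns=["run_id", "group", "ct"]).to_csv(path, index=False)


def read_dilution_csv(path) -> DilutionSeries:
    """Read a dilution series from a CSV with columns log10_conc, ct."""
    table = pd.read_csv(path)
    if not {"log10_conc", "ct"}.issubset(table.columns):
        raise ValueError("dilution table needs columns log10_conc, ct")
    table = table.sort_values("log10_conc", ascending=False)
    return DilutionSeries(
        log10_conc=table["log10_conc"].to_numpy(), ct=table["ct"].to_numpy()
    )
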