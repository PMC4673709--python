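"""Probe-level log2-ratio profiles.

A :class:`ProbeProfile` holds, per chromosome, the ordered probe positions
(1-based bp) and the log2 ratio of test over reference hybridization
intensity for one array.  Profiles round-trip through a three-column TSV
(``chromosome``, ``position``, ``log2_ratio``).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["ProbeProfile", "read_probe_tsv", "write_probe_tsv"]


class ProbeProfile:
    """Ordered per-chromosome probe positions with log2 ratios.

    Parameters
    ----------
    data
        Mapping of chromosome name to a ``(positions, ratios)`` pair.
        Positions must be strictly increasing 1-based integers; the two
        arrays must have equal length.
    """

    def __init__(self, data: Mapping[str, tuple[Iterable[int], Iterable[float]]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, vals) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            vals = np.asarray(vals, dtype=np.float64)
            if pos.shape != vals.shape or pos.ndim != 1:
                raise ValueError(
                    f"{chrom}: positions and ratios must be 1-D arrays of equal length"
                )
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: probe positions must be strictly increasing")
            if pos.size and pos[0] < 1:
                raise ValueError(f"{chrom}: probe positions are 1-based (got {pos[0]})")
            self._data[str(chrom)] = (pos, vals)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._data)

    def positions(self, chrom: str) -> np.ndarray:
        return self._data[chrom][0]

    def ratios(self, chrom: str) -> np.ndarray:
        return self._data[chrom][1]

    @property
    def n_probes(self) -> int:
        return sum(p.size for p, _ in self._data.values())

    def flat_values(self) -> np.ndarray:
        """All log2 ratios concatenated in chromosome order."""
        if not self._data:
            return np.empty(0)
        return np.concatenate([v for _, v in self._data.values()])

    def with_flat_values(self, values: np.ndarray) -> "ProbeProfile":
        """A copy of this profile with ratios replaced from a flat array."""
        values = np.asarray(values, dtype=np.float64)
        if values.size != self.n_probes:
            raise ValueError("flat value array does not match probe count")
        out, off = {}, 0
        for chrom, (pos, _) in self._data.items():
            out[chrom] = (pos.copy(), values[off : off + pos.size].copy())
            off += pos.size
        return ProbeProfile(out)

    def same_grid(self, other: "ProbeProfile") -> bool:
        """True when both profiles interrogate the identical probe set."""
        if self.chromosomes != other.chromosomes:
            return False
        return all(
            np.array_equal(self.positions(c), other.positions(c))
            for c in self.chromosomes
        )

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {"chromosome": chrom, "position": pos, "log2_ratio": vals}
            )
            for chrom, (pos, vals) in self._data.items()
        ]
        if not frames:
            return pd.DataFrame(columns=["chromosome", "position", "log2_ratio"])
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProbeProfile":
        required = {"chromosome", "position", "log2_ratio"}
        if not required.issubset(frame.columns):
            raise ValueError(f"probe table needs columns {sorted(required)}")
        data = {}
        for chrom, grp in frame.groupby("chromosome", sort=False):
            grp = grp.sort_values("position")
            data[str(chrom)] = (
                grp["position"].to_numpy(),
                grp["log2_ratio"].to_numpy(),
            )
        return cls(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeProfile):
            return NotImplemented
        return self.same_grid(other) and all(
            np.array_equal(self.ratios(c), other.ratios(c)) for c in self.chromosomes
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ProbeProfile({len(self._data)} chromosomes, {self.n_probes} probes)"
        )


def read_probe_tsv(path) -> ProbeProfile:
    # round_trip parsing keeps log2 ratios bit-identical across save/load
    return ProbeProfile.from_frame(
        pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    )


def write_probe_tsv(profile: ProbeProfile, path) -> None:
    # %.17g keeps float64 ratios lossless across the round trip
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
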