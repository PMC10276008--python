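"""Coordinate frame for the analysis: chromosome lengths and arm boundaries.

All internal coordinates are 0-based half-open. Sex chromosomes may be parsed
from input files but are excluded from every downstream computation by a single
central filter (:func:`drop_sex_chromosomes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

#: chromosome labels treated as sex chromosomes (with and without "chr" prefix)
SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY", "23", "24"})


def is_autosome(chrom: str) -> bool:
    return str(chrom) not in SEX_CHROMOSOMES


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths and p/q arm boundaries.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp (> 0).
    arm_boundaries
        Mapping chromosome name -> position splitting the p and q arms,
        strictly inside (0, chrom_length).
    """

    chrom_lengths: Mapping[str, int]
    arm_boundaries: Mapping[str, int]
    name: str = "custom"

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
            bound = self.arm_boundaries.get(chrom)
            if bound is None:
                raise ValueError(f"chromosome {chrom} lacks an arm boundary")
            if not 0 < bound < length:
                raise ValueError(
                    f"arm boundary {bound} of {chrom} outside (0, {length})"
                )

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.chrom_lengths)

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.chrom_lengths if is_autosome(c))

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    def arm_boundary(self, chrom: str) -> int:
        return self.arm_boundaries[chrom]

    def arm_of(self, chrom: str, start: int, end: int) -> str:
        """Arm ('p' or 'q') with the larger overlap with [start, end)."""
        bound = self.arm_boundaries[chrom]
        p_overlap = max(0, min(end, bound) - start)
        q_overlap = max(0, end - max(start, bound))
        return "p" if p_overlap >= q_overlap else "q"

    def arm_length(self, chrom: str, arm: str) -> int:
        bound = self.arm_boundaries[chrom]
        return bound if arm == "p" else self.chrom_lengths[chrom] - bound

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom in self.chrom_lengths and 0 <= pos < self.chrom_lengths[chrom]


def drop_sex_chromosomes(df: pd.DataFrame, chrom_col: str = "chrom") -> pd.DataFrame:
    """Central X/Y exclusion filter applied before any scoring."""
    mask = df[chrom_col].astype(str).map(is_autosome)
    return df.loc[mask].reset_index(drop=True)


def simulation_build(
    n_chromosomes: int = 3,
    chrom_length: int = 100_000_000,
    arm_fraction: float = 0.5,
) -> GenomeBuild:
    """Equal-sized autosome genome used by the synthetic-cohort generator."""
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    lengths = {c: int(chrom_length) for c in names}
    arms = {c: int(round(chrom_length * arm_fraction)) for c in names}
    return GenomeBuild(lengths, arms, name=f"sim{n_chromosomes}x{chrom_length // 10**6}Mbp")
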