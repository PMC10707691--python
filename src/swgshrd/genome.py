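"""Chromosome-arm genome models.

Copy-number scars are counted per chromosome arm: a breakpoint that coincides
with a centromere is never evidence of genomic instability, so every
downstream stage (binning, segmentation, LGA counting) works on arms, not
whole chromosomes.  Two karyotypes are bundled:

* :func:`reduced_karyotype` — six 100 Mb chromosomes with a 40 Mb p and a
  60 Mb q arm (600 Mb total).  Small enough that the whole pipeline runs in
  seconds; large enough that each arm can hold several >=10 Mb segments.
* :func:`hg19_karyotype` — the 22 autosomes plus X of hg19, with
  cytoband-derived (approximate) centromere boundaries, read from packaged
  data.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterator

__all__ = ["Arm", "GenomeModel", "reduced_karyotype", "hg19_karyotype"]


@dataclass(frozen=True)
class Arm:
    """One chromosome arm in chromosome coordinates (0-based, half-open)."""

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.end <= self.start:
            raise ValueError(
                f"{self.chrom}{self.arm}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"


@dataclass(frozen=True)
class GenomeModel:
    """An ordered, non-overlapping collection of chromosome arms."""

    arms: tuple[Arm, ...]

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("GenomeModel needs at least one arm")
        by_chrom: dict[str, list[Arm]] = {}
        for a in self.arms:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom, arms in by_chrom.items():
            arms = sorted(arms, key=lambda a: a.start)
            for left, right in zip(arms, arms[1:]):
                if right.start < left.end:
                    raise ValueError(
                        f"overlapping arms on {chrom}: "
                        f"{left.name}[{left.start},{left.end}) and "
                        f"{right.name}[{right.start},{right.end})"
                    )

    def __iter__(self) -> Iterator[Arm]:
        return iter(self.arms)

    def __len__(self) -> int:
        return len(self.arms)

    @property
    def total_length(self) -> int:
        return sum(a.length for a in self.arms)

    @property
    def min_arm_length(self) -> int:
        return min(a.length for a in self.arms)

    def arm_of(self, chrom: str, pos: int) -> Arm:
        """Return the arm containing position ``pos`` on ``chrom``."""
        for a in self.arms:
            if a.chrom == chrom and a.start <= pos < a.end:
                return a
        raise KeyError(f"no arm contains {chrom}:{pos}")


def reduced_karyotype(n_chroms: int = 6, p_len: int = 40_000_000, q_len: int = 60_000_000) -> GenomeModel:
    """Small built-in karyotype for fast simulation and testing."""
    arms = []
    for i in range(1, n_chroms + 1):
        chrom = f"chr{i}"
        arms.append(Arm(chrom, "p", 0, p_len))
        arms.append(Arm(chrom, "q", p_len, p_len + q_len))
    return GenomeModel(tuple(arms))


def hg19_karyotype() -> GenomeModel:
    """Full hg19 autosomes + X, from the packaged arm table.

    Chromosome lengths are exact; centromere boundaries are approximate
    (cytoband midpoints).  Acrocentric p arms (13, 14, 15, 21, 22) are kept
    although they are too short to ever host an LGA.
    """
    arms = []
    ref = resources.files("swgshrd.data").joinpath("hg19_arms.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            arms.append(Arm(row["chrom"], row["arm"], int(row["start"]), int(row["end"])))
    return GenomeModel(tuple(arms))
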