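"""Binned read counts -> normalized log2 copy-ratio profiles.

The segmentation substrate is a per-bin log2 ratio on an arm-aware tiling
grid.  Bins never cross a chromosome-arm boundary (the last bin of an arm
may be short).  Normalization is deliberately simple and fully
deterministic:

1. filter bins with zero counts or extreme GC (outside [0.28, 0.72]);
2. optionally correct GC bias by dividing each count by the median count of
   its GC decile (deciles computed over retained bins);
3. divide by the median corrected count and take log2, so the median
   retained log2 ratio is exactly 0.

A sample whose grid loses more than half of its bins to filtering fails QC:
scoring such a sample must produce an explicit "undetermined" (ND) verdict
rather than a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "BinGrid",
    "CoverageProfile",
    "QCError",
    "GridMismatchError",
    "build_grid",
    "read_bin_table",
    "normalize_counts",
]

GC_MIN, GC_MAX = 0.28, 0.72
MAX_FILTERED_FRACTION = 0.5


class QCError(RuntimeError):
    """Sample failed quality control (too many bins filtered)."""


class GridMismatchError(ValueError):
    """Bin table coordinates do not match the expected grid."""


@dataclass(frozen=True)
class BinGrid:
    """Arm-aware tiling of a genome at one window size.

    ``bins`` has one row per bin: chrom, arm, start, end, sorted by
    (chrom order of the genome model, start).
    """

    window_bp: int
    bins: pd.DataFrame

    def __len__(self) -> int:
        return len(self.bins)


@dataclass
class CoverageProfile:
    """Normalized per-bin log2 copy ratios plus the filter mask.

    ``table`` carries every grid bin with columns: chrom, arm, start, end,
    gc, count, retained (bool), filter_reason ("" for retained bins) and
    log2_ratio (NaN for filtered bins).
    """

    grid: BinGrid
    table: pd.DataFrame

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    def arm_values(self) -> dict[str, pd.DataFrame]:
        """Retained bins grouped by arm, in genomic order."""
        r = self.retained
        return {name: g for name, g in r.groupby("arm_name", sort=False)}


def build_grid(genome: GenomeModel, window_bp: int) -> BinGrid:
    """Tile every arm left to right with ``window_bp`` bins.

    Each arm gets ceil(arm_length / window_bp) bins; the final bin of an arm
    is truncated at the arm end, so no bin ever spans a centromere.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    if window_bp < 1000:
        raise ValueError(f"window_bp must be >= 1000, got {window_bp}")
    rows = []
    for arm in genome:
        starts = np.arange(arm.start, arm.end, window_bp)
        ends = np.minimum(starts + window_bp, arm.end)
        for s, e in zip(starts, ends):
            rows.append((arm.chrom, arm.arm, int(s), int(e)))
    bins = pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"])
    return BinGrid(window_bp, bins)


def read_bin_table(path: str | Path) -> pd.DataFrame:
    """Read a BED-style bin TSV (chrom, start, end, count, gc)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "count", "gc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if (df["count"] < 0).any():
        bad = df.index[df["count"] < 0][0]
        raise ValueError(f"{path}: negative count at line {bad + 2}")
    return df


def _check_grid(table: pd.DataFrame, grid: BinGrid) -> None:
    g = grid.bins
    if len(table) != len(g):
        raise GridMismatchError(
            f"bin table has {len(table)} rows, grid expects {len(g)}"
        )
    same = (
        (table["chrom"].to_numpy() == g["chrom"].to_numpy())
        & (table["start"].to_numpy() == g["start"].to_numpy())
        & (table["end"].to_numpy() == g["end"].to_numpy())
    )
    if not same.all():
        i = int(np.argmin(same))
        raise GridMismatchError(
            f"bin table/grid mismatch at row {i}: table has "
            f"{table['chrom'].iat[i]}:{table['start'].iat[i]}-{table['end'].iat[i]}, "
            f"grid expects {g['chrom'].iat[i]}:{g['start'].iat[i]}-{g['end'].iat[i]}"
        )


def normalize_counts(
    table: pd.DataFrame,
    grid: BinGrid,
    gc_correct: bool = True,
) -> CoverageProfile:
    """Normalize a raw bin-count table into a log2 copy-ratio profile.

    Raises :class:`QCError` when more than half of the bins are filtered
    and :class:`GridMismatchError` when the table does not match the grid.
    """
    _check_grid(table, grid)
    out = grid.bins.copy()
    out["arm_name"] = out["chrom"] + out["arm"]
    out["gc"] = table["gc"].to_numpy()
    out["count"] = table["count"].to_numpy()

    reason = np.full(len(out), "", dtype=object)
    zero = out["count"].to_numpy() == 0
    reason[zero] = "zero_count"
    gc = out["gc"].to_numpy()
    bad_gc = (~zero) & ((gc < GC_MIN) | (gc > GC_MAX))
    reason[bad_gc] = "gc_extreme"
    retained = reason == ""
    out["retained"] = retained
    out["filter_reason"] = reason

    frac_filtered = 1.0 - retained.mean()
    if frac_filtered > MAX_FILTERED_FRACTION:
        raise QCError(
            f"sample fails QC: {frac_filtered:.0%} of bins filtered "
            f"(limit {MAX_FILTERED_FRACTION:.0%})"
        )

    counts = out["count"].to_numpy().astype(float)
    corrected = counts.copy()
    if gc_correct:
        ranks = pd.Series(gc[retained]).rank(method="first")
        decile = np.ceil(ranks * 10 / len(ranks)).astype(int).clip(1, 10)
        med = pd.Series(counts[retained]).groupby(decile.to_numpy()).median()
        scale = decile.map(med).to_numpy()
        overall = np.median(counts[retained])
        corrected[retained] = counts[retained] / scale * overall

    ref = np.median(corrected[retained])
    log2_ratio = np.full(len(out), np.nan)
    log2_ratio[retained] = np.log2(corrected[retained] / ref)
    # re-center: the median of log2 is not exactly log2 of the median ratio
    log2_ratio[retained] -= np.median(log2_ratio[retained])
    out["log2_ratio"] = log2_ratio
    return CoverageProfile(grid, out)
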