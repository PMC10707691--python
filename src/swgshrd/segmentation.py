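"""Change-point segmentation, LGA counting and GIA integration.

The genomic-instability score counted here is the number of **large-scale
genomic alterations** (LGAs): copy-number breakpoints between two adjacent
segments of the *same* chromosome arm, each at least 10 Mb long, separated
by a log2-ratio step of at least ``delta``.  Centromeres never contribute a
breakpoint because segmentation is strictly per-arm.

Segmentation is exact penalized least squares: minimise over all
partitions of an arm's per-bin log2 ratios

    sum_over_segments( sum (x_i - segment mean)^2 )  +  beta * (#segments - 1)

with ``beta = penalty_scale * sigma^2 * log(n)`` and sigma a robust noise
estimate (Gaussian-scaled MAD of successive differences divided by sqrt 2).
The minimiser is found with PELT (pruned exact linear time), which returns
the same global optimum as O(n^2) optimal partitioning but prunes
candidates that can never win.

Per-sample scoring runs the window models (5 kb - 1 Mb tilings) and
integrates their LGA counts into a single **GIA** (genomic instability
assessment) as the rounded median; a model that fails coverage QC makes
the whole sample "undetermined" (ND).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import BinGrid, CoverageProfile, QCError, build_grid, normalize_counts
from .genome import GenomeModel

__all__ = [
    "LGAParams",
    "Segment",
    "SegmentSet",
    "GIAResult",
    "DEFAULT_WINDOWS",
    "pelt_changepoints",
    "segment_arm",
    "merge_segments",
    "count_lga",
    "integrate_models",
    "segment_profile",
    "score_sample",
]

logger = logging.getLogger(__name__)

#: default window models: six tilings spanning the 5 kb - 1 Mb range
DEFAULT_WINDOWS: tuple[int, ...] = (5_000, 25_000, 50_000, 100_000, 500_000, 1_000_000)


@dataclass(frozen=True)
class LGAParams:
    """Tunable constants of the LGA method.

    min_lga_len
        Minimum extent (bp) of both segments flanking a breakpoint for it to
        count as "large-scale"; 10 Mb is the defining scale of an LGA.
    delta
        Minimum absolute log2-ratio step of a counted breakpoint.
    merge_threshold
        Adjacent segments whose means differ by less than this are merged
        before counting (smoothing of spurious change-points).
    penalty_scale
        Multiplier on the sigma^2 * log(n) segmentation penalty; larger
        values give fewer change-points.
    """

    min_lga_len: int = 10_000_000
    delta: float = 0.25
    merge_threshold: float = 0.10
    penalty_scale: float = 3.0

    def __post_init__(self) -> None:
        if self.min_lga_len <= 0:
            raise ValueError("min_lga_len must be > 0")
        if not 0 < self.merge_threshold < self.delta:
            raise ValueError("require 0 < merge_threshold < delta")
        if self.penalty_scale <= 0:
            raise ValueError("penalty_scale must be > 0")


@dataclass(frozen=True)
class Segment:
    chrom: str
    arm: str
    start: int
    end: int
    mean: float
    n_bins: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def arm_name(self) -> str:
        return f"{self.chrom}{self.arm}"


@dataclass
class SegmentSet:
    """Ordered piecewise-constant segments, grouped per chromosome arm."""

    by_arm: dict[str, list[Segment]] = field(default_factory=dict)

    @property
    def segments(self) -> list[Segment]:
        return [s for arm in self.by_arm.values() for s in arm]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.chrom, s.start, s.end, s.mean, s.n_bins)
                for s in self.segments
            ],
            columns=["chrom", "start", "end", "mean_log2_ratio", "n_bins"],
        )


@dataclass
class GIAResult:
    """Integrated genomic-instability assessment for one sample."""

    per_model_lga: dict[int, int]
    gia: int | None
    status: str  # "OK" or "ND"
    model_status: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_model_lga": {str(k): v for k, v in self.per_model_lga.items()},
            "gia": self.gia,
            "status": self.status,
            "model_status": {str(k): v for k, v in self.model_status.items()},
        }


# ---------------------------------------------------------------------------
# exact penalized segmentation

def robust_sigma(x: np.ndarray) -> float:
    """Noise level from successive differences: Gaussian-scaled MAD / sqrt(2).

    Successive differences double the variance but cancel the piecewise-
    constant signal except at the (rare) change-points, which the median
    absorbs.
    """
    d = np.diff(np.asarray(x, dtype=float))
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


def _pelt_core(x: np.ndarray, beta: float) -> np.ndarray:
    """Optimal-partitioning recursion with PELT pruning; returns the
    predecessor array for backtracking.  Plain loops so numba can JIT it."""
    n = x.shape[0]
    S = np.empty(n + 1)
    S2 = np.empty(n + 1)
    S[0] = 0.0
    S2[0] = 0.0
    for i in range(n):
        S[i + 1] = S[i] + x[i]
        S2[i + 1] = S2[i] + x[i] * x[i]
    F = np.empty(n + 1)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=np.int64)
    cand = np.empty(n + 1, dtype=np.int64)
    cand[0] = 0
    m = 1
    tot = np.empty(n + 1)
    for t in range(1, n + 1):
        best = np.inf
        besti = 0
        for ci in range(m):
            s = cand[ci]
            d = S[t] - S[s]
            v = F[s] + (S2[t] - S2[s]) - d * d / (t - s)
            tot[ci] = v
            if v < best:  # strict: ties go to the leftmost candidate
                best = v
                besti = ci
        F[t] = best + beta
        prev[t] = cand[besti]
        k = 0
        for ci in range(m):
            if tot[ci] <= F[t]:
                cand[k] = cand[ci]
                k += 1
        cand[k] = t
        m = k + 1
    return prev


try:  # JIT when available; the pure-Python path is identical, only slower
    from numba import njit

    _pelt_core_fast = njit(cache=False)(_pelt_core)
except ImportError:  # pragma: no cover
    _pelt_core_fast = _pelt_core


def pelt_changepoints(x: np.ndarray, beta: float) -> list[int]:
    """Global minimiser of penalized squared-error segmentation cost.

    Returns the sorted inner change-point indices (a change-point at ``k``
    means segments split between ``x[k-1]`` and ``x[k]``).  PELT pruning
    keeps the exact optimal-partitioning recursion but discards candidates
    that can no longer be optimal; ties in the recursion go to the leftmost
    candidate, making the output fully deterministic.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = len(x)
    if n == 0:
        return []
    prev = _pelt_core_fast(x, float(beta))
    cps: list[int] = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            cps.append(s)
        t = s
    return cps[::-1]


def segment_arm(
    ratios: np.ndarray,
    params: LGAParams,
    *,
    chrom: str = "chr?",
    arm: str = "p",
    starts: np.ndarray | None = None,
    ends: np.ndarray | None = None,
) -> list[Segment]:
    """Segment one arm's ordered per-bin log2 ratios.

    ``starts``/``ends`` give each bin's genomic coordinates; when omitted,
    unit-width bins are assumed (useful for tests).  An arm with fewer than
    two bins is returned as a single trivial segment.
    """
    x = np.asarray(ratios, dtype=float)
    n = len(x)
    if n == 0:
        return []
    if starts is None:
        starts = np.arange(n, dtype=np.int64)
    if ends is None:
        ends = np.asarray(starts) + 1
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    if n < 2:
        logger.warning("%s%s: fewer than 2 retained bins, trivial segment", chrom, arm)
        cps: list[int] = []
    else:
        sigma = max(robust_sigma(x), 1e-8)
        beta = params.penalty_scale * sigma * sigma * math.log(n)
        cps = pelt_changepoints(x, beta)
    bounds = [0, *cps, n]
    return [
        Segment(
            chrom,
            arm,
            int(starts[a]),
            int(ends[b - 1]),
            float(x[a:b].mean()),
            b - a,
        )
        for a, b in zip(bounds, bounds[1:])
    ]


def merge_segments(segs: SegmentSet, params: LGAParams) -> SegmentSet:
    """Smooth a segmentation by merging near-equal neighbours.

    Repeatedly merges the adjacent same-arm pair with the smallest absolute
    mean difference while that difference is below ``merge_threshold``;
    the merged mean is the bin-count-weighted average.  Ties break to the
    leftmost pair.  Terminates because each merge removes one segment.
    """
    out: dict[str, list[Segment]] = {}
    for arm_name, arm_segs in segs.by_arm.items():
        cur = list(arm_segs)
        while len(cur) > 1:
            gaps = [abs(b.mean - a.mean) for a, b in zip(cur, cur[1:])]
            i = int(np.argmin(gaps))
            if gaps[i] >= params.merge_threshold:
                break
            a, b = cur[i], cur[i + 1]
            nb = a.n_bins + b.n_bins
            merged = Segment(
                a.chrom,
                a.arm,
                a.start,
                b.end,
                (a.mean * a.n_bins + b.mean * b.n_bins) / nb,
                nb,
            )
            cur[i : i + 2] = [merged]
        out[arm_name] = cur
    return SegmentSet(out)


def count_lga(segs: SegmentSet, params: LGAParams) -> int:
    """Count large-scale genomic alterations in a merged segmentation.

    A breakpoint counts iff both flanking segments lie on the same arm,
    both span at least ``min_lga_len``, and their means differ by at least
    ``delta``.  Arm boundaries (centromeres) are structurally excluded
    because segments never cross arms.
    """
    n = 0
    for arm_segs in segs.by_arm.values():
        for a, b in zip(arm_segs, arm_segs[1:]):
            if (
                a.length >= params.min_lga_len
                and b.length >= params.min_lga_len
                and abs(b.mean - a.mean) >= params.delta
            ):
                n += 1
    return n


def integrate_models(
    per_model_lga: dict[int, int],
    qc: dict[int, str] | None = None,
) -> GIAResult:
    """Integrate per-window LGA counts into the GIA score.

    GIA is the median of the per-model counts with half-integers rounded
    up.  If any model failed QC the sample is ND and no score is emitted.
    """
    qc = qc or {}
    if not per_model_lga and not any(s != "OK" for s in qc.values()):
        raise ValueError("integrate_models needs at least one model")
    status = {w: qc.get(w, "OK") for w in set(per_model_lga) | set(qc)}
    if any(s != "OK" for s in status.values()):
        return GIAResult(dict(per_model_lga), None, "ND", status)
    med = float(np.median(list(per_model_lga.values())))
    gia = int(math.floor(med + 0.5))
    return GIAResult(dict(per_model_lga), gia, "OK", status)


# ---------------------------------------------------------------------------
# per-sample orchestration

def segment_profile(profile: CoverageProfile, params: LGAParams) -> SegmentSet:
    """Segment every arm of a normalized coverage profile and merge."""
    raw: dict[str, list[Segment]] = {}
    for arm_name, bins in profile.arm_values().items():
        segs = segment_arm(
            bins["log2_ratio"].to_numpy(),
            params,
            chrom=bins["chrom"].iloc[0],
            arm=bins["arm"].iloc[0],
            starts=bins["start"].to_numpy(),
            ends=bins["end"].to_numpy(),
        )
        if segs:
            raw[arm_name] = segs
    return merge_segments(SegmentSet(raw), params)


def score_sample(
    tables: dict[int, pd.DataFrame],
    genome: GenomeModel,
    params: LGAParams = LGAParams(),
    gc_correct: bool = True,
    grids: dict[int, BinGrid] | None = None,
) -> tuple[GIAResult, dict[int, SegmentSet]]:
    """Run every window model on one sample's bin tables and integrate.

    ``tables`` maps window size (bp) to its raw bin table.  Returns the
    integrated :class:`GIAResult` plus the merged segmentation of each
    window model that passed QC.
    """
    if not tables:
        raise ValueError("score_sample needs at least one bin table")
    per_model: dict[int, int] = {}
    qc: dict[int, str] = {}
    segsets: dict[int, SegmentSet] = {}
    for window, table in sorted(tables.items()):
        grid = grids[window] if grids else build_grid(genome, window)
        try:
            prof = normalize_counts(table, grid, gc_correct=gc_correct)
        except QCError as exc:
            logger.warning("window %d failed QC: %s", window, exc)
            qc[window] = f"QC_FAIL: {exc}"
            continue
        segset = segment_profile(prof, params)
        segsets[window] = segset
        per_model[window] = count_lga(segset, params)
        qc[window] = "OK"
    return integrate_models(per_model, qc), segsets
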