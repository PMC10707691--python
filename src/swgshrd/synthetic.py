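"""Ground-truthed simulation of shallow-WGS copy-number data.

Real FFPE tumor sWGS data for HRD scoring cannot be redistributed, so every
stage of the pipeline is exercised on simulated data with a known answer.
The generator produces, per sample:

* a :class:`TruthProfile` — piecewise-constant copy-ratio segments per
  chromosome arm with an exactly known number of large-scale genomic
  alterations (LGAs: adjacent same-arm segments, both >=10 Mb, separated by
  a large copy-ratio step);
* binned read-count tables at any window size, modelling tumor-purity
  dilution, a smooth unimodal GC bias and negative-binomial (overdispersed)
  count noise.

Copy-ratio states are drawn from {0.5, 1.0, 1.5} — copy numbers 1/2/3 at a
diploid baseline — with adjacent segments always one state apart, so every
true breakpoint carries a log2 step of at least log2(1.5) ~ 0.585.  After
dilution at purity p the observed step log2((p*r2+1-p)/(p*r1+1-p)) stays at
or above the 0.25 detection threshold for any purity >= 0.4, which keeps the
truth recoverable over the purity range the assay is rated for.

A separate cohort simulator emulates the clinical layer (HRD class,
reference score band, exponential progression-free survival per class) for
the concordance and survival statistics.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Arm, GenomeModel

__all__ = [
    "SimulationConfig",
    "TruthSegment",
    "TruthProfile",
    "CapacityError",
    "simulate_truth_profile",
    "simulate_bin_counts",
    "simulate_sample",
    "simulate_cohort",
    "recount_lga",
    "write_bin_table",
    "write_truth",
    "read_truth",
]

logger = logging.getLogger(__name__)

#: copy-ratio states: copy numbers 1, 2, 3 over a diploid baseline
RATIO_STATES = (0.5, 1.0, 1.5)

#: truth segments are drawn with this much length margin over the 10 Mb LGA
#: floor so that bin-edge quantisation never pushes a flank under the floor
SEGMENT_MARGIN_BP = 2_000_000

MIN_WINDOW_BP = 5_000
MAX_WINDOW_BP = 1_000_000


class CapacityError(ValueError):
    """Requested more LGAs than the genome's arms can host."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the assay's rated operating range: 0.4-0.8x effective
    coverage, tumor purity 0.4-0.9, overdispersed counts (relative noise
    floor 1/sqrt(dispersion) ~ 22%), and a 20-patient cohort dominated by
    HRD-positive ovarian carcinomas with class-ordered mean PFS
    (HRD > HRM > HRN, means converted from 95.04 / 39.97 / 20.73 months at
    30.4375 days per month).
    """

    seed: int = 0
    n_samples: int = 20
    lga_target_range: tuple[int, int] = (0, 20)
    purity_range: tuple[float, float] = (0.4, 0.9)
    coverage_range: tuple[float, float] = (0.4, 0.8)
    dispersion: float = 20.0
    gc_bias_amplitude: float = 0.3
    censor_fraction: float = 0.2
    group_mean_pfs_days: dict[str, float] = field(
        default_factory=lambda: {"HRD": 2893.0, "HRM": 1217.0, "HRN": 631.0}
    )
    class_probs: dict[str, float] = field(
        default_factory=lambda: {"HRD": 0.65, "HRM": 0.20, "HRN": 0.15}
    )

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")
        for name, rng in (
            ("lga_target_range", self.lga_target_range),
            ("purity_range", self.purity_range),
            ("coverage_range", self.coverage_range),
        ):
            if len(rng) != 2 or rng[1] < rng[0]:
                raise ValueError(f"{name} must be a non-empty (lo, hi) range, got {rng}")
        if not 0 <= self.purity_range[0] and self.purity_range[1] <= 1:
            raise ValueError("purity_range must lie within [0, 1]")


@dataclass(frozen=True)
class TruthSegment:
    """One constant-copy-ratio stretch of an arm (chromosome coordinates)."""

    chrom: str
    arm: str
    start: int
    end: int
    ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthProfile:
    """Ground-truth copy-number profile of one simulated sample."""

    segments: list[TruthSegment]
    true_lga_count: int
    purity: float
    coverage: float
    seed: int

    def ratio_at(self, chrom: str, pos: int) -> float:
        for s in self.segments:
            if s.chrom == chrom and s.start <= pos < s.end:
                return s.ratio
        raise KeyError(f"no truth segment covers {chrom}:{pos}")


def recount_lga(
    segments: list[TruthSegment],
    min_lga_len: int = 10_000_000,
    delta: float = 0.25,
) -> int:
    """Recount LGAs from segments alone: adjacent same-arm pairs with both
    lengths >= ``min_lga_len`` and an absolute log2-ratio step >= ``delta``."""
    n = 0
    for a, b in zip(segments, segments[1:]):
        if (a.chrom, a.arm) != (b.chrom, b.arm):
            continue  # centromere or chromosome boundary
        if a.length >= min_lga_len and b.length >= min_lga_len:
            if abs(math.log2(b.ratio / a.ratio)) >= delta:
                n += 1
    return n


def _arm_capacity(arm: Arm, seg_min: int) -> int:
    return max(arm.length // seg_min - 1, 0)


def _partition_arm(rng: np.random.Generator, arm: Arm, k: int, seg_min: int) -> list[int]:
    """Split an arm into k+1 integer lengths, each >= seg_min, summing to
    the arm length; slack distributed by a flat Dirichlet."""
    n_seg = k + 1
    slack = arm.length - n_seg * seg_min
    if slack < 0:
        raise CapacityError(f"arm {arm.name} cannot hold {k} LGAs")
    w = rng.dirichlet(np.ones(n_seg))
    extra = np.floor(w * slack).astype(int)
    extra[-1] += slack - int(extra.sum())
    return [seg_min + int(e) for e in extra]


def _walk_states(rng: np.random.Generator, k: int) -> list[float]:
    """Random walk over RATIO_STATES starting at 1.0, one state per step."""
    idx = RATIO_STATES.index(1.0)
    out = [RATIO_STATES[idx]]
    for _ in range(k):
        if idx == 0:
            idx += 1
        elif idx == len(RATIO_STATES) - 1:
            idx -= 1
        else:
            idx += rng.choice((-1, 1))
        out.append(RATIO_STATES[idx])
    return out


def simulate_truth_profile(
    genome: GenomeModel,
    n_lga_target: int,
    seed: int,
    purity: float = 1.0,
    coverage: float = 0.6,
    min_lga_len: int = 10_000_000,
    n_focal: int = 0,
) -> TruthProfile:
    """Simulate a piecewise-constant copy-ratio profile with exactly
    ``n_lga_target`` large-scale genomic alterations.

    LGA breakpoints are allocated across arms at random (respecting each
    arm's capacity), segment lengths are drawn with a 2 Mb margin over the
    10 Mb floor, and ratios follow a one-state random walk, so every
    breakpoint is a bona fide LGA.  ``n_focal`` optional sub-10 Mb focal
    distractor events are inserted strictly inside long segments; they add
    breakpoints that must *not* be counted.

    Raises :class:`CapacityError` if the genome cannot host the target.
    """
    if n_lga_target < 0:
        raise ValueError("n_lga_target must be >= 0")
    if not 0 <= purity <= 1:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    rng = np.random.default_rng(seed)
    seg_min = min_lga_len + SEGMENT_MARGIN_BP

    capacities = {a: _arm_capacity(a, seg_min) for a in genome}
    budget = sum(capacities.values())
    if n_lga_target > budget:
        detail = ", ".join(f"{a.name}:{c}" for a, c in capacities.items())
        raise CapacityError(
            f"target of {n_lga_target} LGAs exceeds the genome's capacity of "
            f"{budget} (per-arm budget: {detail})"
        )

    # allocate breakpoints to arms uniformly among arms with spare capacity
    alloc = {a: 0 for a in genome}
    open_arms = [a for a in genome if capacities[a] > 0]
    for _ in range(n_lga_target):
        a = open_arms[rng.integers(len(open_arms))]
        alloc[a] += 1
        if alloc[a] == capacities[a]:
            open_arms.remove(a)

    segments: list[TruthSegment] = []
    for arm in genome:
        k = alloc[arm]
        if k == 0:
            segments.append(TruthSegment(arm.chrom, arm.arm, arm.start, arm.end, 1.0))
            continue
        lengths = _partition_arm(rng, arm, k, seg_min)
        ratios = _walk_states(rng, k)
        pos = arm.start
        for length, ratio in zip(lengths, ratios):
            segments.append(TruthSegment(arm.chrom, arm.arm, pos, pos + length, ratio))
            pos += length

    if n_focal > 0:
        segments = _insert_focal_events(rng, segments, n_focal, seg_min)

    count = recount_lga(segments, min_lga_len=min_lga_len)
    assert count == n_lga_target, "internal error: truth recount mismatch"
    return TruthProfile(segments, count, purity, coverage, seed)


def _insert_focal_events(
    rng: np.random.Generator,
    segments: list[TruthSegment],
    n_focal: int,
    seg_min: int,
) -> list[TruthSegment]:
    """Split long segments with short (<10 Mb) focal alterations that leave
    both flanks above the LGA length floor."""
    focal_len = 5_000_000
    out = list(segments)
    candidates = [i for i, s in enumerate(out) if s.length >= 2 * seg_min + focal_len]
    rng.shuffle(candidates)
    for i in candidates[:n_focal]:
        s = out[i]
        lo = s.start + seg_min
        hi = s.end - seg_min - focal_len
        fstart = int(rng.integers(lo, hi + 1))
        other = [r for r in RATIO_STATES if r != s.ratio]
        fratio = float(other[rng.integers(len(other))])
        out[i : i + 1] = [
            TruthSegment(s.chrom, s.arm, s.start, fstart, s.ratio),
            TruthSegment(s.chrom, s.arm, fstart, fstart + focal_len, fratio),
            TruthSegment(s.chrom, s.arm, fstart + focal_len, s.end, s.ratio),
        ]
    return out


def _gc_multiplier(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth unimodal GC bias, peaking at GC 0.5, unity at the range edges."""
    z = (gc - 0.5) / 0.2
    return 1.0 + amplitude * np.clip(1.0 - z * z, 0.0, None)


def simulate_bin_counts(
    profile: TruthProfile,
    genome: GenomeModel,
    window_bp: int,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a binned read-count table for one sample at one window size.

    The expected count of a bin is proportional to
    ``purity * ratio + (1 - purity)`` (tumor signal diluted by normal cells),
    scaled so that a flat diploid genome averages ``coverage * bin_length``
    and modulated by the GC bias curve; counts are negative-binomial with
    the configured dispersion (Poisson in the infinite-dispersion limit).
    """
    from .coverage import build_grid  # deferred: avoids import cycle at load

    if not MIN_WINDOW_BP <= window_bp <= MAX_WINDOW_BP:
        raise ValueError(
            f"window_bp must be in [{MIN_WINDOW_BP}, {MAX_WINDOW_BP}], got {window_bp}"
        )
    if window_bp > genome.min_arm_length:
        raise ValueError(
            f"window_bp {window_bp} exceeds the smallest arm ({genome.min_arm_length} bp)"
        )
    if not 0 <= profile.purity <= 1:
        raise ValueError(f"purity must be in [0, 1], got {profile.purity}")

    rng = np.random.default_rng(profile.seed if seed is None else seed)
    grid = build_grid(genome, window_bp)
    bins = grid.bins

    mids = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    ratio = np.empty(len(bins))
    chroms = bins["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        segs = [s for s in profile.segments if s.chrom == chrom]
        starts = np.array([s.start for s in segs])
        vals = np.array([s.ratio for s in segs])
        sel = chroms == chrom
        idx = np.searchsorted(starts, mids[sel], side="right") - 1
        ratio[sel] = vals[idx]
    rel = profile.purity * ratio + (1.0 - profile.purity)
    rel = rel / rel.mean()

    gc = 0.3 + 0.4 * rng.beta(5.0, 5.0, size=len(bins))
    mult = _gc_multiplier(gc, config.gc_bias_amplitude)
    mult = mult / mult.mean()

    lengths = (bins["end"] - bins["start"]).to_numpy()
    lam = profile.coverage * lengths * rel * mult

    if math.isinf(config.dispersion):
        counts = rng.poisson(lam)
    else:
        a = config.dispersion
        counts = rng.negative_binomial(a, a / (a + lam))

    return pd.DataFrame(
        {
            "chrom": bins["chrom"],
            "start": bins["start"],
            "end": bins["end"],
            "count": counts.astype(np.int64),
            "gc": np.round(gc, 6),
        }
    )


def simulate_sample(
    genome: GenomeModel,
    config: SimulationConfig,
    sample_index: int,
    windows: tuple[int, ...],
    n_lga_target: int | None = None,
) -> tuple[TruthProfile, dict[int, pd.DataFrame]]:
    """Simulate one sample end to end: truth profile plus one bin table per
    window size.  All randomness derives from ``(config.seed, sample_index)``."""
    ss = np.random.SeedSequence([config.seed, sample_index])
    states = ss.generate_state(2 + len(windows)) >> 1  # keep seeds < 2**31
    rng = np.random.default_rng(int(states[0]))
    if n_lga_target is None:
        lo, hi = config.lga_target_range
        n_lga_target = int(rng.integers(lo, hi + 1))
    purity = float(rng.uniform(*config.purity_range))
    coverage = float(rng.uniform(*config.coverage_range))
    profile = simulate_truth_profile(
        genome, n_lga_target, seed=int(states[1]), purity=purity, coverage=coverage
    )
    tables = {
        w: simulate_bin_counts(profile, genome, w, config, seed=int(s))
        for w, s in zip(windows, states[2:])
    }
    return profile, tables


# ---------------------------------------------------------------------------
# clinical cohort emulation

_GIA_RANGES = {"HRN": (0, 14), "HRM": (15, 19), "HRD": (20, 40)}
_REF_RANGES = {"HRN": (5, 42), "HRM": (43, 55), "HRD": (56, 100)}


def simulate_cohort(
    n: int,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the clinical cohort table.

    Each patient gets an HRD class (per ``config.class_probs``), a GIA score
    inside the class band, a reference score inside the matching commercial
    band (HRN <= 42, HRM 43-55, HRD >= 56), exponential PFS with the class
    mean and an independent censoring flag.  OS is PFS plus an exponential
    tail.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2 patients")
    if sum(p > 0 for p in config.class_probs.values()) < 2:
        raise ValueError("at least two classes must have nonzero allocation")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    classes = list(config.class_probs)
    probs = np.array([config.class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    rows = []
    for i in range(n):
        cls = classes[rng.choice(len(classes), p=probs)]
        gia = int(rng.integers(_GIA_RANGES[cls][0], _GIA_RANGES[cls][1] + 1))
        ref = int(rng.integers(_REF_RANGES[cls][0], _REF_RANGES[cls][1] + 1))
        pfs = float(rng.exponential(config.group_mean_pfs_days[cls]))
        os_days = pfs + float(rng.exponential(365.0))
        pfs_event = int(rng.random() >= config.censor_fraction)
        os_event = int(rng.random() >= config.censor_fraction)
        rows.append(
            {
                "sample_id": f"S{i + 1:03d}",
                "hrd_class": cls,
                "gia": gia,
                "ref_score": ref,
                "pfs_days": round(pfs, 1),
                "pfs_event": pfs_event,
                "os_days": round(os_days, 1),
                "os_event": os_event,
            }
        )
    df = pd.DataFrame(rows)
    if df["hrd_class"].nunique() == 1:
        logger.warning(
            "simulated cohort contains a single HRD class (%s); "
            "group comparisons downstream will be undefined",
            df["hrd_class"].iloc[0],
        )
    return df


# ---------------------------------------------------------------------------
# plain-text I/O

def write_bin_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a bin table as BED-style TSV (header, tabs, Unix newlines)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_truth(profile: TruthProfile, path: str | Path) -> None:
    payload = {
        "segments": [asdict(s) for s in profile.segments],
        "true_lga_count": profile.true_lga_count,
        "purity": profile.purity,
        "coverage": profile.coverage,
        "seed": profile.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_truth(path: str | Path) -> TruthProfile:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    segs = [TruthSegment(**s) for s in payload["segments"]]
    return TruthProfile(
        segs,
        payload["true_lga_count"],
        payload["purity"],
        payload["coverage"],
        payload["seed"],
    )
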