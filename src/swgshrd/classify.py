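"""HRD classification from GIA scores and commercial reference bands.

Three-class call from the integrated GIA (LGA-based) score:

* HRN (negative)   GIA <= 14
* HRM (mild)       15 <= GIA <= 19
* HRD (deficient)  GIA >= 20

Two-class call collapses HRM into HRD (positive iff GIA >= 15).  Reference
(Myriad-style, 0-100) scores are banded N <= 42 / M 43-55 / D >= 56, with
clinical positivity at score >= 42.  Note the deliberate overlap at exactly
42: the band edge puts 42 in N while the positivity cutoff calls it
positive; both facts are reported rather than silently reconciled.

An undetermined (ND) scoring verdict propagates through every classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ClassificationThresholds",
    "ND",
    "classify_three",
    "classify_two",
    "myriad_band",
    "classify_cohort",
]

ND = "ND"


@dataclass(frozen=True)
class ClassificationThresholds:
    """Band edges for the academic three-/two-class calls and the reference
    score; all bands are closed and exhaustive over their integer domain."""

    hrn_max: int = 14           # GIA <= hrn_max          -> HRN
    hrm_max: int = 19           # hrn_max < GIA <= hrm_max -> HRM, above -> HRD
    two_class_positive_min: int = 15
    myriad_n_max: int = 42      # score <= 42 -> band N
    myriad_m_max: int = 55      # 43-55 -> band M, >= 56 -> band D
    myriad_positive_cutoff: int = 42  # positive iff score >= 42

    def __post_init__(self) -> None:
        if not self.hrn_max < self.hrm_max:
            raise ValueError("require hrn_max < hrm_max")
        if self.two_class_positive_min != self.hrn_max + 1:
            raise ValueError(
                "two-class positive set must equal HRM u HRD "
                "(two_class_positive_min == hrn_max + 1)"
            )
        if not self.myriad_n_max < self.myriad_m_max:
            raise ValueError("require myriad_n_max < myriad_m_max")


DEFAULT_THRESHOLDS = ClassificationThresholds()


def _check_gia(gia) -> int | None:
    if gia is None or (isinstance(gia, str) and gia.upper() == ND):
        return None
    g = int(gia)
    if g < 0:
        raise ValueError(f"GIA must be >= 0, got {gia}")
    return g


def classify_three(gia, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS) -> str:
    """Three-class HRD call; ND (None or "ND") propagates unchanged."""
    g = _check_gia(gia)
    if g is None:
        return ND
    if g <= thresholds.hrn_max:
        return "HRN"
    if g <= thresholds.hrm_max:
        return "HRM"
    return "HRD"


def classify_two(gia, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS) -> str:
    """Two-class HRD call: positive (HRD) iff GIA >= 15; ND propagates.

    Identical to collapsing :func:`classify_three` (HRM -> HRD).
    """
    g = _check_gia(gia)
    if g is None:
        return ND
    return "HRD" if g >= thresholds.two_class_positive_min else "HRN"


def myriad_band(
    score: float, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
) -> tuple[str, bool]:
    """Band a reference (0-100) genomic-instability score.

    Returns ``(band, positive)`` with band in {"N", "M", "D"} and clinical
    positivity at score >= 42.  A score of exactly 42 is band N *and*
    positive; both are reported.
    """
    if not 0 <= score <= 100:
        raise ValueError(f"reference score must be in [0, 100], got {score}")
    if score <= thresholds.myriad_n_max:
        band = "N"
    elif score <= thresholds.myriad_m_max:
        band = "M"
    else:
        band = "D"
    return band, score >= thresholds.myriad_positive_cutoff


def classify_cohort(
    df: pd.DataFrame,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Classify a cohort table with columns sample_id, gia and optionally
    ref_score; emits sample_id, gia, class3, class2 (+ ref_band,
    ref_positive when reference scores are present)."""
    out = pd.DataFrame({"sample_id": df["sample_id"], "gia": df["gia"]})
    out["class3"] = [classify_three(g, thresholds) for g in df["gia"]]
    out["class2"] = [classify_two(g, thresholds) for g in df["gia"]]
    if "ref_score" in df.columns:
        bands = [myriad_band(s, thresholds) for s in df["ref_score"]]
        out["ref_score"] = df["ref_score"]
        out["ref_band"] = [b for b, _ in bands]
        out["ref_positive"] = [p for _, p in bands]
    return out
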