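"""Method-comparison statistics for categorical HRD calls and paired scores.

Implements the agreement toolbox used when benchmarking an academic HRD
assay against a reference: K x K contingency tables, Cohen's kappa with the
conventional interpretation scale (slight / fair / moderate / substantial /
almost perfect), percentage positive agreement (PPA), Spearman rank
correlation of the underlying numeric scores, and Fisher's exact test of
association.

Kappa is computed from first principles — kappa = (po - pe) / (1 - pe) —
with a p-value from the large-sample normal approximation of its standard
error under the null of chance agreement (the approximation is coarse for
small cohorts; the kappa itself is exact arithmetic).  Spearman and Fisher
delegate to scipy; scipy's two-sided Fisher rule (sum the probabilities of
all margin-fixed tables no more likely than the observed one) is the
convention used here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "KappaResult",
    "cohens_kappa",
    "interpret_kappa",
    "ppa",
    "spearman_rho",
    "fisher_exact",
    "compare_calls",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-classification of two raters' categorical calls.

    Rows are rater A's classes, columns rater B's, in the given label
    order.  For PPA the *last* label is taken as the positive class unless
    stated otherwise.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("contingency table is empty")
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match the count matrix")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @classmethod
    def from_calls(
        cls,
        a: list[str] | pd.Series,
        b: list[str] | pd.Series,
        labels: tuple[str, ...],
    ) -> "ContingencyTable":
        a = pd.Categorical(a, categories=labels)
        b = pd.Categorical(b, categories=labels)
        counts = pd.crosstab(a, b, dropna=False).reindex(
            index=labels, columns=labels, fill_value=0
        )
        return cls(counts.to_numpy(), tuple(labels), tuple(labels))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    interpretation: str
    p_value: float
    n: int


def interpret_kappa(kappa: float) -> str:
    """Conventional verbal scale for Cohen's kappa."""
    if kappa < 0:
        return "no agreement"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def cohens_kappa(t: ContingencyTable) -> KappaResult:
    """Chance-corrected agreement of a square contingency table.

    kappa = (po - pe) / (1 - pe), po the observed diagonal fraction and pe
    the chance agreement from the marginals.  The p-value tests kappa = 0
    with the large-sample null standard error.
    """
    c = t.counts
    if c.shape[0] != c.shape[1]:
        raise ValueError("kappa requires a square table")
    n = t.n
    if min((c.sum(axis=0) + c.sum(axis=1) > 0).sum(), c.shape[0]) < 2:
        raise ValueError("kappa requires at least two categories with mass")
    p = c / n
    po = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0:
        raise ValueError("degenerate table: chance agreement pe = 1, kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss null SE of kappa
    var0 = (pe + pe * pe - float(np.sum(row * col * (row + col)))) / (
        n * (1.0 - pe) ** 2
    )
    if var0 <= 0:
        p_value = float("nan")
    else:
        z = kappa / np.sqrt(var0)
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    return KappaResult(float(kappa), interpret_kappa(kappa), p_value, n)


def ppa(
    t: ContingencyTable,
    reference: str = "col",
    positive_label: str | None = None,
) -> float:
    """Percentage positive agreement as an exact fraction in [0, 1].

    Both-positive count divided by the reference rater's positive total;
    ``reference`` is "col" (rater B, the usual comparator) or "row".  The
    positive class defaults to the last label.
    """
    c = t.counts
    if c.shape != (2, 2):
        raise ValueError("PPA requires a 2x2 table")
    labels = t.col_labels if reference == "col" else t.row_labels
    pos = positive_label if positive_label is not None else labels[-1]
    i_row = t.row_labels.index(pos)
    i_col = t.col_labels.index(pos)
    both = int(c[i_row, i_col])
    ref_total = int(c[:, i_col].sum() if reference == "col" else c[i_row, :].sum())
    if ref_total == 0:
        raise ValueError("PPA undefined: reference rater has no positives")
    return both / ref_total


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of missing values.

    Ties receive average ranks; the p-value uses the t approximation.
    Constant input (after deletion) has no defined rank correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("Spearman needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    Sums hypergeometric probabilities (margins fixed) of every table no
    more probable than the observed one.
    """
    c = t.counts
    if c.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    _, p = stats.fisher_exact(c, alternative="two-sided")
    return float(p)


def compare_calls(
    df: pd.DataFrame,
    a_col: str,
    b_col: str,
    labels: tuple[str, ...],
    score_a: str | None = None,
    score_b: str | None = None,
) -> dict:
    """Full agreement report for two call columns of a cohort table.

    ND calls (either rater) are excluded with a logged count, mirroring
    how an undetermined sample must drop out of a method comparison.
    Numeric score columns, when given, add Spearman correlation.
    """
    nd_mask = df[a_col].eq("ND") | df[b_col].eq("ND")
    if nd_mask.any():
        logger.info("excluding %d ND sample(s) from the comparison", int(nd_mask.sum()))
    d = df[~nd_mask]
    if d.empty:
        raise ValueError("no samples left after excluding ND calls")
    table = ContingencyTable.from_calls(d[a_col], d[b_col], labels)
    report: dict = {
        "n": table.n,
        "n_excluded_nd": int(nd_mask.sum()),
        "labels": list(labels),
        "table": table.counts.tolist(),
    }
    # degenerate tables (e.g. an all-negative mini-cohort) make individual
    # statistics undefined; report the reason instead of a number
    try:
        kap = cohens_kappa(table)
        report["kappa"] = kap.kappa
        report["kappa_interpretation"] = kap.interpretation
        report["kappa_p_value"] = kap.p_value
    except ValueError as exc:
        report["kappa_error"] = str(exc)
    if len(labels) == 2:
        try:
            frac = ppa(table, reference="col")
            report["ppa"] = frac
            report["ppa_percent"] = round(100.0 * frac)
        except ValueError as exc:
            report["ppa_error"] = str(exc)
        report["fisher_p_value"] = fisher_exact(table)
    if score_a and score_b:
        rho, p = spearman_rho(d[score_a], d[score_b])
        report["spearman_rho"] = rho
        report["spearman_p_value"] = p
    return report
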