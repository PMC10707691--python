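"""Bundled reference data: a published 20-sample method-comparison cohort.

The package ships, as plain TSV, the cross-tabulated results of a published
20-patient ovarian-carcinoma comparison between an academic sWGS HRD assay
(run on two library chemistries, "R" and "W") and the commercial Myriad
myChoice reference:

* ``example_cohort.tsv`` — per-sample academic class (HRD-H / HRD-M /
  HRD-N, one sample ND for DNA quality), Myriad band letter and Myriad
  numeric score (0-100);
* ``agreement_r_vs_w.tsv`` — 3x3 cross-classification of the R and W
  three-class calls;
* ``agreement_r_vs_myriad.tsv`` / ``agreement_w_vs_myriad.tsv`` — 2x2
  cross-classifications of the two-class academic calls against Myriad
  positivity.

These tables drive worked examples and regression checks of the
concordance statistics against their published values (kappa 0.736 for
R vs W; 0.608 / 0.483 and PPA 94% / 88% against Myriad).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .concordance import ContingencyTable

__all__ = ["load_example_cohort", "load_agreement_table", "AGREEMENT_TABLES"]

AGREEMENT_TABLES = ("r_vs_w", "r_vs_myriad", "w_vs_myriad")


def _data_path(name: str):
    return resources.files("swgshrd.data").joinpath(name)


def load_example_cohort() -> pd.DataFrame:
    """The bundled 20-sample cohort (academic class, Myriad band + score)."""
    with _data_path("example_cohort.tsv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_agreement_table(name: str) -> ContingencyTable:
    """One of the bundled cross-classifications; ``name`` in
    ``AGREEMENT_TABLES``.  Rows are the first-named rater."""
    if name not in AGREEMENT_TABLES:
        raise KeyError(f"unknown agreement table {name!r}; choose from {AGREEMENT_TABLES}")
    with _data_path(f"agreement_{name}.tsv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    labels = tuple(df.columns)
    return ContingencyTable(df.to_numpy(), tuple(df.index), labels)
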