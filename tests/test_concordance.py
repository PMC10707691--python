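import itertools
import math

import numpy as np
import pandas as pd
import pytest

from swgshrd import (
    ContingencyTable,
    cohens_kappa,
    compare_calls,
    fisher_exact,
    interpret_kappa,
    load_agreement_table,
    ppa,
    spearman_rho,
)


def table(cells, labels):
    return ContingencyTable(np.array(cells), tuple(labels), tuple(labels))


def calls_from_table(t):
    """Expand a contingency table back into two call vectors."""
    a, b = [], []
    for i, ra in enumerate(t.row_labels):
        for j, cb in enumerate(t.col_labels):
            a += [ra] * t.counts[i, j]
            b += [cb] * t.counts[i, j]
    return a, b


def fisher_enumeration(c):
    """Exact two-sided Fisher p by full hypergeometric enumeration."""
    a, b = int(c[0, 0]), int(c[0, 1])
    cc, d = int(c[1, 0]), int(c[1, 1])
    n = a + b + cc + d
    r1, c1 = a + b, a + cc
    obs = math.comb(r1, a) * math.comb(n - r1, c1 - a)
    denom = math.comb(n, c1)
    total = 0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        pr = math.comb(r1, x) * math.comb(n - r1, c1 - x)
        if pr <= obs * (1 + 1e-7):  # same inclusion rule as scipy
            total += pr
    return total / denom


class TestKappa:
    def test_three_class_published_table(self):
        t = load_agreement_table("r_vs_w")
        res = cohens_kappa(t)
        assert res.kappa == pytest.approx(0.736, abs=5e-4)
        assert res.interpretation == "substantial"

    @pytest.mark.parametrize(
        "name,expected,interp",
        [
            ("r_vs_myriad", 0.608, "substantial"),
            ("w_vs_myriad", 0.483, "moderate"),
        ],
    )
    def test_two_class_published_tables(self, name, expected, interp):
        res = cohens_kappa(load_agreement_table(name))
        assert res.kappa == pytest.approx(expected, abs=5e-4)
        assert res.interpretation == interp

    def test_perfect_diagonal_is_one(self):
        res = cohens_kappa(table([[5, 0], [0, 5]], ["N", "P"]))
        assert res.kappa == pytest.approx(1.0)
        assert res.interpretation == "almost perfect"

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        for name in ("r_vs_w", "r_vs_myriad", "w_vs_myriad"):
            t = load_agreement_table(name)
            a, b = calls_from_table(t)
            assert cohens_kappa(t).kappa == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_label_permutation_invariance(self):
        t = load_agreement_table("r_vs_w")
        perm = [2, 0, 1]
        c = t.counts[np.ix_(perm, perm)]
        labels = tuple(t.row_labels[i] for i in perm)
        res = cohens_kappa(ContingencyTable(c, labels, labels))
        assert res.kappa == pytest.approx(cohens_kappa(t).kappa)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(table([[7, 0], [0, 0]], ["N", "P"]))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(
                ContingencyTable(np.array([[1, 2, 3], [4, 5, 6]]), ("a", "b"), ("x", "y", "z"))
            )

    def test_interpretation_scale(self):
        assert interpret_kappa(-0.1) == "no agreement"
        assert interpret_kappa(0.10) == "slight"
        assert interpret_kappa(0.30) == "fair"
        assert interpret_kappa(0.50) == "moderate"
        assert interpret_kappa(0.70) == "substantial"
        assert interpret_kappa(0.95) == "almost perfect"


class TestPPA:
    def test_published_values(self):
        assert ppa(load_agreement_table("r_vs_myriad")) == pytest.approx(16 / 17)
        assert ppa(load_agreement_table("w_vs_myriad")) == pytest.approx(15 / 17)
        assert round(100 * ppa(load_agreement_table("r_vs_myriad"))) == 94
        assert round(100 * ppa(load_agreement_table("w_vs_myriad"))) == 88

    def test_perfect_agreement(self):
        assert ppa(table([[3, 0], [0, 9]], ["HRN", "HRD"])) == 1.0

    def test_no_reference_positives_rejected(self):
        with pytest.raises(ValueError, match="no positives"):
            ppa(table([[3, 0], [2, 0]], ["HRN", "HRD"]))

    def test_row_reference(self):
        t = table([[2, 1], [1, 16]], ["HRN", "HRD"])
        assert ppa(t, reference="row") == pytest.approx(16 / 17)


class TestSpearman:
    def test_monotone(self):
        rho, _ = spearman_rho([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)

    def test_antitone(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_hand_ranked_oracle(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        # average ranks assigned by hand: x -> (1, 2.5, 2.5, 4), y -> (1, 3, 2, 4)
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 3.0, 2.0, 4.0])
        expect = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(expect, abs=1e-12)

    def test_missing_values_dropped_pairwise(self):
        rho, _ = spearman_rho([1, 2, 3, np.nan], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])


class TestFisher:
    def test_perfect_disagreement_enumeration(self):
        t = table([[0, 5], [5, 0]], ["N", "P"])
        # 2 / C(10,5) = 0.00793...
        assert fisher_exact(t) == pytest.approx(2 / math.comb(10, 5), rel=1e-9)
        assert fisher_exact(t) == pytest.approx(fisher_enumeration(t.counts), rel=1e-9)

    def test_no_association(self):
        assert fisher_exact(table([[1, 1], [1, 1]], ["N", "P"])) == pytest.approx(1.0)

    def test_published_table_matches_enumeration(self):
        t = table([[2, 1], [1, 16]], ["HRN", "HRD"])
        assert fisher_exact(t) == pytest.approx(fisher_enumeration(t.counts), rel=1e-9)

    @pytest.mark.parametrize("seed", range(30))
    def test_random_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            c = rng.integers(0, 11, size=(2, 2))
            if 0 < c.sum() <= 40 and c.sum(0).min() >= 0:
                break
        t = ContingencyTable(c, ("a", "b"), ("a", "b"))
        assert fisher_exact(t) == pytest.approx(fisher_enumeration(c), rel=1e-9)


class TestContingencyTable:
    def test_from_calls(self):
        a = ["HRN", "HRN", "HRD", "HRD", "HRD"]
        b = ["HRN", "HRD", "HRD", "HRD", "HRN"]
        t = ContingencyTable.from_calls(a, b, ("HRN", "HRD"))
        assert t.counts.tolist() == [[1, 1], [1, 2]]

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[0, 0], [0, 0]]), ("a", "b"), ("a", "b"))
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, -1], [0, 0]]), ("a", "b"), ("a", "b"))


def test_compare_calls_excludes_nd():
    df = pd.DataFrame(
        {
            "a": ["HRD", "HRN", "ND", "HRD"],
            "b": ["HRD", "HRN", "HRD", "HRD"],
            "sa": [20, 5, 18, 30],
            "sb": [60, 22, 50, 70],
        }
    )
    rep = compare_calls(df, "a", "b", ("HRN", "HRD"), score_a="sa", score_b="sb")
    assert rep["n"] == 3
    assert rep["n_excluded_nd"] == 1
    assert rep["kappa"] == pytest.approx(1.0)
    assert rep["ppa_percent"] == 100
    assert "spearman_rho" in rep
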