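"""Fisher combination, multiple-testing corrections, and correlation diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tiermeta.meta_genes import (
    adjust_pvalues,
    combine_disease_genes,
    correlate_pvalues,
    fisher_combine,
    select_significant,
)


def chi2_sf_even_df(x: float, df: int) -> float:
    """Closed-form survival function of chi-square with even df.

    P(X > x) = exp(-x/2) * sum_{j<df/2} (x/2)^j / j!  — independent log-space
    oracle for the Fisher combiner.
    """
    assert df % 2 == 0
    half = x / 2.0
    if half == 0.0:
        return 1.0
    total = 0.0
    term_log = -half  # log of exp(-x/2) * (x/2)^0 / 0!
    for j in range(df // 2):
        if j > 0:
            term_log += math.log(half) - math.log(j)
        total += math.exp(term_log)
    return total


class TestFisherCombine:
    def test_all_ones(self):
        stat, df, p = fisher_combine([1.0, 1.0, 1.0])
        assert stat == 0.0 and df == 6 and p == pytest.approx(1.0)

    def test_single_p_is_identity(self):
        _, df, p = fisher_combine([0.3])
        assert df == 2 and p == pytest.approx(0.3, rel=1e-12)

    def test_two_studies_closed_form(self):
        stat, df, p = fisher_combine([0.05, 0.05])
        assert stat == pytest.approx(11.98293, abs=1e-5)
        assert df == 4
        assert p == pytest.approx(math.exp(-stat / 2) * (1 + stat / 2), rel=1e-12)
        assert p == pytest.approx(0.0174787, abs=1e-7)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=10)
    )
    def test_matches_log_space_oracle(self, p_list):
        stat, df, p = fisher_combine(p_list)
        assert p == pytest.approx(chi2_sf_even_df(stat, df), rel=1e-12, abs=1e-300)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=0.99), min_size=2, max_size=6),
        st.integers(min_value=0, max_value=5),
    )
    def test_decreasing_any_p_decreases_combined(self, p_list, idx):
        idx %= len(p_list)
        _, _, p_before = fisher_combine(p_list)
        smaller = list(p_list)
        smaller[idx] = smaller[idx] / 2.0
        _, _, p_after = fisher_combine(smaller)
        assert p_after < p_before

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_combine([])
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            fisher_combine([1.5])


class TestAdjustPvalues:
    def test_bh_step_up_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04] * 4
        )

    def test_by_harmonic_factor_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "by"), [0.04 * 25 / 12] * 4
        )

    def test_bonferroni_m1_identity(self):
        np.testing.assert_allclose(adjust_pvalues([1e-4], "bonferroni"), [1e-4])

    def test_none_is_identity_and_order_preserved(self):
        p = [0.5, 0.01, 0.2]
        np.testing.assert_array_equal(adjust_pvalues(p, "none"), p)
        adj = adjust_pvalues(p, "bonferroni")
        np.testing.assert_allclose(adj, [1.0, 0.03, 0.6])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([-0.1], "bh")
        with pytest.raises(ValueError):
            adjust_pvalues([1.1], "bonferroni")
        with pytest.raises(ValueError, match="unknown correction"):
            adjust_pvalues([0.5], "holm")

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_correction_ordering_nested(self, p):
        # provable dominance relations: BY/bonferroni both dominate BH,
        # BH dominates raw (bonferroni vs BY is not ordered elementwise —
        # BY's harmonic factor makes it the stricter one at top ranks)
        raw = np.asarray(p)
        bh = adjust_pvalues(p, "bh")
        by = adjust_pvalues(p, "by")
        bonf = adjust_pvalues(p, "bonferroni")
        assert (bonf >= bh - 1e-12).all()
        assert (by >= bh - 1e-12).all()
        assert (bh >= raw - 1e-12).all()
        c_m = sum(1.0 / i for i in range(1, len(p) + 1))
        np.testing.assert_allclose(
            by, np.minimum(1.0, np.asarray(bh) * c_m), rtol=1e-10, atol=1e-300
        )


class TestCorrelatePvalues:
    def test_hand_computed_r(self):
        vecs = {
            "a": pd.Series([1.0, 2.0, 3.0], index=["g1", "g2", "g3"]),
            "b": pd.Series([1.0, 3.0, 2.0], index=["g1", "g2", "g3"]),
        }
        row = correlate_pvalues(vecs).iloc[0]
        assert row["pearson_r"] == pytest.approx(0.5)
        assert not row["flagged"]  # r=0.5 but n=3 -> test p large

    def test_perfect_anticorrelation(self):
        vecs = {
            "a": pd.Series([1.0, 2.0, 3.0], index=["g1", "g2", "g3"]),
            "b": pd.Series([3.0, 2.0, 1.0], index=["g1", "g2", "g3"]),
        }
        row = correlate_pvalues(vecs).iloc[0]
        assert row["pearson_r"] == pytest.approx(-1.0)

    def test_identical_long_vectors_flagged(self):
        s = pd.Series(np.linspace(0.01, 0.99, 30), index=[f"g{i}" for i in range(30)])
        row = correlate_pvalues({"a": s, "b": s}).iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["flagged"]

    def test_constant_vector_unflagged_with_warning(self, caplog):
        vecs = {
            "a": pd.Series([0.5, 0.5, 0.5], index=["g1", "g2", "g3"]),
            "b": pd.Series([0.1, 0.2, 0.3], index=["g1", "g2", "g3"]),
        }
        with caplog.at_level("WARNING"):
            row = correlate_pvalues(vecs).iloc[0]
        assert np.isnan(row["pearson_r"]) and not row["flagged"]
        assert any("constant" in r.message for r in caplog.records)

    def test_intersection_only_and_too_small_overlap(self):
        vecs = {
            "a": pd.Series([1.0, 2.0], index=["g1", "g2"]),
            "b": pd.Series([1.0, 2.0], index=["g3", "g4"]),
        }
        with pytest.raises(ValueError, match="shares only"):
            correlate_pvalues(vecs)


def _stats_table(p_by_gene):
    return pd.DataFrame({"gene": list(p_by_gene), "p": list(p_by_gene.values())})


class TestCombineDiseaseGenes:
    def test_single_study_identity(self):
        table = _stats_table({"g1": 0.3, "g2": 0.01})
        meta, diag = combine_disease_genes({"S1": table}, "D1")
        got = meta.set_index("gene")
        assert got.loc["g1", "combined_p"] == pytest.approx(0.3, rel=1e-9)
        assert got.loc["g1", "k"] == 1 and got.loc["g1", "df"] == 2
        assert diag.empty

    def test_gene_available_in_subset_of_studies(self):
        tables = {
            "S1": _stats_table({"g1": 0.5, "g2": 0.5, "g3": 0.5, "g4": 0.5}),
            "S2": _stats_table({"g1": 0.5, "g2": 0.5, "g3": 0.5, "g4": 0.5}),
            "S3": _stats_table({"g1": 0.5, "g2": 0.5, "g3": 0.5}),
        }
        meta, _ = combine_disease_genes(tables, "D1")
        got = meta.set_index("gene")
        assert got.loc["g4", "k"] == 2 and got.loc["g4", "df"] == 4
        assert got.loc["g1", "k"] == 3 and got.loc["g1", "df"] == 6

    def test_null_combined_pvalues_uniform(self):
        from scipy import stats as ss

        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(2000)]
        tables = {
            f"S{j}": pd.DataFrame({"gene": genes, "p": rng.uniform(size=2000)})
            for j in range(3)
        }
        meta, _ = combine_disease_genes(tables, "D1")
        assert ss.kstest(meta["combined_p"], "uniform").pvalue > 0.01

    def test_adjusted_columns_ordering(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(100)]
        tables = {"S1": pd.DataFrame({"gene": genes, "p": rng.uniform(size=100)})}
        meta, _ = combine_disease_genes(tables, "D1")
        assert (meta["p_bonferroni"] >= meta["p_bh"] - 1e-12).all()
        assert (meta["p_by"] >= meta["p_bh"] - 1e-12).all()
        assert (meta["p_bh"] >= meta["combined_p"] - 1e-12).all()


class TestSelectSignificant:
    def _meta(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        p = rng.uniform(size=200) ** 3  # skew small
        meta, _ = combine_disease_genes(
            {"S1": pd.DataFrame({"gene": genes, "p": p})}, "D1"
        )
        return meta

    def test_threshold_is_strict(self):
        meta = pd.DataFrame(
            {"gene": ["a", "b"], "p_bh": [0.04, 0.06]}
        )
        assert select_significant(meta, "bh") == {"a"}

    def test_alpha_zero_selects_nothing(self):
        assert select_significant(self._meta(), "none", alpha=0.0) == frozenset()

    def test_nesting_across_corrections(self):
        meta = self._meta()
        sel = {c: select_significant(meta, c) for c in ("bonferroni", "by", "bh", "none")}
        assert sel["by"] <= sel["bh"] <= sel["none"]
        assert sel["bonferroni"] <= sel["bh"]

    def test_unknown_correction_errors(self):
        with pytest.raises(ValueError):
            select_significant(self._meta(), "holm")
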