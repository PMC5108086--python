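"""Permutation-null priors, minimum Bayes factors, minimum posteriors."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from tiermeta.bayes import (
    NullRunMatrix,
    average_null,
    calibrate_pathways,
    estimate_priors,
    generate_null_distributions,
    min_bf_chisq,
    min_bf_p,
    min_posterior,
)
from tiermeta.enrichment import filter_collection
from tiermeta.simulate import SimulationConfig, generate_collection, generate_null_cohort


@pytest.fixture(scope="module")
def null_setup():
    cfg = SimulationConfig(n_genes=400, n_pathways=8, pathway_size_range=(10, 20),
                           seed=21)
    collection = filter_collection(generate_collection(cfg))
    cohort = generate_null_cohort(n_samples=40, n_genes=400, seed=22)
    return cohort, collection


class TestNullDistributions:
    def test_shape_and_reproducibility(self, null_setup):
        cohort, collection = null_setup
        a = generate_null_distributions(cohort, collection, R=5, seed=9)
        b = generate_null_distributions(cohort, collection, R=5, seed=9)
        assert a.runs.shape == (5, len(collection))
        pd.testing.assert_frame_equal(a.runs, b.runs)

    def test_per_run_gene_selection_near_alpha(self, null_setup):
        """Random relabeling of a null cohort selects ~5% of genes per run."""
        cohort, collection = null_setup
        from tiermeta.diffexpr import fit_moderated_t, preprocess
        from tiermeta.io import ExpressionStudy

        rng = np.random.default_rng(1)
        fracs = []
        base = preprocess(cohort)
        n = len(base.samples)
        for _ in range(20):
            perm = rng.permutation(n)
            labels = np.where(np.isin(np.arange(n), perm[: n // 2]), "case", "control")
            st = ExpressionStudy(base.study_id, base.disease_id, list(base.genes),
                                 list(base.samples), base.values, labels.tolist())
            de = fit_moderated_t(st)
            fracs.append(float((de["p"] < 0.05).mean()))
        assert 0.02 < np.mean(fracs) < 0.08

    def test_minimum_run_count(self, null_setup):
        cohort, collection = null_setup
        with pytest.raises(ValueError, match="R = 2"):
            generate_null_distributions(cohort, collection, R=1, seed=0)
        ok = generate_null_distributions(cohort, collection, R=2, seed=0)
        assert ok.n_runs == 2

    def test_labeled_cohort_rejected(self, null_setup, tiny_study):
        _, collection = null_setup
        with pytest.raises(ValueError, match="unlabeled"):
            generate_null_distributions(tiny_study, collection, R=2, seed=0)


class TestPriors:
    def _matrix(self):
        runs = pd.DataFrame({
            "pw_a": [0.01] * 7 + [0.5] * 93,     # significant in 7/100 runs
            "pw_b": [0.5] * 100,                 # never significant
            "pw_c": [0.01] * 100,                # always significant
        })
        return NullRunMatrix(runs=runs)

    def test_counting_and_clamps(self):
        q = estimate_priors(self._matrix())
        assert q["pw_a"] == pytest.approx(0.07)
        assert q["pw_b"] == pytest.approx(0.005)  # clamped up from 0
        assert q["pw_c"] == pytest.approx(0.995)  # clamped down from 1

    def test_average_null_per_pathway(self):
        nm = NullRunMatrix(runs=pd.DataFrame({"pw": [0.2, 0.4, 0.6]}))
        assert average_null(nm)["pw"] == pytest.approx(0.4)

    def test_average_null_pooled_option(self):
        nm = NullRunMatrix(runs=pd.DataFrame({"a": [0.2, 0.4], "b": [0.1, 0.3]}))
        pooled = average_null(nm, pooled=True)
        np.testing.assert_allclose(pooled, [0.1, 0.2, 0.3, 0.4])

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            NullRunMatrix(runs=pd.DataFrame({"pw": [0.5]}))  # R=1
        with pytest.raises(ValueError):
            NullRunMatrix(runs=pd.DataFrame({"pw": [0.0, 0.5]}))  # p=0


class TestMinimumBayesFactors:
    def test_p_value_form_examples(self):
        assert min_bf_p(1 / math.e) == pytest.approx(1.0, rel=1e-12)
        # direct evaluation of -e * p * ln p at p = 0.05
        assert min_bf_p(0.05) == pytest.approx(-math.e * 0.05 * math.log(0.05),
                                               rel=1e-12)
        assert min_bf_p(0.05) == pytest.approx(0.4071622, abs=1e-6)
        assert min_bf_p(0.5) == 1.0

    def test_p_value_form_errors(self):
        with pytest.raises(ValueError):
            min_bf_p(0.0)
        with pytest.raises(ValueError):
            min_bf_p(1.5)

    def test_chisq_form_examples(self):
        assert min_bf_chisq(10, 10) == 1.0
        assert min_bf_chisq(10, 2) == pytest.approx(5 * math.exp(-4), rel=1e-12)
        assert min_bf_chisq(10, 2) == pytest.approx(0.0915782, abs=1e-6)
        assert min_bf_chisq(1, 2) == 1.0

    def test_chisq_log_space_matches_direct(self):
        for x in [5.0, 20.0, 100.0]:
            for v in [2.0, 4.0, 16.0]:
                direct = (v / x) ** (-v / 2) * math.exp(-(x - v) / 2) if x > v else 1.0
                assert min_bf_chisq(x, v) == pytest.approx(direct, rel=1e-12)

    def test_chisq_decreasing_in_x_beyond_v(self):
        xs = np.linspace(4.1, 60, 100)
        bf = min_bf_chisq(xs, 4.0)
        assert (np.diff(bf) < 0).all()

    def test_chisq_errors(self):
        with pytest.raises(ValueError):
            min_bf_chisq(10, 0)
        with pytest.raises(ValueError):
            min_bf_chisq(-1, 2)

    def test_sellke_bound_matches_numeric_minimization(self):
        """-e*p*ln p is the minimum over the beta-family alternatives of the
        Bayes factor; check against direct numeric minimization of
        p -> xi * p^(xi-1) likelihood ratio bound."""
        for p in [0.001, 0.01, 0.05, 0.1, 0.2]:
            # BF(xi) = 1 / (xi * p^(xi - 1)); minimize over xi in (0, 1)
            res = optimize.minimize_scalar(
                lambda xi: 1.0 / (xi * p ** (xi - 1.0)),
                bounds=(1e-9, 1.0), method="bounded",
                options={"xatol": 1e-12},
            )
            assert min_bf_p(p) == pytest.approx(res.fun, abs=1e-9)


class TestMinPosterior:
    def test_even_odds(self):
        assert min_posterior(1.0, 0.5) == pytest.approx(0.5)

    def test_worked_examples(self):
        bf = min_bf_p(0.05)
        assert min_posterior(bf, 0.5) == pytest.approx(bf / (1 + bf), rel=1e-12)
        odds = 0.1 * (0.05 / 0.95)
        assert min_posterior(0.1, 0.05) == pytest.approx(odds / (1 + odds), rel=1e-9)
        assert min_posterior(0.1, 0.05) == pytest.approx(0.0052356, abs=1e-6)

    def test_bf_one_returns_prior(self):
        for q in [0.1, 0.5, 0.9]:
            assert min_posterior(1.0, q) == pytest.approx(q, rel=1e-12)

    def test_monotone_in_both_arguments(self):
        bf = np.linspace(0.01, 1.0, 30)
        post_bf = min_posterior(bf, 0.3)
        assert (np.diff(post_bf) > 0).all()
        q = np.linspace(0.01, 0.99, 30)
        post_q = min_posterior(0.4, q)
        assert (np.diff(post_q) > 0).all()

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            min_posterior(0.5, 0.0)
        with pytest.raises(ValueError):
            min_posterior(0.5, 1.0)


class TestCalibratePathways:
    def _shared(self):
        shared = pd.DataFrame(
            {
                "D1": [0.5, 0.01],
                "D2": [0.001, 0.02],
                "chi2_stat": [15.0, 12.0],
                "df": [4, 4],
            },
            index=pd.Index(["pw_a", "pw_b"], name="pathway"),
        )
        return shared

    def test_bf_one_leaves_posterior_at_prior(self):
        priors = pd.Series({"pw_a": 0.07, "pw_b": 0.05})
        out = calibrate_pathways(self._shared(), ["D1", "D2"], priors)
        row = out[(out["pathway"] == "pw_a") & (out["scope"] == "D1")].iloc[0]
        assert row["bf"] == 1.0  # p = 0.5 >= 1/e
        assert row["min_posterior"] == pytest.approx(0.07)

    def test_combined_scope_uses_chisq_form(self):
        priors = pd.Series({"pw_a": 0.07, "pw_b": 0.05})
        out = calibrate_pathways(self._shared(), ["D1", "D2"], priors)
        row = out[(out["pathway"] == "pw_a") & (out["scope"] == "combined")].iloc[0]
        assert row["bf"] == pytest.approx(min_bf_chisq(15.0, 4.0), rel=1e-12)

    def test_smaller_p_gives_smaller_posterior_at_fixed_prior(self):
        priors = pd.Series({"pw_a": 0.07, "pw_b": 0.07})
        out = calibrate_pathways(self._shared(), ["D1", "D2"], priors)
        d2 = out[out["scope"] == "D2"].set_index("pathway")
        assert d2.loc["pw_a", "min_posterior"] < d2.loc["pw_b", "min_posterior"]

    def test_missing_prior_errors(self):
        with pytest.raises(ValueError, match="missing prior"):
            calibrate_pathways(self._shared(), ["D1", "D2"],
                               pd.Series({"pw_a": 0.07}))
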