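"""Pairwise interaction fitting: closed form vs reference, GLM, scan engine."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from epinet.epistasis import (

    count_pairs,
    fit_pair_bidirectional,
    fit_pair_glm,
    fit_pair_linear,
    run_all_pairs,
    runtime_probe,
)



def _random_instance(rng, n=50, binary=False):
    gi = rng.binomial(2, rng.uniform(0.15, 0.5), size=n).astype(float)
    gj = rng.binomial(2, rng.uniform(0.15, 0.5), size=n).astype(float)
    eta = rng.normal() + rng.normal() * gi + rng.normal() * gj \
        + rng.normal() * gi * gj
    if binary:
        y = (eta + rng.normal(size=n) > np.median(eta)).astype(float)
    else:
        y = eta + rng.normal(size=n)
    return y, gi, gj


class TestFitPairLinear:
    def test_noiseless_interpolation_recovers_coefficients(self):
        rng = np.random.default_rng(0)
        gi = rng.binomial(2, 0.4, size=60).astype(float)
        gj = rng.binomial(2, 0.3, size=60).astype(float)
        y = 0.5 + 1.0 * gi + 0.0 * gj + 2.0 * gi * gj
        r = fit_pair_linear(y, gi, gj)
        assert r.status == "ok"
        np.testing.assert_allclose(
            [r.mu, r.beta1, r.beta2, r.beta3], [0.5, 1.0, 0.0, 2.0], atol=1e-10
        )
        assert r.p3 <= 1e-250  # exact fit: p at the floor

    def test_constant_locus_is_degenerate(self):
        rng = np.random.default_rng(1)
        gi = rng.binomial(2, 0.4, size=40).astype(float)
        gj = np.ones(40)
        r = fit_pair_linear(rng.normal(size=40), gi, gj)
        assert r.status == "degenerate"
        assert np.isnan(r.p3)

    def test_matches_reference_ols(self):
        """Closed-form normal equations vs statsmodels on random instances."""
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 200:
            y, gi, gj = _random_instance(rng)
            X = np.column_stack([np.ones_like(gi), gi, gj, gi * gj])
            if np.linalg.matrix_rank(X) < 4:
                continue
            r = fit_pair_linear(y, gi, gj)
            ref = sm.OLS(y, X).fit()
            np.testing.assert_allclose(
                [r.mu, r.beta1, r.beta2, r.beta3], ref.params, rtol=1e-8
            )
            np.testing.assert_allclose(r.se3, ref.bse[3], rtol=1e-8)
            np.testing.assert_allclose(r.p3, ref.pvalues[3], rtol=1e-6)
            checked += 1

    def test_casewise_deletion_matches_complete_subset(self):
        rng = np.random.default_rng(3)
        y, gi, gj = _random_instance(rng, n=80)
        gi_m, y_m = gi.copy(), y.copy()
        gi_m[:10] = np.nan
        y_m[75:] = np.nan
        r = fit_pair_linear(y_m, gi_m, gj)
        keep = slice(10, 75)
        ref = fit_pair_linear(y[keep], gi[keep], gj[keep])
        assert r.n_used == 65
        np.testing.assert_allclose(r.beta3, ref.beta3, rtol=1e-12)
        np.testing.assert_allclose(r.p3, ref.p3, rtol=1e-12)

    def test_symmetry_in_locus_order(self):
        rng = np.random.default_rng(4)
        y, gi, gj = _random_instance(rng)
        a = fit_pair_linear(y, gi, gj)
        b = fit_pair_linear(y, gj, gi)
        np.testing.assert_allclose(a.beta3, b.beta3, rtol=1e-10)
        np.testing.assert_allclose(a.p3, b.p3, rtol=1e-10)
        np.testing.assert_allclose([a.beta1, a.beta2], [b.beta2, b.beta1], rtol=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        y, gi, gj = _random_instance(rng)
        a = fit_pair_linear(y, gi, gj)
        b = fit_pair_linear(3.7 * y, gi, gj)
        np.testing.assert_allclose(b.beta3, 3.7 * a.beta3, rtol=1e-10)
        np.testing.assert_allclose(b.p3, a.p3, rtol=1e-10)


class TestFitPairGLM:
    def test_matches_reference_probit(self):
        rng = np.random.default_rng(6)
        checked = 0
        while checked < 40:
            y, gi, gj = _random_instance(rng, n=300, binary=True)
            X = np.column_stack([np.ones_like(gi), gi, gj, gi * gj])
            if np.linalg.matrix_rank(X) < 4:
                continue
            r = fit_pair_glm(y, gi, gj, link="probit")
            if r.status != "ok":
                continue
            ref = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit())).fit(tol=1e-12, maxiter=200)
            np.testing.assert_allclose(
                [r.mu, r.beta1, r.beta2, r.beta3], ref.params, rtol=1e-6, atol=1e-8
            )
            np.testing.assert_allclose(r.p3, ref.pvalues[3], rtol=1e-4, atol=1e-10)
            checked += 1

    def test_matches_reference_logit(self):
        rng = np.random.default_rng(7)
        y, gi, gj = _random_instance(rng, n=400, binary=True)
        r = fit_pair_glm(y, gi, gj, link="logit")
        X = np.column_stack([np.ones_like(gi), gi, gj, gi * gj])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            [r.mu, r.beta1, r.beta2, r.beta3], ref.params, rtol=1e-6, atol=1e-8
        )

    def test_zero_interaction_column_degenerate(self):
        rng = np.random.default_rng(8)
        gi = np.array([0.0, 1, 0, 1] * 25)
        gj = np.array([1.0, 0, 1, 0] * 25)  # gi*gj identically zero
        y = rng.integers(0, 2, size=100).astype(float)
        r = fit_pair_glm(y, gi, gj)
        assert r.status == "degenerate"

    def test_single_class_phenotype_raises(self):
        gi = np.array([0.0, 1, 2, 1] * 10)
        with pytest.raises(ValueError, match="single class"):
            fit_pair_glm(np.ones(40), gi, gi[::-1])

    def test_covariates_enter_design(self):
        rng = np.random.default_rng(9)
        n = 600
        gi = rng.binomial(2, 0.4, size=n).astype(float)
        gj = rng.binomial(2, 0.3, size=n).astype(float)
        cov = rng.normal(size=n)
        liab = 2.0 * cov + 0.5 * gi * gj + rng.normal(size=n)
        y = (liab > 0).astype(float)
        r_with = fit_pair_glm(y, gi, gj, covariates=cov)
        X = np.column_stack([np.ones(n), gi, gj, gi * gj, cov])
        ref = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit())).fit(tol=1e-12, maxiter=200)
        np.testing.assert_allclose(r_with.beta3, ref.params[3], rtol=1e-6)


class TestBidirectional:
    def test_reversed_construction_reported_in_reversed_orientation(self):
        rng = np.random.default_rng(10)
        gi = rng.binomial(2, 0.4, size=100).astype(float)
        gj = rng.binomial(2, 0.4, size=100).astype(float)
        y = gi * (2.0 - gj)
        r = fit_pair_bidirectional(y, gi, gj)
        assert r.encoding_used == "minor_reversed_j"
        assert r.beta3 == pytest.approx(1.0, abs=1e-10)
        assert r.p3 <= 1e-250

    def test_standard_orientation_kept_for_planted_standard_effect(self):
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            gi = rng.binomial(2, 0.3, size=500).astype(float)
            gj = rng.binomial(2, 0.4, size=500).astype(float)
            y = 1.0 * gi * gj + rng.normal(size=500)
            r = fit_pair_bidirectional(y, gi, gj)
            wins += r.encoding_used == "minor_dominant"
        assert wins >= 47

    def test_analytic_reversal_equals_explicit_refit(self):
        """The reversed parameterization must equal actually refitting on 2-gj."""
        rng = np.random.default_rng(11)
        gi = rng.binomial(2, 0.4, size=200).astype(float)
        gj = rng.binomial(2, 0.3, size=200).astype(float)
        y = -0.8 * gi * gj + rng.normal(size=200)  # negative effect: reversal wins
        r = fit_pair_bidirectional(y, gi, gj)
        assert r.encoding_used == "minor_reversed_j"
        explicit = fit_pair_linear(y, gi, 2.0 - gj)
        np.testing.assert_allclose(
            [r.mu, r.beta1, r.beta2, r.beta3],
            [explicit.mu, explicit.beta1, explicit.beta2, explicit.beta3],
            rtol=1e-9,
        )
        np.testing.assert_allclose(r.p3, explicit.p3, rtol=1e-9)

    def test_gradient_scheme_single_orientation(self):
        rng = np.random.default_rng(12)
        gi = rng.choice([1.0, 1.5, 2.0], size=100)
        gj = rng.choice([1.0, 1.5, 2.0], size=100)
        y = -2.0 * gi * gj + rng.normal(size=100)
        r = fit_pair_bidirectional(y, gi, gj, base_scheme="gradient")
        assert r.encoding_used == "gradient"
        assert r.beta3 < 0  # sign preserved: no relabelling under gradient


class TestRunAllPairs:
    def test_three_variants_give_three_pairs(self, hwe_dosages, make_table):
        g = make_table(hwe_dosages(50, 3, seed=30))
        tbl = run_all_pairs(g, np.random.default_rng(30).normal(size=50))
        assert len(tbl) == 3
        assert list(zip(tbl.pairs["i"], tbl.pairs["j"])) == [(0, 1), (0, 2), (1, 2)]

    def test_result_invariant_to_workers_and_chunking(self, hwe_dosages, make_table):
        g = make_table(hwe_dosages(80, 12, seed=31))
        y = np.random.default_rng(31).normal(size=80)
        a = run_all_pairs(g, y, n_workers=1, chunk_size=1000)
        b = run_all_pairs(g, y, n_workers=3, chunk_size=7)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    def test_explicit_pair_list(self, hwe_dosages, make_table):
        g = make_table(hwe_dosages(60, 6, seed=32))
        y = np.random.default_rng(32).normal(size=60)
        tbl = run_all_pairs(g, y, pairs=[(0, 3), (5, 2)])
        assert len(tbl) == 2
        assert set(zip(tbl.pairs["i"], tbl.pairs["j"])) == {(0, 3), (2, 5)}

    def test_single_variant_rejected(self, make_table):
        g = make_table(np.zeros((5, 1)))
        with pytest.raises(ValueError):
            run_all_pairs(g, np.zeros(5))

    def test_chunk_files_allow_resume(self, hwe_dosages, make_table, tmp_path):
        g = make_table(hwe_dosages(60, 10, seed=33))
        y = np.random.default_rng(33).normal(size=60)
        full = run_all_pairs(g, y, chunk_size=10)
        # first run writes chunks; drop some and resume
        run_all_pairs(g, y, chunk_size=10, chunk_dir=tmp_path)
        for f in sorted(tmp_path.glob("chunk_*.tsv"))[::2]:
            f.unlink()
        resumed = run_all_pairs(g, y, chunk_size=10, chunk_dir=tmp_path)
        np.testing.assert_allclose(
            resumed.pairs["beta3"].to_numpy(), full.pairs["beta3"].to_numpy()
        )

    def test_null_interaction_pvalues_uniform(self, hwe_dosages, make_table):
        from scipy import stats

        g = make_table(hwe_dosages(400, 46, seed=34))
        y = np.random.default_rng(34).normal(size=400)
        tbl = run_all_pairs(g, y)  # 1035 pairs
        p = tbl.ok_pairs["p3"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_roundtrip_tsv(self, hwe_dosages, make_table, tmp_path):
        from epinet.epistasis import EpistasisTable

        g = make_table(hwe_dosages(50, 5, seed=35))
        tbl = run_all_pairs(g, np.random.default_rng(35).normal(size=50))
        path = tbl.to_tsv(tmp_path / "pairs.tsv")
        back = EpistasisTable.from_tsv(path)
        np.testing.assert_allclose(
            back.pairs["beta3"].to_numpy(), tbl.pairs["beta3"].to_numpy()
        )


class TestCountPairs:
    @pytest.mark.parametrize(
        "n,exact", [(0, 0), (1, 0), (2, 1), (3, 3), (1000, 499500)]
    )
    def test_exact_counts(self, n, exact):
        assert count_pairs(n).exact == exact

    def test_700k_array_approximation(self):
        from epinet.epistasis import round_sig

        pc = count_pairs(700_000)
        assert pc.approx == 700_000 ** 2 / 2
        # two significant figures of the approximation
        assert round_sig(pc.approx, 2) == 2.5e11

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            count_pairs(-1)


class TestRuntimeProbe:
    def test_probe_reports_sane_numbers(self):
        r = runtime_probe(n_variants=40, n_samples=100, seed=0)
        assert r.n_pairs == count_pairs(40).exact
        assert r.models_per_second > 0 and np.isfinite(r.models_per_second)
        # self-extrapolation within 2x of the measured time
        assert r.projected_total_s == pytest.approx(r.elapsed_s, rel=1.0)

    def test_projection_scales_with_pair_count(self):
        r = runtime_probe(n_variants=40, n_samples=100, seed=0, target_variants=80)
        assert r.projected_total_s == pytest.approx(
            count_pairs(80).exact / r.models_per_second
        )
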