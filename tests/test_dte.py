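"""Filtering, normalization, NB GLM fitting, EB squeezing and quasi-F tests."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dividedcounts import (
    CountModel,
    bh_adjust,
    estimate_common_dispersion,
    filter_by_expression,
    fit_nb_glm,
    ql_f_test,
    squeeze_quasi_dispersions,
    tmm_norm_factors,
)
from dividedcounts.dte import QLStats, ave_log_cpm, top_expressed_indices
from dividedcounts.ecquant import InputError
from dividedcounts.glmfit import nb_unit_deviance


class TestFilterByExpression:
    def test_all_zero_transcript_excluded(self):
        counts = np.vstack([np.zeros(6), np.full(6, 1000.0)])
        lib = np.full(6, 1e6)
        keep = filter_by_expression(counts, lib, (3, 3))
        assert not keep[0] and keep[1]

    def test_hand_computed_oracle_on_toy_matrix(self):
        """Apply the two filter rules literally to an 8-transcript toy."""
        lib = np.array([1e5, 2e5, 1e5, 2e5])
        rngl = np.random.default_rng(0)
        counts = rngl.poisson(
            np.outer([0.0, 1.0, 5.0, 20.0, 100.0, 3.0, 50.0, 8.0], lib / 1e5)
        ).astype(float)
        min_count, min_total = 10.0, 15.0
        cutoff = min_count / np.median(lib) * 1e6
        cpm = counts / lib * 1e6
        expected = ((cpm > cutoff).sum(axis=1) >= 2) & (counts.sum(axis=1) >= min_total)
        keep = filter_by_expression(counts, lib, (2, 2), min_count, min_total)
        np.testing.assert_array_equal(keep, expected)

    def test_everything_filtered_is_an_error(self):
        with pytest.raises(InputError):
            filter_by_expression(np.zeros((3, 4)), np.full(4, 1e6), (2, 2))


class TestTMM:
    def test_identical_samples_give_unit_factors(self, rng):
        col = rng.poisson(50.0, size=500).astype(float) + 1.0
        counts = np.column_stack([col] * 4)
        f = tmm_norm_factors(counts, counts.sum(axis=0))
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_pure_depth_change_absorbed_by_library_size(self, rng):
        col = rng.poisson(100.0, size=800).astype(float) + 1.0
        counts = np.column_stack([col, 2.0 * col])
        f = tmm_norm_factors(counts, counts.sum(axis=0))
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_spiked_sample_down_weighted(self, rng):
        counts = rng.poisson(100.0, size=(1000, 3)).astype(float) + 1.0
        counts[0, 2] = 2e5  # one transcript swallows ~2/3 of that library
        f = tmm_norm_factors(counts, counts.sum(axis=0))
        assert f[2] < 1.0 < f[0]
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_matches_reference_implementation(self, rng, tmp_path):
        """Cross-check against edgeR's calcNormFactors TMM on a small matrix."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        counts = (rng.poisson(60.0, size=(400, 4)) * rng.choice(
            [1, 1, 1, 3], size=(400, 4))).astype(float) + 1.0
        lib = counts.sum(axis=0)
        np.savetxt(tmp_path / "counts.tsv", counts, delimiter="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"y <- as.matrix(read.delim('{tmp_path}/counts.tsv', header=FALSE))\n"
            "f <- calcNormFactors(y, method='TMM')\n"
            "cat(f, sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = np.array([float(x) for x in out.stdout.split()])
        ours = tmm_norm_factors(counts, lib)
        np.testing.assert_allclose(ours, ref, rtol=2e-3)

    def test_all_zero_sample_rejected(self):
        counts = np.ones((5, 3))
        counts[:, 1] = 0.0
        with pytest.raises(InputError):
            tmm_norm_factors(counts, np.array([5.0, 1.0, 5.0]))


class TestCommonDispersion:
    def test_nb_dispersion_recovered(self, rng):
        phi = 0.04
        mu = np.exp(rng.normal(5.0, 1.0, size=2000))
        y = rng.negative_binomial(
            1 / phi, 1 / (1 + phi * mu[:, None]), size=(2000, 10)
        ).astype(float)
        X = np.column_stack([np.ones(10), np.repeat([0, 1], 5)])
        phi_hat = estimate_common_dispersion(y, X, lib_size=y.sum(axis=0))
        assert phi_hat == pytest.approx(phi, rel=0.25)

    def test_poisson_counts_give_near_zero(self, rng):
        mu = np.exp(rng.normal(5.0, 1.0, size=1000))
        y = rng.poisson(mu[:, None] * np.ones(8)).astype(float)
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        phi_hat = estimate_common_dispersion(y, X, lib_size=y.sum(axis=0))
        assert phi_hat <= 0.005

    def test_top_selection_arithmetic(self):
        idx = top_expressed_indices(np.arange(100.0), 0.05)
        assert len(idx) == 5
        assert set(idx) == {95, 96, 97, 98, 99}


class TestFitNBGLM:
    def test_intercept_only_poisson_closed_form(self, rng):
        y = rng.poisson(30.0, size=(5, 6)).astype(float)
        offsets = np.log(np.array([1.0, 1.0, 2.0, 2.0, 4.0, 4.0]))
        model = CountModel(
            counts=y, lib_size=np.exp(offsets), design=np.ones((6, 1)), offsets=offsets
        )
        fit = fit_nb_glm(model, 0.0)
        L = np.exp(offsets)
        expected_mu = (y.sum(axis=1) / L.sum())[:, None] * L[None, :]
        np.testing.assert_allclose(fit.mu, expected_mu, rtol=1e-6)
        np.testing.assert_allclose(
            fit.deviance, nb_unit_deviance(y, expected_mu, 0.0).sum(axis=1), rtol=1e-6
        )

    def test_saturated_design_gives_zero_deviance(self, rng):
        y = rng.poisson(30.0, size=(4, 3)).astype(float) + 1.0
        model = CountModel(
            counts=y, lib_size=np.full(3, 100.0), design=np.eye(3),
            offsets=np.zeros(3),
        )
        fit = fit_nb_glm(model, 0.0)
        np.testing.assert_allclose(fit.deviance, 0.0, atol=1e-8)
        np.testing.assert_allclose(fit.adj_df, 0.0)

    def test_large_counts_recover_classical_deviance(self, rng):
        """At means >= 1000 the adjustment agrees with deviance/(N-p) to 2%."""
        y = rng.poisson(2000.0, size=(300, 6)).astype(float)
        X = np.column_stack([np.ones(6), np.repeat([0, 1], 3)])
        model = CountModel(
            counts=y, lib_size=np.full(6, 1e4), design=X, offsets=np.zeros(6)
        )
        fit = fit_nb_glm(model, 0.0)
        classical = fit.deviance / 4.0
        ratio = fit.s2 / classical
        np.testing.assert_allclose(ratio, 1.0, rtol=0.02)

    def test_nonfinite_counts_rejected(self):
        with pytest.raises(InputError):
            CountModel(
                counts=np.array([[1.0, np.nan]]), lib_size=np.ones(2),
                design=np.ones((2, 1)),
            )

    def test_adjusted_df_bounded_by_residual_df(self, rng):
        phi = 0.1
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * 5.0), size=(500, 8)).astype(
            float
        )
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        model = CountModel(
            counts=y, lib_size=np.full(8, 4e3), design=X, offsets=np.zeros(8)
        )
        fit = fit_nb_glm(model, phi)
        assert np.all(fit.adj_df <= 6.0 + 1e-12)
        assert np.all(fit.adj_deviance >= 0.0)


class TestSqueeze:
    def _fit_like(self, s2, adj_df):
        """A minimal stand-in ModelFit carrying s2 = adj_deviance/adj_df."""
        from dividedcounts.glmfit import ModelFit

        T = len(s2)
        return ModelFit(
            beta=np.zeros((T, 1)),
            mu=np.ones((T, 2)),
            deviance=np.asarray(s2) * adj_df,
            adj_deviance=np.asarray(s2) * adj_df,
            adj_df=np.full(T, float(adj_df)),
            nb_dispersion=0.0,
            converged=np.ones(T, dtype=bool),
            dev_scale=np.ones(T),
            moment_backend="synthetic",
            model=None,
        )

    def test_constant_dispersions_give_infinite_prior_df(self):
        fit = self._fit_like(np.full(200, 1.7), 8.0)
        ql = squeeze_quasi_dispersions(fit, np.linspace(0, 10, 200))
        assert np.isinf(ql.d0)
        np.testing.assert_allclose(ql.s2_post, 1.7, rtol=1e-6)

    def test_prior_df_recovered_within_factor_two(self, rng):
        """s2 drawn as trend * (chi2_df1/df1)/(chi2_d0/d0) with d0=40."""
        T, df1, d0 = 4000, 8.0, 40.0
        trend = 1.0
        s2 = (
            trend
            * (rng.chisquare(df1, T) / df1)
            / (rng.chisquare(d0, T) / d0)
        )
        fit = self._fit_like(s2, df1)
        ql = squeeze_quasi_dispersions(fit, rng.normal(5, 1, T))
        assert d0 / 2 <= ql.d0 <= d0 * 2

    def test_posterior_between_raw_and_trend(self, rng):
        s2 = rng.chisquare(8, 500) / 8
        fit = self._fit_like(s2, 8.0)
        ql = squeeze_quasi_dispersions(fit, rng.normal(0, 1, 500))
        lo = np.minimum(ql.s2, ql.trend) - 1e-9
        hi = np.maximum(ql.s2, ql.trend) + 1e-9
        assert np.all((ql.s2_post >= lo) & (ql.s2_post <= hi))

    def test_too_few_transcripts_rejected(self):
        fit = self._fit_like(np.array([1.0, 2.0]), 4.0)
        with pytest.raises(InputError):
            squeeze_quasi_dispersions(fit, np.array([0.0, 1.0]))


class TestQLFTest:
    def test_identical_groups_give_null_result(self):
        y = np.tile(np.array([40.0, 41.0, 39.0]), (1, 2)).reshape(1, 6)
        X = np.column_stack([np.ones(6), np.repeat([0, 1], 3)])
        model = CountModel(
            counts=y, lib_size=np.full(6, 100.0), design=X, offsets=np.zeros(6)
        )
        fit = fit_nb_glm(model, 0.0)
        ql = QLStats(
            s2=fit.s2,
            abundance=np.zeros(1),
            trend=np.ones(1),
            d0=np.inf,
            s2_post=np.ones(1),
        )
        res = ql_f_test(fit, ql, np.array([0.0, 1.0]))
        assert res.logFC[0] == pytest.approx(0.0, abs=1e-8)
        assert res.p[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_chisquare_limit_at_large_counts(self, rng):
        """With d0 = inf and phi = 0, k*F reproduces the likelihood-ratio
        chi-square statistic and its tail probability at large counts."""
        y = rng.poisson(5000.0, size=(200, 6)).astype(float)
        X = np.column_stack([np.ones(6), np.repeat([0, 1], 3)])
        model = CountModel(
            counts=y, lib_size=np.full(6, 3e4), design=X, offsets=np.zeros(6)
        )
        fit = fit_nb_glm(model, 0.0)
        T = y.shape[0]
        ql = QLStats(
            s2=fit.s2,
            abundance=np.zeros(T),
            trend=np.ones(T),
            d0=np.inf,
            s2_post=np.ones(T),
        )
        res = ql_f_test(fit, ql, np.array([0.0, 1.0]))
        # independent oracle: Poisson likelihood-ratio test per transcript
        null_model = CountModel(
            counts=y, lib_size=np.full(6, 3e4), design=np.ones((6, 1)),
            offsets=np.zeros(6),
        )
        lr = fit_nb_glm(null_model, 0.0).deviance - fit.deviance
        p_chi2 = stats.chi2.sf(lr, 1)
        np.testing.assert_allclose(res.p, p_chi2, atol=1e-3)

    def test_null_pvalues_are_uniform(self, rng):
        """Kolmogorov-Smirnov distance below 0.02 for 20 000 null transcripts."""
        phi = 0.04
        T, n = 20000, 10
        mu = np.exp(rng.normal(4.5, 1.0, size=T))
        y = rng.negative_binomial(
            1 / phi, 1 / (1 + phi * mu[:, None]), size=(T, n)
        ).astype(float)
        X = np.column_stack([np.ones(n), np.repeat([0, 1], 5)])
        lib = y.sum(axis=0)
        phi_hat = estimate_common_dispersion(y, X, lib_size=lib)
        model = CountModel(counts=y, lib_size=lib, design=X)
        fit = fit_nb_glm(model, phi_hat)
        ql = squeeze_quasi_dispersions(fit, ave_log_cpm(y, lib))
        res = ql_f_test(fit, ql, np.array([0.0, 1.0]))
        ks = stats.kstest(res.p, "uniform").statistic
        assert ks < 0.02

    def test_zero_contrast_rejected(self, rng):
        y = rng.poisson(30.0, size=(10, 6)).astype(float)
        X = np.column_stack([np.ones(6), np.repeat([0, 1], 3)])
        model = CountModel(counts=y, lib_size=y.sum(axis=0), design=X)
        fit = fit_nb_glm(model, 0.0)
        ql = QLStats(
            s2=fit.s2, abundance=np.zeros(10), trend=np.ones(10), d0=10.0,
            s2_post=np.ones(10),
        )
        with pytest.raises(InputError):
            ql_f_test(fit, ql, np.zeros(2))


class TestBHAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(bh_adjust(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_brute_force_definition(self, pvals):
        p = np.asarray(pvals)
        m = p.size
        # brute force: adjusted p_i = min over thresholds t >= p_i of m*t/rank(t)
        sorted_p = np.sort(p)
        brute = np.empty(m)
        for i, pi in enumerate(p):
            cand = [
                min(1.0, m * t / (k + 1))
                for k, t in enumerate(sorted_p)
                if t >= pi - 1e-15
            ]
            brute[i] = min(cand)
        np.testing.assert_allclose(bh_adjust(p), brute, atol=1e-12)
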