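"""ABC engine: priors, summary statistics, rejection, model choice,
regression adjustment, PCA pre-evaluation, and pod-based validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import condorabc as c
from condorabc.abc import (STAT_NAMES, ReferenceTable, adjust_posterior,
                           confusion_errors, draw_priors, model_choice,
                           posterior_model_check,
                           prior_predictive_pca, reference_table, rejection,
                           summarize, summarize_matrix)


@pytest.fixture(scope="module")
def small_tables():
    """Two small reference tables (scenarios 1 and 2) shared by the
    model-choice and confusion tests."""
    prior = c.NORTH_PRIOR
    model = c.condor_mutation_model()
    design = c.condor_design()
    t1 = reference_table(1, prior, 800, model, design, seed=101)
    t2 = reference_table(2, prior, 800, model, design, seed=202)
    return prior, model, design, t1, t2


class TestPriors:
    def test_scenario4_conditioning_enforced(self):
        rng = np.random.default_rng(0)
        draws = draw_priors(4, c.NORTH_PRIOR, 10000, rng)
        assert (draws["nef2"] > draws["nef1"]).all()
        assert (draws["nef4"] < draws["nef2"]).all()
        assert ((draws["t1"] < draws["te"]) & (draws["te"] < draws["t2"])).all()

    def test_bounds_respected(self):
        rng = np.random.default_rng(1)
        draws = draw_priors(2, c.NORTH_PRIOR, 5000, rng)
        assert draws["nef1"].between(50, 1000).all()
        assert draws["t1"].between(7, 350).all()

    def test_unconditioned_marginal_uniform(self):
        rng = np.random.default_rng(2)
        draws = draw_priors(3, c.NORTH_PRIOR, 10000, rng)
        stat = kstest(draws["t2"], "uniform",
                      args=(1000, 500000 - 1000))
        assert stat.pvalue > 0.01

    def test_incompatible_bounds_error(self):
        bad = c.PriorConfig(nef1=(5000.0, 6000.0), nef2=(500.0, 600.0))
        with pytest.raises(ValueError, match="acceptance rate"):
            draw_priors(2, bad, 100, np.random.default_rng(3))


class TestSummaryStatistics:
    def test_monomorphic_pair_all_zero(self):
        mat = np.zeros((8, 50), dtype=np.uint8)
        labels = np.array([0] * 4 + [1] * 4)
        stats = summarize_matrix(mat, labels)
        named = dict(zip(STAT_NAMES, stats))
        assert named["n_hap_hist"] == 1 and named["n_hap_cont"] == 1
        for k, v in named.items():
            if not k.startswith("n_hap"):
                assert v == 0.0, k

    def test_matches_diversity_module(self, condor_fixture):
        """Cross-module oracle: stratum entries equal the diversity module's
        statistics computed on the same strata."""
        stats = dict(zip(STAT_NAMES, summarize(condor_fixture)))
        hist = condor_fixture.by_period(c.HISTORICAL)
        cont = condor_fixture.by_period(c.CONTEMPORARY)
        k_h, _ = c.mean_pairwise_differences(hist.matrix())
        k_c, _ = c.mean_pairwise_differences(cont.matrix())
        assert stats["mean_pw_hist"] == pytest.approx(k_h)
        assert stats["mean_pw_cont"] == pytest.approx(k_c)
        assert stats["seg_sites_hist"] == c.segregating_sites(hist.matrix())
        h, _ = c.haplotype_diversity(
            list(c.collapse_haplotypes(hist).haplotype_counts().values()))
        assert stats["hap_div_hist"] == pytest.approx(h)
        assert stats["tajima_d_cont"] == pytest.approx(
            c.tajimas_d(cont.matrix()))

    def test_within_stratum_permutation_invariance(self, condor_fixture):
        mat = condor_fixture.matrix()
        labels = np.array([0 if r.period == c.HISTORICAL else 1
                           for r in condor_fixture])
        base = summarize_matrix(mat, labels)
        rng = np.random.default_rng(5)
        perm = np.concatenate([rng.permutation(np.flatnonzero(labels == g))
                               for g in (0, 1)])
        assert summarize_matrix(mat[perm], labels[perm]) == pytest.approx(base)


class TestRejection:
    def _table(self, n=200, d=5, seed=0):
        return np.random.default_rng(seed).normal(size=(n, d))

    def test_tolerance_arithmetic(self):
        stats = self._table(1000)
        idx, _ = rejection(stats, stats[0], tolerance=0.01)
        assert len(idx) == 10

    def test_observed_simulation_ranked_first(self):
        stats = self._table()
        idx, dist = rejection(stats, stats[17], tolerance=0.05)
        assert idx[0] == 17 and dist[17] == 0.0

    def test_matches_exhaustive_sort_oracle(self):
        stats = self._table(150, 4, seed=9)
        obs = np.zeros(4)
        idx, _ = rejection(stats, obs, tolerance=0.1)
        med = np.median(stats, axis=0)
        mad = np.median(np.abs(stats - med), axis=0)
        dist = np.sqrt((((stats - obs) / mad) ** 2).sum(axis=1))
        expected = np.argsort(dist, kind="stable")[:15]
        assert list(idx) == list(expected)

    def test_scale_invariance(self):
        stats = self._table(300, 3, seed=4)
        obs = stats.mean(axis=0)
        idx1, _ = rejection(stats, obs)
        scaled = stats.copy()
        scaled[:, 1] *= 1000.0
        obs2 = obs.copy()
        obs2[1] *= 1000.0
        idx2, _ = rejection(scaled, obs2)
        assert list(idx1) == list(idx2)

    def test_zero_variance_stat_dropped(self):
        stats = self._table(200, 3, seed=6)
        stats[:, 2] = 7.0
        idx, _ = rejection(stats, np.array([0.0, 0.0, 7.0]))
        assert len(idx) == 2

    def test_too_few_simulations(self):
        with pytest.raises(ValueError):
            rejection(self._table(50), np.zeros(5))


class TestModelChoice:
    def test_identical_simulators_symmetric(self, small_tables):
        """Two scenarios backed by the same generating process: posterior
        probabilities near 1/2 with overlapping CIs."""
        prior, model, design, t1, _ = small_tables
        t1b = reference_table(1, prior, 800, model, design, seed=909)
        fake2 = ReferenceTable(scenario_id=2, params=t1b.params,
                               stats=t1b.stats)
        rng = np.random.default_rng(3)
        obs = t1.stats[rng.integers(len(t1.stats))]
        res = model_choice({1: t1, 2: fake2}, obs, n_boot=100, seed=1)
        assert abs(res.probabilities[1] - 0.5) < 0.2
        assert res.ci[1][0] < res.ci[2][1] and res.ci[2][0] < res.ci[1][1]

    def test_direct_method_equals_acceptance_fractions(self):
        rng = np.random.default_rng(8)
        mk = lambda sid, loc: ReferenceTable(
            scenario_id=sid, params=pd.DataFrame({"x": np.zeros(300)}),
            stats=rng.normal(loc=loc, size=(300, 4)))
        ta, tb = mk(1, 0.0), mk(2, 3.0)
        obs = np.zeros(4)
        res = model_choice({1: ta, 2: tb}, obs, method="direct", n_boot=0)
        stats = np.vstack([ta.stats, tb.stats])
        idx, _ = rejection(stats, obs)
        frac1 = (idx < 300).mean()
        assert res.probabilities[1] == pytest.approx(frac1)
        assert res.probabilities[1] + res.probabilities[2] == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self, small_tables):
        _, _, _, t1, t2 = small_tables
        obs = t2.stats[5]
        res = model_choice({1: t1, 2: t2}, obs, n_boot=0)
        assert sum(res.probabilities.values()) == pytest.approx(1.0, abs=1e-6)


class TestAdjustPosterior:
    def test_uninformative_stats_leave_sample_unchanged(self):
        """When statistics carry no information about the parameter the
        adjusted posterior is the accepted sample (zero-slope limit)."""
        rng = np.random.default_rng(0)
        n = 2000
        params = pd.DataFrame({
            "scenario": 1, "nef1": rng.uniform(50, 1000, n),
            **{k: np.nan for k in ("nef2", "nef3", "nef4", "t1", "te", "t2")}})
        stats = rng.normal(size=(n, 4))  # independent of nef1
        table = ReferenceTable(1, params, stats)
        post = adjust_posterior(table, np.zeros(4), c.NORTH_PRIOR,
                                tolerance=0.5)
        idx, _ = rejection(stats, np.zeros(4), 0.5)
        accepted = params["nef1"].to_numpy()[idx]
        from scipy.stats import ks_2samp
        ks = ks_2samp(post.samples["nef1"], accepted).statistic
        assert ks < 0.1

    def test_identical_stats_identity_adjustment(self):
        rng = np.random.default_rng(1)
        n = 500
        params = pd.DataFrame({
            "scenario": 1, "nef1": rng.uniform(50, 1000, n),
            **{k: np.nan for k in ("nef2", "nef3", "nef4", "t1", "te", "t2")}})
        jitter = rng.normal(size=(n, 3))
        stats = np.hstack([np.full((n, 1), 2.0), jitter])
        obs = np.array([2.0, 0.0, 0.0, 0.0])
        table = ReferenceTable(1, params, stats)
        post = adjust_posterior(table, obs, c.NORTH_PRIOR, tolerance=0.05)
        idx, _ = rejection(stats, obs, 0.05)
        # adjustment of informationless deviations stays inside prior bounds
        assert post.samples["nef1"].between(50, 1000).all()
        q = post.quantile("nef1", [0.5])
        assert 50 <= q[0] <= 1000

    def test_quantiles_ordered(self, small_tables):
        _, _, _, t1, _ = small_tables
        post = adjust_posterior(t1, t1.stats[3], c.NORTH_PRIOR,
                                tolerance=0.05)
        s = post.summary().set_index("parameter").loc["nef1"]
        assert s["q2.5"] <= s["q25"] <= s["median"] <= s["q75"] <= s["q97.5"]


class TestPriorPredictivePca:
    def test_central_observation_scores_high(self):
        rng = np.random.default_rng(0)
        stats = rng.normal(size=(500, 6))
        rep = prior_predictive_pca(stats, stats.mean(axis=0))
        assert rep.outlier_score > 0.95

    def test_far_observation_scores_low(self):
        rng = np.random.default_rng(1)
        stats = rng.normal(size=(500, 6))
        rep = prior_predictive_pca(stats, stats.mean(axis=0) + 50.0)
        assert rep.outlier_score < 0.05

    def test_projection_matches_eigendecomposition(self):
        """Oracle: explicit covariance eigendecomposition of the
        standardized table."""
        rng = np.random.default_rng(2)
        stats = rng.normal(size=(60, 3)) @ np.diag([3.0, 1.0, 0.3])
        obs = stats[7]
        rep = prior_predictive_pca(stats, obs, n_components=2)
        z = (stats - stats.mean(0)) / stats.std(0)
        zo = (obs - stats.mean(0)) / stats.std(0)
        cov = np.cov(z, rowvar=False, ddof=1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:2]
        proj = np.abs(zo @ vecs[:, order])  # sign of eigenvectors is free
        assert np.abs(rep.coordinates) == pytest.approx(proj, rel=1e-6)


class TestPodsAndChecks:
    def test_confusion_counts_and_separability(self, small_tables):
        prior, model, design, t1, t2 = small_tables
        res = confusion_errors(prior, scenarios=(1, 2), n_pods=12,
                               model=model, design=design, seed=3,
                               tables={1: t1, 2: t2})
        assert res.counts.loc[1].sum() == 12
        assert res.counts.loc[2].sum() == 12
        assert 0.0 <= res.type_i[1] <= 1.0 and 0.0 <= res.type_ii[2] <= 1.0

    def test_posterior_predictive_pvalues(self, small_tables):
        prior, model, design, t1, _ = small_tables
        obs = t1.stats[11]
        post = adjust_posterior(t1, obs, prior, tolerance=0.05)
        rep = posterior_model_check(post, 1, obs, model, design,
                                    n_rep=60, seed=4)
        assert rep["p_two_sided"].between(0, 1).all()
        rep2 = posterior_model_check(post, 1, obs, model, design,
                                     n_rep=60, seed=4)
        pd.testing.assert_frame_equal(rep, rep2)
        # the observed vector came from the prior-predictive itself: the
        # overwhelming majority of statistics should not be outliers
        assert (rep["p_two_sided"] < 0.05).mean() < 0.3
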