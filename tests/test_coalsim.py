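"""Coalescent simulator: epoch structure, analytic expectations, HKY
mutation behaviour, and an msprime cross-check."""

import math

import numpy as np
import pytest

from condorabc import (Demography, MutationModel, Pulse, SamplingDesign,
                       ScenarioParams, apply_mutations, condor_design,
                       condor_mutation_model, demography_from_scenario,
                       sample_genealogy, simulate_dataset, simulate_matrix)
from condorabc.coalsim import hky_transition_matrix


def _pair_design(delta_gen=0.0, g=7.0):
    if delta_gen == 0:
        return SamplingDesign((Pulse(2, 0.0),))
    return SamplingDesign((Pulse(1, 0.0), Pulse(1, delta_gen * g)))


class TestDemography:
    def test_scenario1_constant(self):
        d = demography_from_scenario(ScenarioParams(1, nef1=1000))
        for t in (0.0, 5.0, 1e6):
            assert d.ne_at(t) == 1000

    def test_scenario2_unit_conversion(self):
        d = demography_from_scenario(
            ScenarioParams(2, nef1=100, nef2=1000, t1=70.0))
        assert d.ne_at(9.99) == 100
        assert d.ne_at(10.01) == 1000

    def test_scenario3_epochs(self):
        d = demography_from_scenario(
            ScenarioParams(3, nef1=500, nef3=50, t2=7000.0))
        assert d.ne_at(999.9) == 500 and d.ne_at(1000.1) == 50

    def test_scenario4_epoch_boundaries(self):
        p = ScenarioParams(4, nef1=100, nef2=5000, nef4=300,
                           t1=70, te=700, t2=7000)
        d = demography_from_scenario(p)
        eps = 1e-6
        for t, ne in [(10 - eps, 100), (10 + eps, 5000),
                      (100 - eps, 5000), (100 + eps, 300),
                      (1000 - eps, 300), (1000 + eps, 5000)]:
            assert d.ne_at(t) == ne
        alt = demography_from_scenario(p, scenario4_oldest_nef2=False)
        assert alt.ne_at(1000 + eps) == 300

    @pytest.mark.parametrize("params,msg", [
        (ScenarioParams(2, nef1=100, nef2=50, t1=70), "nef2 > nef1"),
        (ScenarioParams(3, nef1=100, nef3=200, t2=7000), "nef3 < nef1"),
        (ScenarioParams(4, nef1=100, nef2=500, nef4=600, t1=70, te=700,
                        t2=7000), "nef4 < nef2"),
        (ScenarioParams(4, nef1=100, nef2=500, nef4=50, t1=700, te=70,
                        t2=7000), "t1 < te < t2"),
    ])
    def test_conditioning_violations_named(self, params, msg):
        with pytest.raises(ValueError, match=msg):
            demography_from_scenario(params)


class TestGenealogy:
    def test_mean_tmrca_pair(self):
        dem = Demography((0.0,), (500.0,))
        t = [sample_genealogy(_pair_design(), dem, seed=s).tmrca
             for s in range(5000)]
        se = np.std(t) / math.sqrt(len(t))
        assert abs(np.mean(t) - 500.0) < 3 * se

    def test_serial_pair_tree_length(self):
        # lineages Delta apart add Delta of private branch: E[len] = 2Ne + D
        dem = Demography((0.0,), (500.0,))
        tl = [sample_genealogy(_pair_design(delta_gen=100), dem,
                               seed=s).total_branch_length
              for s in range(5000)]
        se = np.std(tl) / math.sqrt(len(tl))
        assert abs(np.mean(tl) - 1100.0) < 3 * se

    def test_bottleneck_shortens_tmrca(self):
        # severe recent bottleneck: coalescences pile up before t1
        strong = demography_from_scenario(
            ScenarioParams(2, nef1=10, nef2=5000, t1=7000))
        weak = Demography((0.0,), (5000.0,))
        t_s = [sample_genealogy(_pair_design(), strong, seed=s).tmrca
               for s in range(400)]
        t_w = [sample_genealogy(_pair_design(), weak, seed=s).tmrca
               for s in range(400)]
        assert np.mean(t_s) < 0.2 * np.mean(t_w)

    def test_tip_times_match_pulses(self):
        des = SamplingDesign((Pulse(3, 0.0), Pulse(2, 70.0)))
        dem = Demography((0.0,), (100.0,))
        g = sample_genealogy(des, dem, seed=0)
        tips = g.node_times[: g.n_tips]
        assert sorted(tips) == pytest.approx([0, 0, 0, 10, 10])


class TestMutation:
    def test_mu_zero_identical(self):
        dem = Demography((0.0,), (100.0,))
        g = sample_genealogy(SamplingDesign((Pulse(6, 0.0),)), dem, seed=1)
        mat = apply_mutations(g, condor_mutation_model(mu=0.0), seed=2)
        assert (mat == mat[0]).all()

    def test_kappa_one_equal_freqs_transition_third(self):
        """With kappa=1 and uniform frequencies (JC limit) one third of
        observed differences are transitions."""
        model = MutationModel(mu=2e-4, kappa=1.0,
                              base_freqs=(0.25,) * 4,
                              partitions=((310, 1.0),))
        dem = Demography((0.0,), (500.0,))
        ts = tv = 0
        for s in range(300):
            g = sample_genealogy(_pair_design(), dem, seed=s)
            mat = apply_mutations(g, model, seed=1000 + s)
            diff = mat[0] != mat[1]
            trans = diff & ((mat[0].astype(int) + mat[1]) % 2 == 0)
            ts += trans.sum()
            tv += diff.sum() - trans.sum()
        frac = ts / (ts + tv)
        assert abs(frac - 1.0 / 3.0) < 3 * math.sqrt(1 / 9 * 2 / (ts + tv)) + 0.02

    def test_pair_expected_differences(self):
        # E[K] = 2 Ne mu L in the low-mutation regime
        model = condor_mutation_model(mu=1e-6)
        dem = Demography((0.0,), (500.0,))
        rng = np.random.default_rng(3)
        ks = []
        for _ in range(8000):
            g = sample_genealogy(_pair_design(), dem,
                                 seed=rng.integers(2**31))
            mat = apply_mutations(g, model, seed=rng.integers(2**31))
            ks.append(int((mat[0] != mat[1]).sum()))
        expect = 2 * 500 * 1e-6 * 310
        se = np.std(ks) / math.sqrt(len(ks))
        assert abs(np.mean(ks) - expect) < 3.5 * se

    def test_base_composition_converges_to_stationary(self):
        model = MutationModel(mu=0.05, kappa=3.0,
                              base_freqs=(0.4, 0.3, 0.2, 0.1),
                              partitions=((310, 1.0),))
        dem = Demography((0.0,), (200.0,))
        counts = np.zeros(4)
        for s in range(60):
            g = sample_genealogy(SamplingDesign((Pulse(4, 0.0),)), dem, seed=s)
            mat = apply_mutations(g, model, seed=500 + s)
            counts += np.bincount(mat.ravel(), minlength=4)
        freqs = counts / counts.sum()
        assert np.abs(freqs - np.array(model.base_freqs)).max() < 0.02

    def test_hky_rows_are_distributions(self):
        P = hky_transition_matrix(0.7, 8.0, (0.3, 0.3, 0.15, 0.25))
        assert P.min() >= 0
        assert P.sum(axis=1) == pytest.approx(np.ones(4))


class TestEndToEnd:
    def test_seed_reproducibility(self):
        p = ScenarioParams(2, nef1=100, nef2=2000, t1=140)
        model = condor_mutation_model()
        des = condor_design()
        a = simulate_dataset(p, model, des, seed=99)
        b = simulate_dataset(p, model, des, seed=99)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert [r.period for r in a] == [r.period for r in b]

    def test_design_counts_and_periods(self):
        ds = simulate_dataset(ScenarioParams(1, nef1=300),
                              condor_mutation_model(), condor_design(),
                              seed=5)
        assert len(ds) == 73
        periods = [r.period for r in ds]
        assert periods.count("historical") == 35
        assert periods.count("contemporary") == 38

    def test_batch_stat_stability_across_seeds(self):
        """Mean pairwise diversity of simulation batches agrees across seed
        streams within Monte-Carlo error."""
        from condorabc.abc import summarize_matrix
        model = condor_mutation_model()
        des = condor_design()
        p = ScenarioParams(1, nef1=400)
        means = []
        for seed0 in (11, 77):
            rng = np.random.default_rng(seed0)
            ks = []
            for _ in range(150):
                mat, tp = simulate_matrix(p, model, des,
                                          seed=rng.integers(2**31))
                labels = (np.array([des.pulses[i].years_before_present
                                    for i in tp]) == 0).astype(int)
                ks.append(summarize_matrix(mat, labels)[2])
            means.append((np.mean(ks), np.std(ks) / math.sqrt(len(ks))))
        (m1, s1), (m2, s2) = means
        assert abs(m1 - m2) < 3.5 * math.hypot(s1, s2)


class TestMsprimeCrossCheck:
    def test_serial_tmrca_distribution_matches_msprime(self):
        """Independent oracle: msprime's heterochronous coalescent under the
        same two-pulse, two-epoch demography."""
        import msprime
        from scipy.stats import ks_2samp

        ne1, ne2, t_change = 200.0, 2000.0, 50.0
        dem = Demography((0.0, t_change), (ne1, ne2))
        des = SamplingDesign((Pulse(3, 0.0), Pulse(3, 70.0)))  # 10 gens
        ours = [sample_genealogy(des, dem, seed=s).tmrca for s in range(1200)]

        md = msprime.Demography()
        md.add_population(initial_size=ne1)
        md.add_population_parameters_change(time=t_change, initial_size=ne2)
        samples = [msprime.SampleSet(3, time=0, ploidy=1),
                   msprime.SampleSet(3, time=10, ploidy=1)]
        theirs = [ts.max_root_time for ts in msprime.sim_ancestry(
            samples=samples, demography=md, ploidy=1,
            num_replicates=1200, random_seed=7)]
        assert ks_2samp(ours, theirs).pvalue > 1e-3


def test_design_from_sample_set(condor_fixture):
    from condorabc import design_from_sample_set
    design = design_from_sample_set(condor_fixture)
    assert design.total == 73
    ages = [p.years_before_present for p in design.pulses]
    assert min(ages) == 0.0
    assert all(a % 7.0 == 0 for a in ages)  # rounded to whole generations
    # museum-era samples (1884-1946) are all > 60 years older than the
    # newest contemporary sample; modern ones all < 60
    hist_n = sum(p.count for p in design.pulses
                 if p.years_before_present > 60)
    assert hist_n == 35
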