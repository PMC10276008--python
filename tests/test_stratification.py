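"""Rank correlations, strata registry, paired tests, meta-analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnbuffer import (
    BUILTIN_STRATA,
    CohortSummary,
    CorrelationResult,
    SimConfig,
    compare_strata,
    correlate,
    exact_signed_rank_p,
    meta_correlation,
    significant_cohorts,
    simulate_cohort,
    spearman,
    stratified_correlations,
    stratum_masks,
)
from cnbuffer.scores import coding_bp_per_bin, cohort_scores, prepare_mutations


def _scores(amp, mu):
    return pd.DataFrame({"bin_id": range(len(amp)), "amp_freq": amp, "mu": mu})


class TestCorrelate:
    def test_perfect_monotone(self):
        res = correlate(_scores(np.arange(10.0), np.arange(10.0) ** 2 - 5))
        assert res.rho == pytest.approx(1.0)

    def test_constant_predictor_is_degenerate(self):
        res = correlate(_scores(np.full(10, 0.3), np.arange(10.0)))
        assert math.isnan(res.rho)

    def test_fewer_than_three_bins_undefined(self):
        res = correlate(_scores([0.1, 0.2], [-5.0, -4.0]))
        assert not res.defined and res.n_bins == 2

    def test_midrank_oracle_on_five_bins(self):
        amp = np.array([0.1, 0.4, 0.4, 0.2, 0.9])
        mu = np.array([-5.0, -4.0, -4.5, -4.9, -3.9])
        res = correlate(_scores(amp, mu))
        ra, rm = stats.rankdata(amp), stats.rankdata(mu)
        expected = np.corrcoef(ra, rm)[0, 1]
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_nan_mu_bins_are_dropped(self):
        res = correlate(_scores([0.1, 0.2, 0.3, 0.4],
                                [-5.0, float("nan"), -4.0, -3.0]))
        assert res.n_bins == 3

    def test_exact_permutation_p_small_n(self):
        rho, p = spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4], exact=True)
        # |rho| >= 0.9 needs sum(d^2) in {0, 2, 38, 40}: 1+4+4+1 = 10 of 120
        assert p == pytest.approx(10 / 120)
        with pytest.raises(ValueError):
            spearman(range(9), range(9), exact=True)


class TestExactSignedRank:
    def test_uniform_positive_shift_nine_pairs(self):
        w, p = exact_signed_rank_p(np.full(9, 0.2))
        assert p == pytest.approx(2 / 2**9)  # 0.00390625

    def test_all_zero_differences(self):
        w, p = exact_signed_rank_p(np.zeros(4))
        assert p == 1.0

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1, 12)
        w, p = exact_signed_rank_p(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def _results(rhos, label="x"):
    return [CorrelationResult(cohort=f"c{i}", scale="", variable_pair="amp_freq~mu",
                              rho=r, p_value=0.01, n_bins=50, stratum_label=label)
            for i, r in enumerate(rhos)]


class TestCompareStrata:
    def test_identical_lists_no_signal(self):
        res = compare_strata(_results([0.1, 0.2, 0.3]), _results([0.1, 0.2, 0.3]))
        assert res.p_value == 1.0

    def test_uniform_shift_exact_p(self):
        base = [0.1 * i for i in range(9)]
        res = compare_strata(_results(base), _results([b + 0.2 for b in base]))
        assert res.p_value == pytest.approx(0.00390625)
        assert res.method == "exact"

    def test_unpaired_cohorts_are_named(self):
        a = _results([0.1, 0.2])
        b = _results([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="c2"):
            compare_strata(a, b)

    def test_single_pair_is_degenerate(self):
        with pytest.raises(ValueError):
            compare_strata(_results([0.1]), _results([0.3]))


class TestStrataRegistry:
    @pytest.fixture(scope="class")
    def cohort(self):
        return simulate_cohort(SimConfig(seed=11, coupling_beta=1.0))

    @pytest.mark.parametrize("spec", BUILTIN_STRATA, ids=lambda s: s.name)
    def test_stratum_complement_discard_partition(self, spec, cohort):
        muts = prepare_mutations(cohort.mutations)
        in_s, in_c, disc = stratum_masks(spec, cohort.genes, muts)
        total = in_s.astype(int) + in_c.astype(int) + disc.astype(int)
        assert (total == 1).all()

    def test_frequencies_never_change_under_stratification(self, cohort):
        scores, states = cohort_scores(cohort.cna, cohort.mutations, cohort.genes,
                                       cohort.build, grid=cohort.truth["grid"])
        muts = prepare_mutations(cohort.mutations)
        muts = muts[muts["patient"].isin(set(states["patient"]))]
        cb = coding_bp_per_bin(cohort.genes, cohort.truth["grid"])
        from cnbuffer.scores import score_table
        control = score_table(states, muts, cohort.truth["grid"], cb)
        for spec in BUILTIN_STRATA[:3]:
            in_s, _, _ = stratum_masks(spec, cohort.genes, muts)
            tbl = score_table(states, muts.loc[in_s], cohort.truth["grid"], cb)
            np.testing.assert_array_equal(tbl["amp_freq"], control["amp_freq"])
            np.testing.assert_array_equal(tbl["del_freq"], control["del_freq"])

    def test_filter_passing_everything_equals_control(self, cohort):
        scores, states = cohort_scores(cohort.cna, cohort.mutations, cohort.genes,
                                       cohort.build, grid=cohort.truth["grid"])
        muts = prepare_mutations(cohort.mutations)
        muts = muts[muts["patient"].isin(set(states["patient"]))]
        cb = coding_bp_per_bin(cohort.genes, cohort.truth["grid"])
        from cnbuffer.stratification import StratumSpec
        passthrough = StratumSpec("everything", "mutation",
                                  lambda m: pd.Series(True, index=m.index),
                                  "nothing")
        res = stratified_correlations(states, muts, cohort.genes,
                                      cohort.truth["grid"], cb,
                                      strata=[passthrough])
        by_label = {r.stratum_label: r for r in res}
        assert by_label["everything"].rho == pytest.approx(
            by_label["unfiltered"].rho)
        assert math.isnan(by_label["nothing"].rho)  # flagged empty


class TestMetaCorrelation:
    def _summary(self, cohort, burden):
        return CohortSummary(cohort=cohort, mean_amp_freq=0.1, mean_del_freq=0.1,
                             pooled_mu=-5, mutation_burden=burden,
                             n_patients=10, n_bins_defined=10)

    def test_perfect_monotone_over_five_cohorts(self):
        summaries = [self._summary(f"c{i}", 10 * (i + 1)) for i in range(5)]
        results = _results([0.1, 0.2, 0.3, 0.4, 0.5])
        assert meta_correlation(summaries, results).rho == pytest.approx(1.0)

    def test_two_cohorts_undefined(self):
        summaries = [self._summary(f"c{i}", 10) for i in range(2)]
        assert not meta_correlation(summaries, _results([0.1, 0.2])).defined


def test_significance_gate():
    results = [
        CorrelationResult("a", "", "amp_freq~mu", 0.5, 0.01, 50),
        CorrelationResult("b", "", "amp_freq~mu", 0.2, 0.30, 50),
        CorrelationResult("c", "", "amp_freq~mu", 0.4, 0.05, 50),
    ]
    assert significant_cohorts(results) == ["a", "c"]
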