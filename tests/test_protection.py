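"""Protection index, permutation percentiles, consensus, essentiality."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnbuffer import (
    consensus,
    essentiality_comparison,
    gene_scores,
    make_fixture,
    make_protection_scores,
    protection_index,
)


def _gene_df(amp, mu):
    return pd.DataFrame({"gene": [f"g{i}" for i in range(len(amp))],
                         "amp_freq": amp, "mu": mu})


class TestProtectionIndex:
    def test_reproducible_with_same_seed(self):
        df, _ = make_protection_scores(n_genes=150, seed=1)
        a = protection_index(df, n_perm=500, seed=9)
        b = protection_index(df, n_perm=500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        df, _ = make_protection_scores(n_genes=150, seed=1)
        a = protection_index(df, n_perm=500, seed=9)
        b = protection_index(df, n_perm=500, seed=10)
        assert not np.allclose(a["percentile"], b["percentile"])

    def test_antisymmetry_under_global_swap(self):
        df, _ = make_protection_scores(n_genes=200, seed=2)
        fwd = protection_index(df, n_perm=400, seed=7)
        swapped_df = df.rename(columns={"amp_freq": "mu", "mu": "amp_freq"})
        rev = protection_index(swapped_df, n_perm=400, seed=7)
        merged = fwd.merge(rev, on="gene", suffixes=("_f", "_r"))
        np.testing.assert_allclose(merged["p_index_f"], -merged["p_index_r"],
                                   atol=1e-12)
        np.testing.assert_allclose(
            merged["percentile_f"] + merged["percentile_r"], 100.0, atol=1e-9)

    def test_identical_scores_are_all_neither(self):
        df = _gene_df(np.full(120, 0.3), np.full(120, -5.0))
        rec = protection_index(df, n_perm=200, seed=0)
        assert (rec["klass"] == "neither").all()
        np.testing.assert_allclose(rec["percentile"], 50.0)

    def test_planted_extreme_is_protected(self):
        rng = np.random.default_rng(4)
        amp = rng.uniform(0, 0.5, 200)
        mu = rng.uniform(-6, -4, 200)
        amp[0], mu[0] = 0.99, -6.5  # extreme planted gene
        rec = protection_index(_gene_df(amp, mu), n_perm=1000, seed=3)
        assert rec.set_index("gene").loc["g0", "klass"] == "protected"

    def test_planted_set_recovery(self):
        df, planted = make_protection_scores(n_genes=400, seed=5)
        rec = protection_index(df, n_perm=2000, seed=6)
        called = set(rec.loc[rec["klass"] == "protected", "gene"])
        assert len(called & set(planted)) / len(planted) >= 0.8

    def test_swap_null_percentiles(self):
        df = _gene_df([0.9, 0.1, 0.5], [-6.0, -4.0, -5.0])
        rec = protection_index(df, n_perm=200, seed=0, null="swap").set_index("gene")
        # per-gene null {P, -P}: positive P -> 75, negative -> 25, zero -> 50
        assert rec.loc["g0", "percentile"] == 75.0
        assert rec.loc["g1", "percentile"] == 25.0
        assert rec.loc["g2", "percentile"] == 50.0

    def test_per_gene_null_option_runs(self):
        df, _ = make_protection_scores(n_genes=100, seed=8)
        rec = protection_index(df, n_perm=200, seed=1, null="per-gene")
        assert rec["percentile"].between(0, 100).all()

    def test_small_n_perm_warns(self):
        df, _ = make_protection_scores(n_genes=100, seed=8)
        with pytest.warns(UserWarning):
            protection_index(df, n_perm=10, seed=1)


class TestGeneScores:
    def test_non_expressed_genes_absent(self):
        fx = make_fixture("mini-eq3")
        genes = pd.concat([fx["genes"], fx["genes"].assign(
            gene="G2", median_tpm=0.0)], ignore_index=True)
        out = gene_scores(fx["cna"], fx["mutations"], genes, fx["build"],
                          patients=fx["patients"])
        assert "G2" not in set(out["gene"])

    def test_matches_hand_computation_at_gene_scale(self):
        fx = make_fixture("mini-eq3")
        out = gene_scores(fx["cna"], fx["mutations"], fx["genes"], fx["build"],
                          patients=fx["patients"])
        row = out.set_index("gene").loc["G1"]
        assert row["amp_freq"] == pytest.approx(0.4)
        assert row["mu"] == pytest.approx(-5.0)


class TestConsensus:
    def _records(self, klass_by_cohort):
        return {c: pd.DataFrame({"gene": ["G"], "cohort": c,
                                 "amp_freq_gene": 0.5, "mu_gene": 0.2,
                                 "p_index": 0.3, "percentile": 99.0,
                                 "klass": k})
                for c, k in klass_by_cohort.items()}

    def test_three_of_nine_is_protected(self):
        records = self._records({f"c{i}": ("protected" if i < 3 else "neither")
                                 for i in range(9)})
        out = consensus(records)
        assert out.loc[0, "consensus"] == "protected"

    def test_two_of_nine_is_none(self):
        records = self._records({f"c{i}": ("protected" if i < 2 else "neither")
                                 for i in range(9)})
        assert consensus(records).loc[0, "consensus"] == "none"

    def test_four_unprotected(self):
        records = self._records({f"c{i}": ("unprotected" if i < 4 else "neither")
                                 for i in range(9)})
        assert consensus(records).loc[0, "consensus"] == "unprotected"


class TestEssentialityComparison:
    def _genes(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        prot = [f"p{i}" for i in range(n)]
        unprot = [f"u{i}" for i in range(n)]
        return pd.DataFrame({
            "gene": prot + unprot,
            "crispr_effect": np.concatenate([
                rng.normal(-1.0, 0.2, n), rng.normal(0.0, 0.2, n)]),
            "median_tpm": np.concatenate([
                rng.lognormal(3, 1, n), rng.lognormal(2, 1, n)]),
            "is_common_essential": [True] * n + [False] * n,
            "is_nonessential": [False] * n + [True] * n,
        }), prot, unprot

    def _consensus(self, prot, unprot):
        return pd.DataFrame({
            "gene": prot + unprot,
            "consensus": ["protected"] * len(prot) + ["unprotected"] * len(unprot),
        })

    def test_separated_effect_distributions(self):
        genes, prot, unprot = self._genes()
        out = essentiality_comparison(self._consensus(prot, unprot), genes)
        assert out["crispr_effect"]["p_value"] < 1e-10
        assert (out["crispr_effect"]["median_protected"]
                < out["crispr_effect"]["median_unprotected"])

    def test_fisher_overlap_matches_hypergeometric_oracle(self):
        genes, prot, unprot = self._genes()
        out = essentiality_comparison(self._consensus(prot, unprot), genes)
        table = np.array(out["essential_overlap"]["table"])
        oracle = stats.fisher_exact(table, alternative="two-sided")[1]
        assert out["essential_overlap"]["p_value"] == pytest.approx(oracle)

    def test_fisher_contingency_oracle_values(self):
        # [[50,10],[10,50]] checked against the hypergeometric sum
        table = np.array([[50, 10], [10, 50]])
        _, p = stats.fisher_exact(table)
        n, k1, k2 = 120, 60, 60
        probs = [stats.hypergeom.pmf(x, n, k1, k2) for x in range(0, 61)]
        obs = stats.hypergeom.pmf(50, n, k1, k2)
        expected = sum(pr for pr in probs if pr <= obs * (1 + 1e-10))
        assert p == pytest.approx(expected, rel=1e-8)

    def test_null_calibration_of_rank_sum(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(200):
            a, b = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
            pvals.append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        frac = float(np.mean(np.asarray(pvals) <= 0.05))
        assert 0.02 <= frac <= 0.09

    def test_empty_set_is_skipped(self):
        genes, prot, unprot = self._genes()
        out = essentiality_comparison(self._consensus(prot, []), genes)
        assert "note" in out
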