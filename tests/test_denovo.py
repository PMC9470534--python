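import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rarefam.denovo import (
    WeightTable,
    cohort_burden,
    derive_ppv_weights,
    flat_weights,
    geneset_permutation_test,
    poisson_tail_p,
    preprocess_dnvs,
    weighted_enrichment_score_tail,
    weighted_enrichment_test,
)
from rarefam.mutation import GeneModel


def dnv_frame(rows):
    return pd.DataFrame(
        rows, columns=["individual_id", "gene_id", "variant_class", "position", "twin_group"]
    )


class TestPreprocess:
    def test_cluster_collapses_to_most_severe(self):
        df = dnv_frame(
            [("i1", "G1", "dmis", 100, None), ("i1", "G1", "lof", 150, None)]
        )
        out = preprocess_dnvs(df)
        assert len(out) == 1
        assert out.iloc[0]["variant_class"] == "lof"

    def test_distant_variants_retained(self):
        df = dnv_frame([("i1", "G1", "syn", 100, None), ("i1", "G1", "syn", 301, None)])
        assert len(preprocess_dnvs(df)) == 2

    def test_twin_shared_variant_counted_once(self):
        df = dnv_frame(
            [("tw_a", "G1", "lof", 500, "tw"), ("tw_b", "G1", "lof", 500, "tw")]
        )
        out = preprocess_dnvs(df)
        assert len(out) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"i{rng.integers(5)}", f"G{rng.integers(3)}",
             rng.choice(["lof", "dmis", "other_mis", "syn"]), int(rng.integers(1, 2000)), None)
            for _ in range(60)
        ]
        once = preprocess_dnvs(dnv_frame(rows))
        twice = preprocess_dnvs(once)
        pd.testing.assert_frame_equal(
            once.sort_values(list(once.columns)).reset_index(drop=True),
            twice.sort_values(list(twice.columns)).reset_index(drop=True),
        )


class TestPoissonTail:
    def test_zero_observed_is_one(self):
        assert poisson_tail_p(0, 5.0) == 1.0
        assert poisson_tail_p(0, 0.0) == 1.0

    def test_cohort_scale_example(self):
        # 5 observed at expectation 0.2027 (2 x 23,039 x 4.4e-6)
        lam = 0.2027
        direct = sum(math.exp(-lam) * lam**k / math.factorial(k) for k in range(5, 60))
        assert poisson_tail_p(5, lam) == pytest.approx(direct, rel=1e-9)
        assert poisson_tail_p(5, lam) == pytest.approx(2.4e-6, rel=0.05)

    def test_matches_survival_identity(self):
        for k, lam in [(1, 0.1), (3, 2.5), (10, 4.0)]:
            assert poisson_tail_p(k, lam) == pytest.approx(
                1 - stats.poisson.cdf(k - 1, lam), rel=1e-12
            )

    def test_invalid_expectation(self):
        with pytest.raises(ValueError):
            poisson_tail_p(2, 0.0)


class TestCohortBurden:
    def test_equal_rates(self):
        case = dnv_frame([("i1", "G1", "lof", 1, None)] * 10)
        ctrl = dnv_frame([("c1", "G1", "lof", 1, None)] * 5)
        res = cohort_burden(case, ctrl, 100, 50)
        assert res.rate_ratio == pytest.approx(1.0)
        assert res.rate_difference == pytest.approx(0.0)
        assert res.p_value > 0.4

    def test_excess_rate_is_par_contribution(self):
        case = dnv_frame([("i", "G1", "lof", 1, None)] * 30)
        ctrl = dnv_frame([("c", "G1", "lof", 1, None)] * 20)
        res = cohort_burden(case, ctrl, 100, 100)
        assert res.rate_difference == pytest.approx(0.10)
        assert res.par_contribution == pytest.approx(0.10)

    def test_scale_invariance_of_rates(self):
        case = dnv_frame([("i", "G1", "lof", 1, None)] * 6)
        ctrl = dnv_frame([("c", "G1", "lof", 1, None)] * 3)
        r1 = cohort_burden(case, ctrl, 20, 10)
        r2 = cohort_burden(pd.concat([case, case]), pd.concat([ctrl, ctrl]), 40, 20)
        assert r1.rate_case == pytest.approx(r2.rate_case)
        assert r1.rate_control == pytest.approx(r2.rate_control)

    def test_zero_trios_rejected(self):
        with pytest.raises(ValueError):
            cohort_burden(dnv_frame([]), dnv_frame([]), 0, 10)


class TestPpvWeights:
    def test_formula_and_clipping(self):
        w = derive_ppv_weights(
            {(True, "lof"): 300, (True, "dmis"): 100, (False, "lof"): 100},
            {(True, "lof"): 100, (True, "dmis"): 100, (False, "lof"): 150},
        )
        assert w.get(True, "lof") == pytest.approx(2 / 3)
        assert w.get(True, "dmis") == 0.0
        assert w.get(False, "lof") == 0.0

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            derive_ppv_weights({(True, "lof"): 5}, {(True, "lof"): 0.0})


class TestWeightedEnrichment:
    def _gene(self, mu_lof=2e-6, mu_dmis=0.0):
        return GeneModel("G1", mu_lof=mu_lof, mu_dmis=mu_dmis, pli=0.99, loeuf_decile=1)

    def test_single_class_reduces_to_poisson_tail(self):
        gene = self._gene()
        weights = WeightTable(
            {(c, k): (1.0 if k == "lof" else 0.0) for c in (False, True)
             for k in ("lof", "dmis", "other_mis")}
        )
        n_trios, k_obs = 5000, 3
        lam = 2 * n_trios * gene.mu_lof
        expected = poisson_tail_p(k_obs, lam)
        sim = weighted_enrichment_test(
            gene, {"lof": k_obs}, weights, n_trios, n_sim=100_000, seed=7, method="simulation"
        )
        se = math.sqrt(expected * (1 - expected) / sim.n_sim)
        assert abs(sim.p_value - expected) < 3 * se + 1.0 / sim.n_sim
        exact = weighted_enrichment_test(
            gene, {"lof": k_obs}, weights, n_trios, method="exact"
        )
        assert exact.p_value == pytest.approx(expected, rel=1e-9)

    def test_all_zero_observed_gives_one(self):
        res = weighted_enrichment_test(self._gene(), {}, flat_weights(), 1000)
        assert res.p_value == 1.0

    def test_exact_matches_enumeration_oracle_two_classes(self):
        """Exhaustive enumeration over count pairs 0..10 as independent oracle."""
        gene = self._gene(mu_lof=1e-6, mu_dmis=3e-6)
        weights = WeightTable(
            {(c, k): w for c in (False, True)
             for k, w in [("lof", 1.0), ("dmis", 0.4), ("other_mis", 0.0)]}
        )
        n_trios = 2000
        lam1, lam2 = 2 * n_trios * 1e-6, 2 * n_trios * 3e-6
        for obs in ({"lof": 1}, {"lof": 2, "dmis": 1}, {"dmis": 3}):
            score = 1.0 * obs.get("lof", 0) + 0.4 * obs.get("dmis", 0)
            oracle = sum(
                stats.poisson.pmf(k1, lam1) * stats.poisson.pmf(k2, lam2)
                for k1 in range(11)
                for k2 in range(11)
                if 1.0 * k1 + 0.4 * k2 >= score - 1e-9
            )
            res = weighted_enrichment_test(gene, obs, weights, n_trios, method="exact")
            assert res.p_value == pytest.approx(oracle, rel=1e-6)

    def test_seed_reproducibility(self):
        gene = self._gene()
        a = weighted_enrichment_test(gene, {"lof": 2}, flat_weights(), 5000, n_sim=20_000, seed=3)
        b = weighted_enrichment_test(gene, {"lof": 2}, flat_weights(), 5000, n_sim=20_000, seed=3)
        assert a.p_value == b.p_value

    def test_null_calibration_conservative(self):
        """On 1,000 simulated null genes, rejection at alpha=0.05 stays <= 0.06."""
        rng = np.random.default_rng(11)
        gene = self._gene(mu_lof=2e-6, mu_dmis=2e-6)
        weights = flat_weights()
        n_trios = 20_000
        lam = np.array([2 * n_trios * gene.mu_lof, 2 * n_trios * gene.mu_dmis])
        rejections = 0
        for _ in range(1000):
            k = rng.poisson(lam)
            counts = {"lof": int(k[0]), "dmis": int(k[1])}
            p = weighted_enrichment_test(gene, counts, weights, n_trios, method="exact").p_value
            rejections += p <= 0.05
        assert rejections / 1000 <= 0.06


class TestGenesetPermutation:
    def _genes(self, n=4, mu=1e-6):
        return [GeneModel(f"G{i}", mu_lof=mu, mu_dmis=mu, pli=0.99) for i in range(n)]

    def test_full_geneset_is_unenriched(self):
        genes = self._genes()
        records = dnv_frame([("i", "G0", "lof", 1, None), ("i2", "G1", "lof", 1, None)])
        res = geneset_permutation_test(
            records, {g.gene_id for g in genes}, genes, flat_weights(), n_perm=500, seed=0
        )
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.p_value > 0.5

    def test_three_mutations_two_equal_genes(self):
        """All 3 case mutations in one of two equal-rate genes: P -> (1/2)^3."""
        genes = self._genes(n=2)
        records = dnv_frame([("a", "G0", "lof", 1, None)] * 3)
        res = geneset_permutation_test(
            records, {"G0"}, genes, flat_weights(), n_perm=40_000, seed=5
        )
        se = math.sqrt(0.125 * 0.875 / res.n_perm)
        assert abs(res.p_value - 0.125) < 4 * se + 1e-4
        assert res.fold_enrichment == pytest.approx(2.0, rel=0.05)

    def test_seed_bit_reproducible(self):
        genes = self._genes()
        records = dnv_frame([("a", "G0", "lof", 1, None), ("b", "G2", "dmis", 5, None)])
        r1 = geneset_permutation_test(records, {"G0"}, genes, flat_weights(), 2000, seed=9)
        r2 = geneset_permutation_test(records, {"G0"}, genes, flat_weights(), 2000, seed=9)
        assert (r1.p_value, r1.fold_enrichment, r1.ci_low) == (
            r2.p_value,
            r2.fold_enrichment,
            r2.ci_low,
        )

    def test_fold_enrichment_invariant_to_uniform_mu_scaling(self):
        records = dnv_frame([("a", "G0", "lof", 1, None)] * 2 + [("b", "G1", "lof", 2, None)])
        res1 = geneset_permutation_test(
            records, {"G0"}, self._genes(mu=1e-6), flat_weights(), 3000, seed=1
        )
        res2 = geneset_permutation_test(
            records, {"G0"}, self._genes(mu=5e-6), flat_weights(), 3000, seed=1
        )
        assert res1.fold_enrichment == pytest.approx(res2.fold_enrichment)
        assert res1.p_value == res2.p_value

    def test_empty_geneset_rejected(self):
        with pytest.raises(ValueError):
            geneset_permutation_test(dnv_frame([]), set(), self._genes(), flat_weights())


def test_weighted_score_tail_matches_poisson_for_unit_weight():
    for lam in (0.05, 0.5, 2.0):
        for k in (1, 2, 5):
            assert weighted_enrichment_score_tail([1.0], [lam], float(k)) == pytest.approx(
                poisson_tail_p(k, lam), rel=1e-9
            )
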