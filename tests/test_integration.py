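import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirstage import (
    ExpressionMatrix,
    PairRecord,
    SimulationConfig,
    TargetMap,
    ValidationError,
    candidate_pairs,
    concordant_pairs,
    normalize_counts,
    prepare_counts,
    screen_pairs,
    simulate_cohort,
    simulate_target_map,
    spearman_rho,
)


def expr(values, feature_ids, sample_ids=None):
    arr = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=feature_ids, columns=sample_ids))


class TestCandidatePairs:
    def test_disjoint_sets_give_empty(self):
        targets = TargetMap([("miR-x", "G1")])
        assert candidate_pairs(["miR-y"], targets) == []

    def test_set_join(self):
        targets = TargetMap([("A", "g1"), ("A", "g2"), ("C", "g3")])
        assert candidate_pairs(["A", "B"], targets) == [("A", "g1"), ("A", "g2")]

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(2)
        mirnas = [f"m{i}" for i in range(5)]
        genes = [f"g{i}" for i in range(12)]
        edges = list(
            {(mirnas[rng.integers(5)], genes[rng.integers(12)]) for _ in range(20)}
        )
        targets = TargetMap(edges)
        signature = ["m0", "m2", "m4"]
        oracle = []
        for m, g in edges:
            for s in signature:
                if m == s:
                    oracle.append((m, g))
        assert sorted(candidate_pairs(signature, targets)) == sorted(oracle)


class TestSpearman:
    def test_perfect_inverse(self):
        rho, _ = spearman_rho(np.arange(12.0), -np.arange(12.0) ** 3)
        assert rho == pytest.approx(-1.0)

    def test_perfect_agreement(self):
        rho, _ = spearman_rho(np.arange(12.0), np.arange(12.0))
        assert rho == pytest.approx(1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.integers(0, 5, size=10).astype(float)
            y = rng.integers(0, 5, size=10).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, p = spearman_rho(x, y, method="t")
            oracle_rho, oracle_p = stats.spearmanr(x, y)
            assert rho == pytest.approx(oracle_rho, abs=1e-12)
            assert p == pytest.approx(oracle_p, rel=1e-9)

    def test_exact_p_agrees_with_t_at_moderate_rho(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([2.0, 1, 4, 3, 6, 5, 8, 7])
        _, p_exact = spearman_rho(x, y, method="exact")
        _, p_t = spearman_rho(x, y, method="t")
        assert p_exact == pytest.approx(p_t, abs=0.06)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValidationError):
            spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestScreenPairs:
    def _matrices(self, rng, n=40):
        mi = rng.normal(size=(3, n))
        mr = np.vstack(
            [
                -1.0 * mi[0] + rng.normal(scale=0.3, size=n),  # strong inverse
                +1.0 * mi[1] + rng.normal(scale=0.3, size=n),  # positive
                rng.normal(size=n),  # noise
            ]
        )
        mirna = expr(mi, ["m0", "m1", "m2"])
        mrna = expr(mr, ["g0", "g1", "g2"])
        return mirna, mrna

    def test_threshold_behaviour(self):
        rng = np.random.default_rng(8)
        mirna, mrna = self._matrices(rng)
        pairs = [("m0", "g0"), ("m1", "g1"), ("m2", "g2")]
        kept = screen_pairs(mirna, mrna, pairs)
        ids = [r.pair_id for r in kept]
        assert ("m0", "g0") in ids  # negative and significant
        assert ("m1", "g1") not in ids  # wrong sign despite tiny p
        assert ("m2", "g2") not in ids  # noise

    def test_unsigned_mode_keeps_positive(self):
        rng = np.random.default_rng(8)
        mirna, mrna = self._matrices(rng)
        kept = screen_pairs(
            mirna, mrna, [("m0", "g0"), ("m1", "g1")], signed=False
        )
        assert ("m1", "g1") in [r.pair_id for r in kept]

    def test_absent_feature_dropped_not_fatal(self):
        rng = np.random.default_rng(8)
        mirna, mrna = self._matrices(rng)
        kept = screen_pairs(mirna, mrna, [("m0", "g0"), ("mX", "g0")])
        assert [r.pair_id for r in kept] == [("m0", "g0")]

    def test_output_subset_of_candidates(self):
        rng = np.random.default_rng(9)
        mirna, mrna = self._matrices(rng)
        pairs = [("m0", "g0"), ("m1", "g1"), ("m2", "g2")]
        kept = screen_pairs(mirna, mrna, pairs)
        assert {r.pair_id for r in kept} <= set(pairs)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(10)
        mirna, mrna = self._matrices(rng)
        pairs = [("m0", "g0"), ("m1", "g1"), ("m2", "g2")]
        a = screen_pairs(mirna, mrna, pairs)
        mirna_t = ExpressionMatrix(np.exp(mirna.values / 2.0))
        mrna_t = ExpressionMatrix(mrna.values**3)
        b = screen_pairs(mirna_t, mrna_t, pairs)
        assert [r.pair_id for r in a] == [r.pair_id for r in b]
        np.testing.assert_allclose(
            [r.rho for r in a], [r.rho for r in b], atol=1e-12
        )


class TestConcordantPairs:
    @staticmethod
    def record(mirna, gene, rho, q, tag):
        return PairRecord(
            mirna_id=mirna, gene_id=gene, rho=rho, p_value=q / 2, q_value=q,
            cohort_tag=tag, n_samples=50,
        )

    def test_pair_in_both_cohorts_retained(self):
        a = [self.record("miR-31-5p", "SATB2", -0.4, 0.01, "a")]
        b = [self.record("miR-31-5p", "SATB2", -0.3, 0.05, "b")]
        assert concordant_pairs(a, b) == [("miR-31-5p", "SATB2")]

    def test_single_cohort_pair_excluded(self):
        a = [self.record("m", "g", -0.4, 0.01, "a")]
        assert concordant_pairs(a, []) == []

    def test_empty_screens(self):
        assert concordant_pairs([], []) == []

    def test_sorted_by_worst_q(self):
        a = [self.record("m1", "g1", -0.4, 0.09, "a"), self.record("m2", "g2", -0.5, 0.01, "a")]
        b = [self.record("m1", "g1", -0.4, 0.02, "b"), self.record("m2", "g2", -0.5, 0.03, "b")]
        assert concordant_pairs(a, b) == [("m2", "g2"), ("m1", "g1")]


class TestPlantedPairRecovery:
    def test_twin_cohorts_recover_planted_pairs(self):
        """Concordant screening recovers >= 80% of planted inverse
        pairs with <= 10% decoy contamination (multi-seed average)."""
        recovered, contaminated, totals = [], [], []
        for seed in range(80, 88):
            config = SimulationConfig(
                seed=seed, n_samples_per_cohort=127, n_mirna=300, n_mrna=300,
                n_planted_mirna=6, planted_fold_changes=(2.0,) * 6,
                n_planted_pairs=3, pair_effect=-1.0,
            )
            screens = []
            truth = None
            for tag in ("discovery", "validation"):
                counts, mrna, ann, truth = simulate_cohort(config, tag)
                mat, sf = prepare_counts(counts)
                mirna_expr = normalize_counts(mat, sf)
                targets = simulate_target_map(truth, n_decoy_edges=30, seed=seed)
                pairs = candidate_pairs(sorted(truth.planted_mirna_ids), targets)
                screens.append(
                    screen_pairs(mirna_expr, mrna, pairs, cohort_tag=tag)
                )
            conc = set(concordant_pairs(*screens))
            planted = set(truth.planted_pairs)
            recovered.append(len(conc & planted) / len(planted))
            contaminated.append(len(conc - planted))
            totals.append(max(len(conc), 1))
        assert np.mean(recovered) >= 0.8
        assert np.mean(np.array(contaminated) / np.array(totals)) <= 0.1
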