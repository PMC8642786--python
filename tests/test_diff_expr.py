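import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirstage import (
    SizeFactors,
    ValidationError,
    bh_adjust,
    estimate_dispersion,
    filter_discovery,
    nb_wald_test,
)
from mirstage.datatypes import DETable

from conftest import make_annotation, make_counts


def brute_force_bh(p):
    """Literal step-up definition, kept independent of the implementation."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestDispersion:
    def test_poisson_like_hits_floor(self):
        # equidispersed counts: the moment formula goes non-positive
        # and lands on the floor
        rng = np.random.default_rng(1)
        y = rng.poisson(50.0, size=500)
        assert estimate_dispersion(y, np.ones(500)) == 1e-8

    def test_constant_vector_hits_floor(self):
        assert estimate_dispersion([7] * 20, np.ones(20)) == 1e-8

    def test_recovers_simulated_nb_dispersion(self):
        rng = np.random.default_rng(1)
        alpha, mu, n = 0.5, 80.0, 2000
        size = 1.0 / alpha
        y = rng.negative_binomial(size, size / (size + mu), size=n)
        assert 0.4 <= estimate_dispersion(y, np.ones(n)) <= 0.6

    def test_needs_four_samples(self):
        with pytest.raises(ValidationError):
            estimate_dispersion([1, 2, 3], np.ones(3))


class TestNbWaldTest:
    def test_equal_group_means_give_zero_log2fc(self):
        counts = make_counts(np.full((3, 8), 25))
        ann = make_annotation(["I"] * 4 + ["II_III"] * 4)
        sf = SizeFactors(pd.Series(np.ones(8), index=counts.sample_ids))
        de = nb_wald_test(counts, ann, sf)
        np.testing.assert_allclose(de.frame["log2fc"], 0.0, atol=1e-8)
        np.testing.assert_allclose(de.frame["wald_stat"], 0.0, atol=1e-8)

    def test_wald_sign_matches_fold_change_sign(self, small_de):
        f = small_de.frame
        nz = f[f["log2fc"].abs() > 1e-12]
        assert (np.sign(nz["wald_stat"]) == np.sign(nz["log2fc"])).all()

    def test_recovers_planted_fold_change(self):
        # 200 features planted at fold change 2.0, n = 127 (41 vs 86)
        rng = np.random.default_rng(12)
        n1, n2, alpha = 41, 86, 0.2
        size = 1.0 / alpha
        mu = rng.uniform(30, 300, size=200)
        early = rng.negative_binomial(size, size / (size + mu[:, None]), size=(200, n1))
        late = rng.negative_binomial(
            size, size / (size + 2.0 * mu[:, None]), size=(200, n2)
        )
        counts = make_counts(np.hstack([early, late]))
        ann = make_annotation(["I"] * n1 + ["II_III"] * n2)
        sf = SizeFactors(pd.Series(np.ones(n1 + n2), index=counts.sample_ids))
        de = nb_wald_test(counts, ann, sf)
        assert abs(de.frame["log2fc"].mean() - 1.0) < 0.15

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(3)
        alpha, n = 0.3, 127
        size = 1.0 / alpha
        mu = rng.uniform(20, 500, size=1000)
        counts = make_counts(
            rng.negative_binomial(size, size / (size + mu[:, None]), size=(1000, n))
        )
        ann = make_annotation(["I"] * 41 + ["II_III"] * 86)
        sf = SizeFactors(pd.Series(np.ones(n), index=counts.sample_ids))
        de = nb_wald_test(counts, ann, sf)
        ks = stats.kstest(de.frame["p_value"], "uniform").statistic
        assert ks < 0.05

    def test_matches_statsmodels_nb_glm(self):
        # independent engine: statsmodels NB GLM with the same fixed
        # dispersion and log-size-factor offset
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n1 = n2 = 30
        y = np.concatenate(
            [rng.negative_binomial(5, 5 / (5 + 40.0), n1),
             rng.negative_binomial(5, 5 / (5 + 90.0), n2)]
        )
        counts = make_counts(y[None, :])
        ann = make_annotation(["I"] * n1 + ["II_III"] * n2)
        sf_vals = np.exp(rng.normal(0, 0.1, n1 + n2))
        sf_vals /= np.exp(np.mean(np.log(sf_vals)))
        sf = SizeFactors(pd.Series(sf_vals, index=counts.sample_ids))
        de = nb_wald_test(counts, ann, sf)
        alpha = estimate_dispersion(y, sf_vals)
        design = np.column_stack([np.ones(n1 + n2), [0] * n1 + [1] * n2])
        fit = sm.GLM(
            y,
            design,
            family=sm.families.NegativeBinomial(alpha=alpha),
            offset=np.log(sf_vals),
        ).fit()
        assert de.frame["log2fc"].iloc[0] == pytest.approx(
            fit.params[1] / np.log(2), rel=1e-4
        )
        assert de.frame["wald_stat"].iloc[0] == pytest.approx(
            fit.tvalues[1], rel=0.02
        )

    def test_zero_group_feature_flagged_and_finite(self):
        mat = np.vstack([
            np.r_[np.zeros(5, int), np.full(5, 40)],
            np.full(10, 30),
        ])
        counts = make_counts(mat)
        ann = make_annotation(["I"] * 5 + ["II_III"] * 5)
        sf = SizeFactors(pd.Series(np.ones(10), index=counts.sample_ids))
        de = nb_wald_test(counts, ann, sf)
        row = de.frame.iloc[0]
        assert row["zero_group"]
        assert np.isfinite(row["log2fc"]) and row["log2fc"] > 0
        assert not de.frame.iloc[1]["zero_group"]

    def test_one_group_empty_is_error(self):
        counts = make_counts(np.full((2, 6), 10))
        ann = make_annotation(["II_III"] * 6)
        sf = SizeFactors(pd.Series(np.ones(6), index=counts.sample_ids))
        with pytest.raises(ValidationError):
            nb_wald_test(counts, ann, sf)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40)).tolist()
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValidationError):
            bh_adjust([])


class TestFilterDiscovery:
    @staticmethod
    def _table(rows):
        frame = pd.DataFrame(
            rows,
            columns=["log2fc", "q_value"],
            index=[f"m{i}" for i in range(len(rows))],
        )
        frame["wald_stat"] = np.sign(frame["log2fc"])
        frame["p_value"] = frame["q_value"]
        frame["mean_expression"] = 10.0
        return DETable(frame)

    def test_threshold_cases(self):
        table = self._table(
            [
                (np.log2(1.81), 5.68e-4),  # clear hit, overexpressed late
                (np.log2(1.40), 0.001),    # fold change below 1.5
                (np.log2(0.50), 0.01),     # underexpression passes on |log2fc|
                (np.log2(2.00), 0.05),     # q not strictly below threshold
                (np.log2(1.50), 0.001),    # |log2fc| not strictly above log2(1.5)
            ]
        )
        kept = filter_discovery(table)
        assert kept.feature_ids == ["m0", "m2"]

    def test_subset_and_idempotent(self, small_de):
        kept = filter_discovery(small_de)
        assert set(kept.feature_ids) <= set(small_de.feature_ids)
        again = filter_discovery(kept)
        assert again.feature_ids == kept.feature_ids
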