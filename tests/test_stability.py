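import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from metstab.data import DataError, TwoWayMeans
from metstab.stability import (
    ReplicateError,
    finlay_wilkinson,
    kang_selection,
    kang_ys,
    lin_binns_pi,
    shukla_sigma2,
    stability_report,
    wricke_ecovalence,
)


def matrix(values, entities=None, envs=None):
    values = np.asarray(values, dtype=float)
    p, q = values.shape
    entities = entities or [f"e{i}" for i in range(p)]
    envs = envs or [f"env{j}" for j in range(q)]
    return TwoWayMeans(entities, envs, values, np.ones((p, q), dtype=int))


random_matrices = arrays(
    dtype=float,
    shape=st.tuples(st.integers(3, 8), st.integers(3, 8)),
    elements=st.floats(-100, 100, allow_nan=False, width=32),
).filter(lambda x: np.ptp(x.mean(axis=0)) > 1e-6)


class TestFinlayWilkinson:
    def test_identity_rows(self):
        base = np.array([10.0, 12.0, 15.0, 20.0])
        m = matrix(np.tile(base, (3, 1)))
        fw = finlay_wilkinson(m)
        np.testing.assert_allclose(fw.b, 1.0)
        np.testing.assert_allclose(fw.p_vs_1, 1.0)

    def test_flat_entity_slope_zero(self):
        m = matrix([[10, 12, 14, 16], [8, 12, 16, 20], [12, 12, 12, 12]])
        fw = finlay_wilkinson(m)
        assert fw.b.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols_oracle(self):
        m = matrix([[10, 12, 14, 16], [8, 12, 16, 20], [12, 12, 12, 12]])
        fw = finlay_wilkinson(m)
        x = m.values.mean(axis=0)
        for i, b in enumerate(fw.b):
            expected = np.polyfit(x, m.values[i], 1)[0]
            assert b == pytest.approx(expected, rel=1e-10)
        np.testing.assert_allclose(fw.b, [1.0, 2.0, 0.0], atol=1e-12)

    def test_needs_three_environments(self):
        with pytest.raises(DataError):
            finlay_wilkinson(matrix([[1, 2], [3, 4]]))

    def test_degenerate_index_rejected(self):
        with pytest.raises(DataError, match="degenerate"):
            finlay_wilkinson(matrix([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]))

    @given(random_matrices)
    @settings(max_examples=50, deadline=None)
    def test_mean_slope_is_one(self, x):
        fw = finlay_wilkinson(matrix(x))
        assert fw.b.mean() == pytest.approx(1.0, abs=1e-6)


class TestLinBinns:
    def test_row_maximal_entity_zero(self):
        m = matrix([[10, 20, 30], [5, 15, 25]])
        pi = lin_binns_pi(m)["pi"]
        assert pi.iloc[0] == 0.0
        assert pi.iloc[1] > 0

    def test_hand_evaluation(self):
        m = matrix([[10, 20], [8, 24]])
        pi = lin_binns_pi(m)["pi"]
        assert pi.iloc[0] == pytest.approx(4.0)
        assert pi.iloc[1] == pytest.approx(1.0)

    @given(random_matrices)
    @settings(max_examples=50, deadline=None)
    def test_formula_oracle(self, x):
        pi = lin_binns_pi(matrix(x))["pi"].to_numpy()
        p, q = x.shape
        best = x.max(axis=0)
        for i in range(p):
            expected = sum((x[i, j] - best[j]) ** 2 for j in range(q)) / (2 * q)
            assert pi[i] == pytest.approx(expected, rel=1e-10, abs=1e-10)

    @given(random_matrices)
    @settings(max_examples=50, deadline=None)
    def test_zero_iff_row_maximal(self, x):
        pi = lin_binns_pi(matrix(x))["pi"].to_numpy()
        best = x.max(axis=0)
        for i in range(x.shape[0]):
            assert (pi[i] == 0.0) == np.allclose(x[i], best)


class TestWricke:
    def test_additive_matrix_zero(self):
        g = np.array([1.0, 5.0, -2.0])
        e = np.array([10.0, 20.0, 15.0, 12.0])
        m = matrix(g[:, None] + e[None, :])
        np.testing.assert_allclose(wricke_ecovalence(m)["w2"], 0.0, atol=1e-18)

    @given(random_matrices)
    @settings(max_examples=50, deadline=None)
    def test_sum_equals_interaction_ss(self, x):
        w2 = wricke_ecovalence(matrix(x))["w2"].to_numpy()
        inter = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
        ss_ge = (inter**2).sum()
        assert w2.sum() == pytest.approx(ss_ge, rel=1e-8, abs=1e-8)

    def test_double_loop_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.normal(50, 10, size=(3, 4))
        w2 = wricke_ecovalence(matrix(x))["w2"].to_numpy()
        p, q = x.shape
        grand = x.mean()
        for i in range(p):
            expected = 0.0
            for j in range(q):
                expected += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
            assert w2[i] == pytest.approx(expected, abs=1e-10)


class TestShukla:
    def test_additive_matrix_zero(self):
        g = np.array([1.0, 5.0, -2.0])
        e = np.array([10.0, 20.0, 15.0])
        m = matrix(g[:, None] + e[None, :])
        np.testing.assert_allclose(shukla_sigma2(m)["sigma2"], 0.0, atol=1e-12)

    @given(random_matrices)
    @settings(max_examples=50, deadline=None)
    def test_linear_transform_of_w2(self, x):
        p, q = x.shape
        w2 = wricke_ecovalence(matrix(x))["w2"].to_numpy()
        sigma2 = shukla_sigma2(matrix(x))["sigma2"].to_numpy()
        for i in range(p):
            expected = p * w2[i] / ((p - 2) * (q - 1)) - w2.sum() / (
                (p - 1) * (p - 2) * (q - 1)
            )
            assert sigma2[i] == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_negative_values_retained(self):
        # one highly interactive entity drives others' sigma2 negative
        x = np.array(
            [[10.0, 10.0, 10.0, 10.0], [12.0, 12.0, 12.0, 12.0], [0.0, 30.0, 0.0, 30.0]]
        )
        sigma2 = shukla_sigma2(matrix(x))["sigma2"].to_numpy()
        assert sigma2.min() < 0

    def test_needs_three_entities(self):
        with pytest.raises(DataError):
            shukla_sigma2(matrix([[1.0, 2.0, 3.0], [3.0, 1.0, 5.0]]))

    def test_stars_require_replicate_error(self):
        m = matrix(np.random.default_rng(1).normal(50, 5, (4, 5)))
        out = shukla_sigma2(m)
        assert out["stars"].isna().all() or (out["stars"].isnull()).all()
        err = ReplicateError(error_ms=4.0, error_df=100, n_per_mean=3)
        out2 = shukla_sigma2(m, err)
        assert out2["stars"].notna().all()


def kang_oracle(x, error_ms, error_df, n_per_mean):
    """Rule-by-rule scripted oracle for the rank-sum statistic."""
    p, q = x.shape
    means = x.mean(axis=1)
    # rule 1: yield ranks, highest mean = p, ties averaged
    ranks = stats.rankdata(means)
    # rule 2: LSD adjustment of ranks
    tcrit = stats.t.ppf(0.975, error_df)
    lsd = tcrit * np.sqrt(2 * error_ms / (n_per_mean * q))
    grand = means.mean()
    adj = np.zeros(p)
    for i in range(p):
        d = means[i] - grand
        k = 0
        while abs(d) > (k + 1) * lsd:
            k += 1
        adj[i] = np.sign(d) * k
    # rule 3: stability rating from sigma2 significance
    w2 = []
    for i in range(p):
        w2.append(((x[i] - x[i].mean() - x.mean(axis=0) + x.mean()) ** 2).sum())
    w2 = np.array(w2)
    sigma2 = p * w2 / ((p - 2) * (q - 1)) - w2.sum() / ((p - 1) * (p - 2) * (q - 1))
    rating = np.zeros(p)
    for i in range(p):
        f = sigma2[i] / (error_ms / n_per_mean)
        pv = stats.f.sf(f, q - 1, error_df) if f > 0 else 1.0
        if pv < 0.001:
            rating[i] = -8
        elif pv < 0.01:
            rating[i] = -4
        elif pv < 0.05:
            rating[i] = -2
    # rules 4-5: sum and selection
    ys = ranks + adj + rating
    return ys, ys > ys.mean()


class TestKang:
    def test_printed_selection_flags(self):
        # YS values with mean 0.6: positive entities selected
        ys = [8, 5, 2, -7, -5]
        assert kang_selection(ys) == [True, True, True, False, False]

    def test_degenerate_identical_entities(self):
        m = matrix(np.tile(np.array([10.0, 11.0, 12.0, 13.0]), (4, 1)))
        err = ReplicateError(error_ms=4.0, error_df=60, n_per_mean=3)
        out = kang_ys(m, err)
        assert (out.yield_rank == 2.5).all()
        assert (out.ys == out.ys.iloc[0]).all()
        assert not out.selected.any()  # strict inequality

    def test_matches_rule_by_rule_oracle(self):
        rng = np.random.default_rng(31)
        x = rng.normal(500, 60, size=(5, 15)) + rng.normal(0, 25, size=(5, 15))
        err = ReplicateError(error_ms=900.0, error_df=120, n_per_mean=3)
        out = kang_ys(matrix(x), err)
        ys, selected = kang_oracle(x, err.error_ms, err.error_df, err.n_per_mean)
        np.testing.assert_allclose(out.ys, ys)
        assert list(out.selected) == list(selected)

    def test_unadjusted_without_replicate_error(self):
        m = matrix(np.random.default_rng(4).normal(500, 50, (5, 6)))
        out = kang_ys(m)
        assert not out.adjusted.any()
        assert (out.rank_adjustment == 0).all()
        assert (out.stability_rating == 0).all()


class TestInvariants:
    @given(random_matrices, st.floats(-500, 500))
    @settings(max_examples=30, deadline=None)
    def test_constant_shift_invariance(self, x, c):
        m1, m2 = matrix(x), matrix(x + c)
        np.testing.assert_allclose(
            finlay_wilkinson(m1).b, finlay_wilkinson(m2).b, atol=1e-6
        )
        np.testing.assert_allclose(
            lin_binns_pi(m1).pi, lin_binns_pi(m2).pi, atol=1e-5
        )
        np.testing.assert_allclose(
            wricke_ecovalence(m1).w2, wricke_ecovalence(m2).w2, atol=1e-5
        )
        np.testing.assert_allclose(
            shukla_sigma2(m1).sigma2, shukla_sigma2(m2).sigma2, atol=1e-5
        )

    @given(random_matrices, st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_scaling_invariance_of_b_and_ranks(self, x, s):
        m1, m2 = matrix(x), matrix(x * s)
        np.testing.assert_allclose(
            finlay_wilkinson(m1).b, finlay_wilkinson(m2).b, atol=1e-6
        )
        np.testing.assert_allclose(
            kang_ys(m1).yield_rank, kang_ys(m2).yield_rank
        )

    def test_power_outlier_genotype_detected(self):
        """An entity with double the interaction SD tops W2 in >= 95% of runs."""
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            p, q = 8, 10
            base = rng.normal(500, 40, size=q)
            noise = rng.normal(0, 10, size=(p, q))
            noise[0] *= 3.0  # outlier entity
            x = base[None, :] + noise
            w2 = wricke_ecovalence(matrix(x))["w2"].to_numpy()
            sigma2 = shukla_sigma2(matrix(x))["sigma2"].to_numpy()
            if w2.argmax() == 0 and sigma2.argmax() == 0:
                hits += 1
        assert hits / n_rep >= 0.95


class TestStabilityReport:
    def test_weighted_ac_slope_mean_is_one(self, default_sim):
        config, records, _, _ = default_sim
        rep = stability_report(records, config.genotypes)
        sizes = rep.genotype.groupby("ac").size()
        ac_b = rep.ac_summary.set_index("ac")["b"]
        weighted = (ac_b * sizes).sum() / sizes.sum()
        assert weighted == pytest.approx(1.0, abs=1e-10)

    def test_ac_summary_is_mean_of_members(self, default_sim):
        config, records, _, _ = default_sim
        rep = stability_report(records, config.genotypes)
        for ac, grp in rep.genotype.groupby("ac"):
            row = rep.ac_summary.set_index("ac").loc[ac]
            assert row["pi"] == pytest.approx(grp["pi"].mean(), rel=1e-12)
            assert row["b"] == pytest.approx(grp["b"].mean(), rel=1e-12)

    def test_true_slope_recovery(self, default_sim):
        from scipy.stats import spearmanr

        config, records, _, truth = default_sim
        rep = stability_report(records, config.genotypes)
        est = dict(zip(rep.genotype.entity, rep.genotype.b))
        genos = sorted(est)
        rho = spearmanr(
            [truth.true_fw_slope[g] for g in genos], [est[g] for g in genos]
        ).statistic
        assert rho > 0.9

    def test_true_slopes_within_ci(self, default_sim):
        config, records, _, truth = default_sim
        rep = stability_report(records, config.genotypes)
        q = 15
        tcrit = stats.t.ppf(0.975, q - 2)
        inside = 0
        for row in rep.genotype.itertuples():
            lo, hi = row.b - tcrit * row.se, row.b + tcrit * row.se
            if lo <= truth.true_fw_slope[row.entity] <= hi:
                inside += 1
        assert inside >= 0.9 * len(rep.genotype)

    def test_both_levels_emitted(self, default_sim):
        config, records, _, _ = default_sim
        rep = stability_report(records, config.genotypes)
        assert len(rep.genotype) == 23
        assert len(rep.ac_summary) == 5
        assert len(rep.ac_direct) == 5
        assert set(rep.ac_letters) >= {"mean", "b", "pi", "sigma2", "w2", "ys"}
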