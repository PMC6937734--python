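import numpy as np
import pytest
from scipy import stats

from retroproteo import lfq_enrichment as lfq
from retroproteo.io_formats import RawIntensityTable


def make_matrix(values, groups=None, imputed=None, ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    groups = groups or ["case"] * (m // 2) + ["control"] * (m - m // 2)
    return lfq.IntensityMatrix(
        protein_ids=ids or [f"P{i}" for i in range(n)],
        samples=[f"s{j}" for j in range(m)],
        groups=groups,
        log2_values=values,
        imputed_mask=imputed if imputed is not None else np.zeros((n, m), dtype=bool),
    )


class TestPreprocess:
    def raw(self):
        return RawIntensityTable(
            protein_ids=["P1", "REV_P2", "IGHG1_HUMAN", "P4", "P5"],
            sample_columns=["a", "b"],
            values=np.array([
                [8.0, 4.0],
                [8.0, 8.0],
                [8.0, 8.0],
                [0.0, 0.0],
                [0.0, 16.0],
            ]),
            reverse_flags=np.array([False, True, False, False, False]),
            contaminant_flags=np.zeros(5, dtype=bool),
        )

    def test_filters_and_log2(self):
        matrix = lfq.preprocess(self.raw(), ["case", "control"])
        assert matrix.protein_ids == ["P1", "P5"]  # reverse, IGHG1, all-zero removed
        assert matrix.log2_values[0, 0] == pytest.approx(3.0)  # log2(8)
        assert np.isnan(matrix.log2_values[1, 0])  # zero becomes missing
        assert matrix.log2_values[1, 1] == pytest.approx(4.0)

    def test_empty_after_filtering_raises(self):
        raw = RawIntensityTable(["IGHG1"], ["a"], np.array([[5.0]]))
        with pytest.raises(ValueError):
            lfq.preprocess(raw, ["case"])


class TestImputeGroupMissing:
    def base(self, n_extra_missing=1):
        rng = np.random.default_rng(7)
        observed = rng.normal(20, 2, size=(50, 6))
        missing = np.full((n_extra_missing, 6), np.nan)
        missing[:, 3:] = rng.normal(20, 2, size=(n_extra_missing, 3))
        return make_matrix(np.vstack([observed, missing]))

    def test_draws_within_interval_and_mask_set(self):
        matrix = self.base(5)
        out = lfq.impute_group_missing(matrix, "case", seed=11)
        for c in range(3):
            col = matrix.log2_values[:, c]
            observed = col[np.isfinite(col)]
            mu, sd = observed.mean(), observed.std(ddof=1)
            imputed = out.log2_values[out.imputed_mask[:, c], c]
            assert len(imputed) == 5
            assert ((imputed >= mu - 3 * sd) & (imputed <= mu - 2 * sd)).all()

    def test_observed_values_untouched(self):
        matrix = self.base(5)
        out = lfq.impute_group_missing(matrix, "case", seed=11)
        observed = np.isfinite(matrix.log2_values)
        np.testing.assert_array_equal(
            out.log2_values[observed], matrix.log2_values[observed]
        )
        assert not out.imputed_mask[observed].any()

    def test_deterministic_under_seed(self):
        matrix = self.base(5)
        a = lfq.impute_group_missing(matrix, "case", seed=11)
        b = lfq.impute_group_missing(matrix, "case", seed=11)
        np.testing.assert_array_equal(a.log2_values, b.log2_values)

    def test_degenerate_sigma_gives_exact_mean(self):
        values = np.array([[20.0, 20.0, 20.0, 1.0, 1.0, 1.0],
                           [20.0, 20.0, 20.0, 1.0, 1.0, 1.0],
                           [np.nan, np.nan, np.nan, 1.0, 1.0, 1.0]])
        matrix = make_matrix(values, groups=["case"] * 3 + ["control"] * 3)
        out = lfq.impute_group_missing(matrix, "case", seed=0)
        assert out.log2_values[2, 0] == pytest.approx(20.0)  # sigma = 0

    def test_underdetermined_column_raises(self):
        values = np.array([[20.0, np.nan, np.nan, 1.0, 1.0, 1.0],
                           [np.nan, np.nan, np.nan, 1.0, 1.0, 1.0]])
        matrix = make_matrix(values, groups=["case"] * 3 + ["control"] * 3)
        with pytest.raises(ValueError, match="fewer than 2"):
            lfq.impute_group_missing(matrix, "case", seed=0)

    def test_uniformity_ks(self):
        """1e4 draws on one column pass a KS test against the uniform law."""
        rng = np.random.default_rng(1)
        observed = rng.normal(22, 1.5, size=(200, 6))
        missing = np.full((10_000, 6), np.nan)
        missing[:, 1:3] = rng.normal(22, 1.5, size=(10_000, 2))
        missing[:, 3:] = rng.normal(22, 1.5, size=(10_000, 3))
        missing[:, 1] = np.nan  # rows all-missing in case need every case cell missing
        missing[:, 2] = np.nan
        matrix = make_matrix(np.vstack([observed, missing]))
        out = lfq.impute_group_missing(matrix, "case", seed=5)
        col = matrix.log2_values[:, 0]
        obs = col[np.isfinite(col)]
        mu, sd = obs.mean(), obs.std(ddof=1)
        draws = out.log2_values[out.imputed_mask[:, 0], 0]
        assert len(draws) == 10_000
        p = stats.kstest(draws, "uniform", args=(mu - 3 * sd, sd)).pvalue
        assert p > 0.01


class TestImputePartialMissing:
    def test_degenerate_model_returns_mean_of_observed(self):
        values = np.array([[20.0, 22.0, np.nan, 1.0, 1.0, 1.0]])
        matrix = make_matrix(values, groups=["case"] * 3 + ["control"] * 3)
        model = lfq.ImputationModel(mu_delta=0.0, sd_delta=0.0, mean_pairwise_correlation=0.9)
        out = lfq.impute_partial_missing(matrix, "case", model, seed=0)
        assert out.log2_values[0, 2] == pytest.approx(21.0)
        assert out.imputed_mask[0, 2]

    def test_small_spread_interval(self):
        values = np.array([[20.0, 22.0, np.nan, 1.0, 1.0, 1.0]] * 200)
        matrix = make_matrix(values, groups=["case"] * 3 + ["control"] * 3)
        s = 0.002
        model = lfq.ImputationModel(
            mu_delta=0.0, sd_delta=s * np.sqrt(2) * 0.9, mean_pairwise_correlation=0.9
        )
        out = lfq.impute_partial_missing(matrix, "case", model, seed=1)
        imputed = out.log2_values[:, 2]
        assert ((imputed > 21 - 4 * 21 * s) & (imputed < 21 + 4 * 21 * s)).all()

    def test_nonpositive_correlation_raises(self):
        values = np.array([[20.0, 22.0, np.nan, 1.0, 1.0, 1.0]])
        matrix = make_matrix(values, groups=["case"] * 3 + ["control"] * 3)
        model = lfq.ImputationModel(mu_delta=0.0, sd_delta=0.1, mean_pairwise_correlation=-0.2)
        with pytest.raises(ValueError, match="correlation"):
            lfq.impute_partial_missing(matrix, "case", model, seed=0)

    def test_ratio_distribution_matches_monte_carlo_oracle(self):
        """I_new/mean(other) should be distributed as |1 + N(mu, sd/(rho*sqrt(2)))|."""
        mu, sd, rho = 0.01, 0.35, 0.85
        values = np.tile([20.0, 24.0, np.nan, 1.0, 1.0, 1.0], (10_000, 1))
        matrix = make_matrix(values, groups=["case"] * 3 + ["control"] * 3)
        model = lfq.ImputationModel(mu_delta=mu, sd_delta=sd, mean_pairwise_correlation=rho)
        out = lfq.impute_partial_missing(matrix, "case", model, seed=2)
        ratio = out.log2_values[:, 2] / 22.0
        oracle = np.abs(1 + np.random.default_rng(99).normal(mu, sd / (rho * np.sqrt(2)), 200_000))
        p = stats.ks_2samp(ratio, oracle).pvalue
        assert p > 0.01


class TestFitImputationModel:
    def test_delta_moments_match_hand_computation(self):
        values = np.array([
            [10.0, 12.0, 11.0, 1.0, 1.0, 1.0],
            [20.0, 18.0, 19.0, 1.0, 1.0, 1.0],
            [30.0, 33.0, 27.0, 1.0, 1.0, 1.0],
            [np.nan, 5.0, 5.0, 1.0, 1.0, 1.0],  # not fully observed: excluded
        ])
        matrix = make_matrix(values, groups=["case"] * 3 + ["control"] * 3)
        model = lfq.fit_imputation_model(matrix, "case")
        deltas = []
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            for r in range(3):
                x, y = values[r, a], values[r, b]
                deltas.append((x - y) / ((x + y) / 2))
        assert model.mu_delta == pytest.approx(np.mean(deltas))
        assert model.sd_delta == pytest.approx(np.std(deltas, ddof=1))


class TestCompare:
    def test_identical_groups_not_significant(self):
        values = np.tile([5.0, 6.0, 7.0, 5.0, 6.0, 7.0], (3, 1))
        results = lfq.compare(make_matrix(values, groups=["case"] * 3 + ["control"] * 3))
        for r in results:
            assert r.log2_fold_change == 0.0
            assert not r.significant

    def test_t_statistic_matches_closed_form(self):
        case = np.array([24.0, 25.0, 26.5])
        ctrl = np.array([20.0, 20.5, 21.5])
        values = np.concatenate([case, ctrl])[None, :].repeat(2, axis=0)
        values[1] = [20, 20.3, 20.1, 20.2, 20.05, 20.15]  # filler row for BH
        matrix = make_matrix(values, groups=["case"] * 3 + ["control"] * 3)
        results = lfq.compare(matrix)
        # Welch statistic by hand
        s1, s2 = case.var(ddof=1), ctrl.var(ddof=1)
        t = (case.mean() - ctrl.mean()) / np.sqrt(s1 / 3 + s2 / 3)
        df = (s1 / 3 + s2 / 3) ** 2 / ((s1 / 3) ** 2 / 2 + (s2 / 3) ** 2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        assert results[0].p_value == pytest.approx(p)
        assert results[0].log2_fold_change == pytest.approx(case.mean() - ctrl.mean())

    def test_nonimputed_rule_blocks_significance(self):
        values = np.array([[30.0, 30.5, 29.5, 10.0, 10.2, 9.8]] * 3)
        imputed = np.zeros((3, 6), dtype=bool)
        imputed[0, 1:3] = True  # only one non-imputed case replicate
        matrix = make_matrix(values, groups=["case"] * 3 + ["control"] * 3, imputed=imputed)
        results = lfq.compare(matrix)
        assert results[0].n_nonimputed_case == 1
        assert not results[0].significant
        assert results[1].significant  # same stats, fully observed

    def test_zero_variance_equal_means_p_one(self):
        values = np.array([[5.0] * 6, [30.0, 30.5, 29.5, 10.0, 10.2, 9.8]])
        results = lfq.compare(make_matrix(values, groups=["case"] * 3 + ["control"] * 3))
        assert results[0].p_value == 1.0

    def test_bh_monotone_and_bounded(self, rng):
        values = rng.normal(20, 2, size=(300, 6))
        results = lfq.compare(make_matrix(values, groups=["case"] * 3 + ["control"] * 3))
        p = np.array([r.p_value for r in results])
        padj = np.array([r.p_adjusted for r in results])
        assert (padj >= p - 1e-12).all() and (padj <= 1.0).all()
        order_p = np.argsort(p, kind="stable")
        assert (np.diff(padj[order_p]) >= -1e-12).all()


class TestIntegrate:
    def comparison(self, sig_ids, all_ids):
        return [
            lfq.ComparisonResult(pid, 2.0, 0.001, 0.01, 3, pid in sig_ids)
            for pid in all_ids
        ]

    def test_tier_counts_match_plants(self):
        ids = [f"P{i}" for i in range(6)]
        comparisons = [
            ("c1", self.comparison({"P0", "P1", "P2"}, ids)),
            ("c2", self.comparison({"P1", "P2"}, ids)),
            ("c3", self.comparison({"P2"}, ids)),
        ]
        counts, tiers = lfq.integrate(comparisons)
        assert counts["P2"] == 3 and counts["P1"] == 2 and counts["P0"] == 1
        assert "P3" not in counts
        assert tiers == {1: 3, 2: 2, 3: 1}

    def test_two_of_three(self):
        ids = ["A", "B"]
        comparisons = [
            ("c1", self.comparison({"A"}, ids)),
            ("c2", self.comparison({"A"}, ids)),
            ("c3", self.comparison(set(), ids)),
        ]
        counts, tiers = lfq.integrate(comparisons)
        assert counts["A"] == 2
        assert tiers == {1: 1, 2: 1, 3: 0}


class TestRankBandIds:
    def cand(self, pid, logE, n, keratin=False, human=True, group=None):
        return lfq.BandCandidate(pid, logE, n, keratin, human, group)

    def test_empty(self):
        assert lfq.rank_band_ids([], "TRYP") == []

    def test_trypsin_cut_drops_lower_ranks(self):
        ids = [
            self.cand("A", -50, 100),
            self.cand("B", -40, 90),
            self.cand("TRYP", -30, 50),
            self.cand("C", -20, 80),
            self.cand("D", -10, 70),
        ]
        retained = [c.protein_id for c in lfq.rank_band_ids(ids, "TRYP")]
        assert retained == ["A", "B"]

    def test_psm_half_rule(self):
        ids = [self.cand("TOP", -50, 100), self.cand("LOW", -40, 40)]
        retained = [c.protein_id for c in lfq.rank_band_ids(ids, "TRYP")]
        assert retained == ["TOP"]  # 40 < 50% of 100

    def test_keratin_nonhuman_homology_filters(self):
        ids = [
            self.cand("TOP", -50, 100, group="g1"),
            self.cand("KER", -45, 90, keratin=True),
            self.cand("MOUSE", -44, 90, human=False),
            self.cand("HOMOLOG", -42, 80, group="g1"),
            self.cand("OK", -40, 60, group="g2"),
        ]
        retained = [c.protein_id for c in lfq.rank_band_ids(ids, "TRYP")]
        assert retained == ["TOP", "OK"]

    def test_idempotent(self, rng):
        ids = [
            self.cand(f"P{i}", float(-rng.integers(10, 90)), int(rng.integers(10, 120)),
                      keratin=bool(rng.random() < 0.2),
                      human=bool(rng.random() < 0.9),
                      group=f"g{int(rng.integers(0, 4))}")
            for i in range(25)
        ] + [self.cand("TRYP", -35.0, 30)]
        once = lfq.rank_band_ids(ids, "TRYP")
        twice = lfq.rank_band_ids(once, "TRYP")
        assert [c.protein_id for c in twice] == [c.protein_id for c in once]
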