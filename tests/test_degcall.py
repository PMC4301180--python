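"""Unit and property tests of normalization, ANOVA, BH, Tukey HSD, fold
changes and the assembled DEG-calling pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from conftest import make_dataset
from coldcourse import (
    anova_k_groups,
    bh_adjust,
    call_degs,
    classify_persistence,
    fold_change,
    median_normalize,
    studentized_range_sf,
    summarize_comparisons,
    tukey_pairwise_p,
)
from coldcourse.degcall import INDUCED, NOT_TESTED, REPRESSED, _anova_matrix, read_deg_table


class TestMedianNormalize:
    def test_equal_medians_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.5, 2.0, 9.0]})
        pd.testing.assert_frame_equal(median_normalize(m), m)

    def test_two_sample_scale_factors(self):
        m = pd.DataFrame({"a": [5.0, 10.0, 20.0], "b": [10.0, 20.0, 40.0]})
        out = median_normalize(m)  # medians 10 and 20, grand median 15
        pd.testing.assert_frame_equal(out, m * np.array([1.5, 0.75]))

    def test_equalizes_medians_and_preserves_ranks(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(np.exp(rng.normal(5, 1, size=(200, 6))))
        out = median_normalize(m)
        med = out.median(axis=0)
        assert np.allclose(med, med.iloc[0])
        for c in m.columns:
            assert (out[c].rank() == m[c].rank()).all()

    def test_zero_median_sample_rejected(self):
        m = pd.DataFrame({"a": [0.0, 0.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            median_normalize(m)


class TestAnova:
    def test_identical_means_give_f_zero(self):
        F, p = anova_k_groups([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_sums_of_squares_oracle(self):
        g1, g2 = [1.0, 1.2, 1.1], [2.0, 2.2, 2.1]
        F, p = anova_k_groups([g1, g2])
        ref_F, ref_p = stats.f_oneway(g1, g2)
        assert F == pytest.approx(ref_F, rel=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-12)

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 15))
        idx = np.repeat(np.arange(5), 3)
        F, p, _, _ = _anova_matrix(X, idx, 5)
        for row in range(20):
            groups = [X[row, idx == g] for g in range(5)]
            f_ref, p_ref = stats.f_oneway(*groups)
            assert F[row] == pytest.approx(f_ref, rel=1e-10)
            assert p[row] == pytest.approx(p_ref, rel=1e-10)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10_000, 15))
        idx = np.repeat(np.arange(5), 3)
        _, p, _, _ = _anova_matrix(X, idx, 5)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(rate - 0.05) < 3 * se

    def test_constant_gene_reports_p_one(self):
        F, p = anova_k_groups([[2.0, 2.0], [2.0, 2.0]])
        assert (F, p) == (0.0, 1.0)

    @pytest.mark.parametrize("groups", [[[1.0, 2.0]], [[1.0], [2.0, 3.0]]])
    def test_degenerate_groups_rejected(self, groups):
        with pytest.raises(ValueError):
            anova_k_groups(groups)


def _bh_literal(p):
    """Literal step-up definition: q_i = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_forced_step_up_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_literal_definition(self, p):
        assert bh_adjust(p) == pytest.approx(_bh_literal(p), abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_adjusted_at_least_raw_and_monotone(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestTukey:
    def test_equal_means_p_one(self):
        out = tukey_pairwise_p([2.0, 2.0, 3.0], [3, 3, 3], msw=1.0, df=6)
        pair = out[(out.group_a == 0) & (out.group_b == 1)]
        assert pair["p"].iloc[0] == pytest.approx(1.0)

    def test_k2_reduces_to_pooled_t_test(self):
        """For two groups the Tukey p equals the two-sided pooled t p."""
        a = np.array([1.0, 1.4, 0.9, 1.2])
        b = np.array([2.0, 2.3, 1.8, 2.2])
        msw = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6
        out = tukey_pairwise_p([a.mean(), b.mean()], [4, 4], msw, df=6)
        _, p_ref = stats.ttest_ind(a, b)
        assert out["p"].iloc[0] == pytest.approx(p_ref, abs=1e-4)

    def test_matches_scipy_distribution(self):
        qs = np.array([0.5, 1.5, 2.5, 3.5, 4.5, 6.0])
        for k, df in [(3, 4), (5, 10), (4, 30)]:
            ref = stats.studentized_range.sf(qs, k, df)
            assert studentized_range_sf(qs, k, df) == pytest.approx(ref, abs=1e-6)

    def test_p_monotone_decreasing_in_q(self):
        p = studentized_range_sf(np.linspace(0.1, 8, 100), 5, 10)
        assert (np.diff(p) < 0).all()

    def test_nonpositive_mean_square_rejected(self):
        with pytest.raises(ValueError):
            tukey_pairwise_p([1.0, 2.0], [3, 3], msw=0.0, df=4)


class TestFoldChange:
    def test_equal_means_unity(self):
        assert fold_change({0: 3.0, 24: 3.0}, (0, 24)) == 1.0

    def test_forced_ratio(self):
        assert fold_change({0: 3.0, 24: 6.0}, (0, 24)) == pytest.approx(2.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change({0: 0.0, 24: 6.0}, (0, 24))


class TestCallDegs:
    def test_forced_single_responder(self, five_point_dataset):
        """A gene with a huge effect at 8 and 24 h is a DEG exactly for the
        pairs separating {0,1,3} from {8,24}."""
        res = call_degs(five_point_dataset)
        gene = res.table.index[0]
        expected_deg = {(0.0, 8.0), (0.0, 24.0), (1.0, 8.0), (1.0, 24.0), (3.0, 8.0), (3.0, 24.0)}
        for pair in res.pairs:
            d = res.direction(pair)[gene]
            if pair in expected_deg:
                assert d == INDUCED, pair
            else:
                assert d not in (INDUCED, REPRESSED), pair

    def test_gate_failures_not_tested(self, five_point_dataset):
        res = call_degs(five_point_dataset)
        untested = res.table.index[~res.table["tested"]]
        assert len(untested) > 0
        pair = res.pairs[0]
        assert (res.direction(pair)[untested] == NOT_TESTED).all()
        assert res.table.loc[untested, res.table.columns[res.table.columns.str.startswith("tukey_p_0h_1h")]].isna().all().all()

    def test_zero_noise_planted_effect_exact_two_fold(self):
        """A +1 log2 planted effect survives normalization as exactly 2x."""
        n = 40
        means = {t: np.full(n, 100.0) for t in (0.0, 1.0, 3.0, 8.0, 24.0)}
        means[24.0] = means[24.0].copy()
        means[24.0][0] = 200.0
        data = make_dataset(means, noise_sd=0.0)
        # perturb one unrelated sample scale to force normalization to act
        data.matrix.iloc[:, 0] *= 3.0
        res = call_degs(data)
        assert res.fold_changes((0.0, 24.0)).iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_sensitivity_and_fdr_on_planted_data(self):
        """10% planted genes at +/-2 log2, noise 0.25: the pipeline recovers
        nearly all of them with controlled false discovery."""
        rng = np.random.default_rng(12)
        n, n_de = 2_000, 200
        tps = (0.0, 1.0, 3.0, 8.0, 24.0)
        sens, fdr = [], []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            means = {t: np.full(n, 200.0) for t in tps}
            signs = rng.choice([-1.0, 1.0], n_de)
            for t in (8.0, 24.0):
                means[t] = means[t].copy()
                means[t][:n_de] *= np.exp2(2.0 * signs)
            data = make_dataset(means, noise_sd=0.25, seed=seed)
            res = call_degs(data)
            called = res.any_deg_genes()
            true = set(res.table.index[:n_de])
            sens.append(len(called & true) / n_de)
            fdr.append(len(called - true) / max(1, len(called)))
        assert np.mean(sens) >= 0.95
        assert np.mean(fdr) <= 0.10


class TestPersistence:
    @pytest.fixture
    def persistence_dataset(self):
        n = 30
        tps = (0.0, 1.0, 3.0, 8.0, 24.0)
        means = {t: np.full(n, 100.0) for t in tps}
        for t in tps[1:]:
            means[t] = means[t].copy()
            means[t][0] = 800.0          # persistently induced
            means[t][2] = 12.0           # persistently repressed
            if t != 24.0:
                means[t][1] = 800.0      # induced early, back to baseline at 24 h
        return make_dataset(means, noise_sd=0.05, seed=3)

    def test_flags_follow_definition(self, persistence_dataset):
        res = call_degs(persistence_dataset)
        flags = classify_persistence(res)
        g = res.table.index
        assert flags.loc[g[0], "persistent_induced"]
        assert not flags.loc[g[1], "persistent_induced"]  # lapses at 24 h
        assert flags.loc[g[2], "persistent_repressed"]
        assert not flags.loc[g[3], "persistent_induced"]


class TestSummaries:
    def test_counts_add_up_for_every_pair(self, five_point_dataset):
        res = call_degs(five_point_dataset)
        summary = summarize_comparisons(res)
        assert (summary["n_induced"] + summary["n_repressed"] == summary["n_deg"]).all()
        assert (summary["n_deg_2fold"] <= summary["n_deg"]).all()

    def test_empty_deg_set_reports_zero_counts(self):
        means = {t: np.full(20, 50.0) for t in (0.0, 1.0, 3.0)}
        data = make_dataset(means, noise_sd=0.3, seed=4)
        res = call_degs(data, alpha=1e-6)
        summary = summarize_comparisons(res)
        assert (summary["n_deg"] == 0).all()
        assert summary["fc_min"].isna().all()

    def test_table_roundtrip(self, five_point_dataset, tmp_path):
        res = call_degs(five_point_dataset)
        path = tmp_path / "deg.tsv"
        res.to_tsv(path)
        back = read_deg_table(path)
        assert back.pairs == res.pairs
        assert back.deg_genes((0.0, 24.0)) == res.deg_genes((0.0, 24.0))
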