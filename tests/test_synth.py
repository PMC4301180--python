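"""Tests of the synthetic time-series generator: determinism, marginal
calibration, effect injection, annotation structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coldcourse import (
    SimulationConfig,
    StageSpec,
    assign_annotations,
    call_degs,
    generate_dataset,
    inject_effects,
)
from coldcourse.degcall import _anova_matrix
from coldcourse.go_classes import STIMULUS_STRESS_TERMS, DEVELOPMENTAL_TERMS


def small_config(**kw):
    defaults = dict(n_genes=400, seed=5)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_genes": 0},
            {"n_replicates": 1},
            {"de_fraction": 1.5},
            {"orphan_fraction": -0.1},
            {"stage_profile": {"early": StageSpec(0.5), "late": StageSpec(0.2)}},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestGenerate:
    def test_same_seed_bit_identical(self):
        d1, a1, t1 = generate_dataset(small_config())
        d2, a2, t2 = generate_dataset(small_config())
        pd.testing.assert_frame_equal(d1.matrix, d2.matrix)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        d1, _, _ = generate_dataset(small_config())
        d2, _, _ = generate_dataset(small_config(seed=6))
        assert not d1.matrix.equals(d2.matrix)

    def test_shape_and_positivity(self):
        cfg = small_config()
        data, ann, truth = generate_dataset(cfg)
        assert data.matrix.shape == (cfg.n_genes, 5 * cfg.n_replicates)
        assert (data.matrix.to_numpy() > 0).all()
        assert list(ann.index) == list(data.gene_ids) == list(truth.index)

    def test_null_config_has_no_planted_effects(self):
        data, _, truth = generate_dataset(small_config(de_fraction=0.0))
        assert not truth["is_de"].any()
        effect_cols = [c for c in truth.columns if c.startswith("effect_log2_")]
        assert (truth[effect_cols].to_numpy() == 0).all()

    def test_orphan_fraction_binomially_calibrated(self):
        cfg = SimulationConfig(n_genes=10_000, orphan_fraction=0.12, seed=1)
        _, ann, _ = generate_dataset(cfg)
        observed = ann["orphan"].mean()
        se = np.sqrt(0.12 * 0.88 / cfg.n_genes)
        assert abs(observed - 0.12) < 3 * se

    def test_de_and_stage_fractions_calibrated(self):
        cfg = SimulationConfig(n_genes=8_000, seed=2)
        _, _, truth = generate_dataset(cfg)
        de = truth["is_de"]
        se = np.sqrt(cfg.de_fraction * (1 - cfg.de_fraction) / cfg.n_genes)
        assert abs(de.mean() - cfg.de_fraction) < 3 * se
        n_de = int(de.sum())
        for stage, spec in cfg.stage_profile.items():
            frac = (truth.loc[de, "stage"] == stage).mean()
            se_s = np.sqrt(spec.fraction * (1 - spec.fraction) / n_de)
            assert abs(frac - spec.fraction) < 3 * se_s

    def test_null_anova_p_uniform(self):
        """With no planted effects the per-gene ANOVA p-values are uniform."""
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(n_genes=1_000, de_fraction=0.0, seed=seed)
            data, _, _ = generate_dataset(cfg)
            X = data.matrix.to_numpy(float)
            _, p, _, _ = _anova_matrix(X, data.group_index(), 5)
            if stats.kstest(p, "uniform").pvalue > 0.01:
                hits += 1
        assert hits >= 18


class TestInjectEffects:
    def test_empty_truth_is_identity(self):
        rng = np.random.default_rng(0)
        cfg = small_config()
        data, _, truth = generate_dataset(cfg)
        log2 = pd.DataFrame(
            rng.normal(8, 1, size=data.matrix.shape),
            index=data.gene_ids, columns=data.matrix.columns,
        )
        out = inject_effects(log2, data.design, truth.iloc[0:0])
        pd.testing.assert_frame_equal(out, log2)

    def test_single_gene_effect_doubles_group_mean(self):
        cfg = SimulationConfig(
            n_genes=50, noise_log2_sd=0.0, de_fraction=0.0, tap_family_sizes=[3], seed=0
        )
        data, _, truth = generate_dataset(cfg)
        truth = truth.copy()
        truth.loc[truth.index[0], "effect_log2_24h"] = 1.0
        log2 = np.log2(data.matrix)
        out = np.exp2(inject_effects(log2, data.design, truth))
        groups = data.groups()
        m0 = out.loc[truth.index[0], groups[0.0]].mean()
        m24 = out.loc[truth.index[0], groups[24.0]].mean()
        assert m24 == pytest.approx(2.0 * m0, rel=1e-12)
        other = truth.index[1]
        assert np.allclose(out.loc[other], data.matrix.loc[other])

    def test_unknown_gene_rejected(self):
        data, _, truth = generate_dataset(small_config())
        bad = truth.iloc[:1].rename(index={truth.index[0]: "no_such_gene"})
        with pytest.raises(KeyError):
            inject_effects(np.log2(data.matrix), data.design, bad)

    def test_fold_change_estimates_unbiased(self):
        """Planted +0.5/+1/+2 log2 effects are recovered without bias by the
        end-to-end fold-change estimator (normalization included)."""
        n = 500
        n_null = 3_000  # null majority with sign-balanced effects keeps medians anchored
        levels = np.repeat([0.5, 1.0, 2.0], n)
        signs = np.tile([1.0, -1.0], 3 * n // 2)
        effects = np.concatenate([levels * signs, np.zeros(n_null)])
        tps = (0.0, 24.0, 48.0)
        means = {t: np.full(len(effects), 300.0) for t in tps}
        means[24.0] = means[24.0] * np.exp2(effects)
        means[48.0] = means[48.0] * np.exp2(effects)
        from conftest import make_dataset

        data = make_dataset(means, noise_sd=0.25, seed=9)
        res = call_degs(data, normalize=True)
        est = np.log2(res.fold_changes((0.0, 24.0)).to_numpy())
        for e in (0.5, -0.5, 1.0, -1.0, 2.0, -2.0):
            sel = est[effects == e]
            mc_se = sel.std(ddof=1) / np.sqrt(len(sel))
            assert abs(sel.mean() - e) < 4 * mc_se + 0.01


class TestAnnotations:
    def test_degenerate_bias_gives_pure_stimulus_families(self):
        cfg = small_config(
            tap_family_sizes=[27], class_bias=1.0, p_both_class=0.0, p_unannotated_tap=0.0
        )
        _, _, truth = generate_dataset(cfg)
        ann = assign_annotations(cfg, truth.index, truth)
        members = ann[ann["tap_family"].notna()]
        assert len(members) == 27
        for terms in members["go_terms"]:
            assert terms & STIMULUS_STRESS_TERMS
            assert not terms & DEVELOPMENTAL_TERMS

    def test_orphan_independent_of_stage_without_enrichment(self):
        """orphan_early_enrichment = 1 leaves orphan status independent of
        the planted stage (chi-square non-significant in >= 18/20 seeds)."""
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(n_genes=4_000, orphan_early_enrichment=1.0, seed=seed)
            _, ann, truth = generate_dataset(cfg)
            de = truth["is_de"]
            early = (truth.loc[de, "stage"] == "early").to_numpy()
            orph = ann.loc[de.index[de], "orphan"].to_numpy()
            table = pd.crosstab(early, orph)
            if table.shape == (2, 2):
                p = stats.chi2_contingency(table).pvalue
                if p > 0.01:
                    hits += 1
            else:  # degenerate table: no association detectable
                hits += 1
        assert hits >= 18

    def test_orphan_enrichment_concentrates_on_early_stage(self):
        cfg = SimulationConfig(n_genes=20_000, orphan_early_enrichment=2.0, seed=3)
        _, ann, truth = generate_dataset(cfg)
        de = truth["is_de"]
        early_genes = truth.index[de & (truth["stage"] == "early")]
        other_genes = truth.index[~truth.index.isin(early_genes)]
        r_early = ann.loc[early_genes, "orphan"].mean()
        r_other = ann.loc[other_genes, "orphan"].mean()
        assert r_early > 1.5 * r_other
        # marginal rate is preserved
        se = np.sqrt(0.12 * 0.88 / cfg.n_genes)
        assert abs(ann["orphan"].mean() - 0.12) < 3 * se
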