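import numpy as np
import pandas as pd
import pytest

from maturix.io import PARENTAL_MAP
from maturix.mixedlm import MixedModelEngine
from maturix.simulate import (
    SimulationConfig,
    simulate_design,
    simulate_expression,
    simulate_genesets,
    simulate_qpcr,
    true_overall_log2fc,
)


class TestDesign:
    def test_default_matches_study_layout(self):
        d = simulate_design(SimulationConfig(seed=0))
        assert d["sow_id"].nunique() == 18
        assert 54 <= len(d) <= 72  # 18 litters of 3-4
        assert d.groupby(["age", "fetal_genotype"]).ngroups == 8

    def test_each_litter_has_purebred_and_crossbred(self):
        d = simulate_design(SimulationConfig(seed=1))
        for sow, grp in d.groupby("sow_id"):
            mat = grp["maternal_genotype"].iloc[0]
            cross = "MSLW" if mat == "LW" else "LWMS"
            assert mat in set(grp["fetal_genotype"])
            assert cross in set(grp["fetal_genotype"])

    def test_minimal_config_forced_by_crossing_rules(self):
        cfg = SimulationConfig(seed=2, n_sows_per_maternal_genotype=1,
                               fetuses_per_sow=(2, 2))
        d = simulate_design(cfg)
        assert len(d) == 4
        lw_litter = d[d["maternal_genotype"] == "LW"]
        assert set(lw_litter["fetal_genotype"]) == {"LW", "MSLW"}

    def test_single_fetus_litters_rejected(self):
        with pytest.raises(ValueError, match="purebred and a crossbred"):
            SimulationConfig(fetuses_per_sow=(1, 2))

    def test_same_seed_same_tables(self):
        d1 = simulate_design(SimulationConfig(seed=3))
        d2 = simulate_design(SimulationConfig(seed=3))
        pd.testing.assert_frame_equal(d1, d2)

    def test_parental_map_consistency(self):
        d = simulate_design(SimulationConfig(seed=4))
        for _, row in d.iterrows():
            mg, pg = PARENTAL_MAP[row["fetal_genotype"]]
            assert (row["maternal_genotype"], row["paternal_genotype"]) == (mg, pg)


class TestExpression:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=5, n_genes={"null": 10, "submodel3": 5})
        d = simulate_design(cfg)
        e1, t1 = simulate_expression(cfg, d)
        e2, t2 = simulate_expression(cfg, d)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_age_class_realises_planted_fold_change(self):
        cfg = SimulationConfig(seed=6, n_genes={"null": 0, "submodel3": 300})
        d = simulate_design(cfg)
        expr, truth = simulate_expression(cfg, d)
        d110 = (d["age"] == "d110").to_numpy()
        Y = expr.values.to_numpy()
        diff = Y[:, d110].mean(axis=1) - Y[:, ~d110].mean(axis=1)
        assert diff.mean() == pytest.approx(1.0, abs=0.1)
        assert (truth["true_log2fc_age_overall"] == 1.0).all()

    def test_every_class_marginal_fold_change_is_effect_size(self):
        """The generator's convention: |genotype-averaged age fold change| of
        every effectful class equals the configured effect size."""
        for cls in ("submodel1", "submodel2", "submodel3", "maternal_interaction",
                    "paternal_interaction", "network_block_1", "network_block_4"):
            assert abs(true_overall_log2fc(cls, 1.0)) == pytest.approx(1.0)
        assert true_overall_log2fc("submodel4", 1.0) == 0.0
        assert true_overall_log2fc("null", 1.0) == 0.0

    def test_littermates_share_sow_effect(self):
        """With a large sow variance and no residual-free contrast the
        intraclass correlation of null genes is high; with sigma_sow = 0 it
        vanishes."""

        def icc(sigma_sow, seed):
            cfg = SimulationConfig(seed=seed, sigma_sow=sigma_sow,
                                   n_genes={"null": 400})
            d = simulate_design(cfg)
            expr, _ = simulate_expression(cfg, d)
            Y = expr.values.to_numpy()
            sows = d["sow_id"].to_numpy()
            levels = sorted(set(sows))
            # one-way ANOVA moment estimator of the between-sow variance
            grand = Y.mean(axis=1, keepdims=True)
            ss_between, ss_within, df_b, df_w, n0 = 0.0, 0.0, 0, 0, 0.0
            counts = np.array([np.sum(sows == s) for s in levels])
            n = Y.shape[1]
            n0 = (n - (counts**2).sum() / n) / (len(levels) - 1)
            for s in levels:
                sel = sows == s
                m = Y[:, sel].mean(axis=1, keepdims=True)
                ss_between += (sel.sum() * (m - grand) ** 2).sum()
                ss_within += ((Y[:, sel] - m) ** 2).sum()
            ms_b = ss_between / (len(levels) - 1) / Y.shape[0]
            ms_w = ss_within / (n - len(levels)) / Y.shape[0]
            s2_sow = (ms_b - ms_w) / n0
            return s2_sow / (s2_sow + ms_w)

        assert icc(0.0, seed=7) == pytest.approx(0.0, abs=0.05)
        assert icc(0.3, seed=8) == pytest.approx(0.09 / 0.34, abs=0.1)

    def test_variance_decomposition_recovered(self):
        """Moment estimates over 1,000 null genes recover the generating
        (sigma_sow^2, sigma_resid^2) within 15%."""
        cfg = SimulationConfig(seed=9, n_genes={"null": 1000})
        d = simulate_design(cfg)
        expr, _ = simulate_expression(cfg, d)
        Y = expr.values.to_numpy()
        sows = d["sow_id"].to_numpy()
        levels = sorted(set(sows))
        n = Y.shape[1]
        counts = np.array([np.sum(sows == s) for s in levels])
        n0 = (n - (counts**2).sum() / n) / (len(levels) - 1)
        grand = Y.mean(axis=1, keepdims=True)
        ss_b = ss_w = 0.0
        for s in levels:
            sel = sows == s
            m = Y[:, sel].mean(axis=1, keepdims=True)
            ss_b += (sel.sum() * (m - grand) ** 2).sum()
            ss_w += ((Y[:, sel] - m) ** 2).sum()
        ms_b = ss_b / (len(levels) - 1) / Y.shape[0]
        ms_w = ss_w / (n - len(levels)) / Y.shape[0]
        assert ms_w == pytest.approx(0.25, rel=0.15)
        assert (ms_b - ms_w) / n0 == pytest.approx(0.09, rel=0.15)

    def test_block_genes_reach_target_correlation(self):
        cfg = SimulationConfig(seed=10, n_genes={"null": 0, "network_block_2": 15})
        d = simulate_design(cfg)
        expr, truth = simulate_expression(cfg, d)
        children = truth.index[truth["role"] == "child"]
        C = np.corrcoef(expr.values.loc[children].to_numpy())
        off = C[np.triu_indices_from(C, k=1)]
        assert off.mean() == pytest.approx(0.99, abs=0.01)


class TestGenesets:
    def _truth(self):
        idx = [f"P{i:05d}" for i in range(100)]
        return pd.DataFrame(
            {
                "gene": [f"G{i:05d}" for i in range(100)],
                "class": ["submodel1"] * 40 + ["null"] * 60,
                "block": [""] * 100,
                "role": [""] * 100,
                "true_log2fc_age_overall": [1.0] * 40 + [0.0] * 60,
            },
            index=idx,
        )

    def test_planted_set_drawn_from_up_classes(self):
        sets, name = simulate_genesets(SimulationConfig(seed=11), self._truth())
        up = {f"G{i:05d}" for i in range(40)}
        assert len(set(sets[name]) & up) >= 25

    def test_empty_truth_gives_empty_collection(self):
        truth = self._truth().iloc[:0]
        sets, _ = simulate_genesets(SimulationConfig(seed=12), truth)
        assert sets == {}

    def test_deterministic(self):
        s1, _ = simulate_genesets(SimulationConfig(seed=13), self._truth())
        s2, _ = simulate_genesets(SimulationConfig(seed=13), self._truth())
        assert s1 == s2


class TestQpcrTables:
    def test_noiseless_doubling_arithmetic(self):
        """With no Ct noise the dilution series falls exactly one cycle per
        halving for a gene at efficiency 2 (checked via the recovered
        slope against each gene's drawn efficiency)."""
        cfg = SimulationConfig(seed=14, n_genes={"null": 2, "submodel3": 3})
        d = simulate_design(cfg)
        expr, truth = simulate_expression(cfg, d)
        ct, dil, eff, _ = simulate_qpcr(cfg, truth, expr, noise_sd=0.0)
        for gene, grp in dil.groupby("gene"):
            grp = grp.sort_values("concentration", ascending=False)
            steps = np.diff(grp["Ct"].to_numpy())
            np.testing.assert_allclose(steps, np.log(2) / np.log(eff[gene]), atol=1e-9)

    def test_reference_gene_constant_without_noise(self):
        cfg = SimulationConfig(seed=15, n_genes={"null": 2, "submodel3": 3})
        d = simulate_design(cfg)
        expr, truth = simulate_expression(cfg, d)
        ct, _, _, _ = simulate_qpcr(cfg, truth, expr, noise_sd=0.0)
        ref = ct[ct["gene"] == "HPRT"]["Ct"]
        assert ref.nunique() == 1
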