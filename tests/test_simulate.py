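"""Synthetic-data generator: determinism, planted signal, fixtures."""

import numpy as np
import pandas as pd
import pytest

from chronopattern import (SyntheticConfig, assign_profiles, fit_twoway_anova,
                           generate_dataset, generate_genesets, log_transform,
                           run_ora)
from chronopattern.interaction import condition_profiles
from chronopattern.templates import build_template_library


class TestGenerateDataset:
    def test_shape_of_outputs(self):
        cfg = SyntheticConfig(n_genes=30, n_timepoints=7, n_replicates=3, seed=0)
        m, truth = generate_dataset(cfg)
        assert m.values.shape == (30, 2 * 7 * 3)
        assert len(truth) == 30
        assert set(truth.index) == set(m.genes)

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(n_genes=40, seed=123)
        m1, t1 = generate_dataset(cfg)
        m2, t2 = generate_dataset(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        m1, _ = generate_dataset(SyntheticConfig(n_genes=40, seed=1))
        m2, _ = generate_dataset(SyntheticConfig(n_genes=40, seed=2))
        assert not m1.values.equals(m2.values)

    def test_noiseless_profiles_correlate_exactly_with_truth(self):
        cfg = SyntheticConfig(n_genes=60, frac_patterned=1.0, noise_sd=0.0, seed=5)
        m, truth = generate_dataset(cfg)
        logm = log_transform(m, pseudocount=0.0)
        lib = build_template_library(cfg.analysis_hours)
        genes = list(m.genes)
        prof = (condition_profiles(logm, genes, "vehicle", cfg.analysis_hours)
                + condition_profiles(logm, genes, "drug", cfg.analysis_hours)) / 2
        z = (prof - prof.mean(axis=1, keepdims=True)) / prof.std(axis=1, keepdims=True)
        for i, g in enumerate(genes):
            tmpl = lib.shape(truth.loc[g, "shape"]).zscored()
            r = float(np.corrcoef(z[i], tmpl)[0, 1])
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_null_genes_have_flat_expectation(self):
        cfg = SyntheticConfig(n_genes=20, frac_patterned=0.0, noise_sd=0.0, seed=3)
        m, truth = generate_dataset(cfg)
        assert (truth["shape"] == "").all()
        vals = m.values.to_numpy()
        assert np.allclose(vals, vals[:, [0]])  # constant within each gene

    def test_drug_shift_applied_to_drug_samples_only(self):
        cfg = SyntheticConfig(n_genes=200, frac_patterned=1.0, noise_sd=0.0,
                              drug_shift=2.0, seed=6)
        m, truth = generate_dataset(cfg)
        logm = log_transform(m, pseudocount=0.0)
        up = truth.index[truth["drug_effect"] == "up"]
        assert len(up) > 0
        for g in up[:5]:
            veh = logm.values.loc[g, logm.samples_for("vehicle", 3.0)].mean()
            drug = logm.values.loc[g, logm.samples_for("drug", 3.0)].mean()
            assert drug - veh == pytest.approx(2.0, abs=1e-9)

    def test_localized_drug_effect_hours(self):
        cfg = SyntheticConfig(n_genes=100, frac_patterned=1.0, noise_sd=0.0,
                              drug_shift=2.0, drug_effect_hours=(5.0, 6.0), seed=6)
        m, truth = generate_dataset(cfg)
        logm = log_transform(m, pseudocount=0.0)
        g = truth.index[truth["drug_effect"] == "up"][0]
        early = (logm.values.loc[g, logm.samples_for("drug", 2.0)].mean()
                 - logm.values.loc[g, logm.samples_for("vehicle", 2.0)].mean())
        late = (logm.values.loc[g, logm.samples_for("drug", 5.0)].mean()
                - logm.values.loc[g, logm.samples_for("vehicle", 5.0)].mean())
        assert early == pytest.approx(0.0, abs=1e-9)
        assert late == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize("kw", [
        {"n_replicates": 1}, {"frac_patterned": 1.5}, {"noise_sd": -0.1},
        {"n_genes": 0},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticConfig(**kw)


class TestGenerateGenesets:
    def test_planted_set_is_flagged_by_ora(self):
        cfg = SyntheticConfig(n_genes=400, frac_patterned=0.3, seed=9)
        _, truth = generate_dataset(cfg)
        coll = generate_genesets(truth, n_sets=10, seed=9)
        planted_name = next(n for n in coll.sets if n.startswith("planted_"))
        shape = planted_name.split("_", 1)[1]
        query = truth.index[truth["shape"] == shape].tolist()
        recs = run_ora(query, coll, min_set=2, max_set=2000)
        by_name = {r.set_id: r for r in recs}
        assert by_name[planted_name].fdr <= 0.05

    def test_random_set_ps_approximately_uniform(self):
        """Null ORA p-values over repeated seeds: mean near 0.5, few extremes."""
        cfg = SyntheticConfig(n_genes=300, frac_patterned=0.2, seed=4)
        _, truth = generate_dataset(cfg)
        rng = np.random.default_rng(0)
        ps = []
        for seed in range(60):
            coll = generate_genesets(truth, n_sets=2, seed=seed)
            query = list(rng.choice(truth.index, size=40, replace=False))
            recs = run_ora(query, coll, min_set=2, max_set=2000)
            ps.append(next(r.p for r in recs if r.set_id.startswith("random_")))
        ps = np.array(ps)
        assert 0.3 < ps.mean() < 0.7
        assert (ps <= 0.01).mean() <= 0.1

    def test_zero_sets_rejected(self):
        _, truth = generate_dataset(SyntheticConfig(n_genes=10, seed=0))
        with pytest.raises(ValueError, match="n_sets"):
            generate_genesets(truth, n_sets=0, seed=0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_genesets(pd.DataFrame(), n_sets=1, seed=0)


def test_null_anova_calibration_moderate_n(small_dataset):
    """Type-I rate sanity on a purely null dataset (full-size check is in
    the acceptance suite)."""
    cfg = SyntheticConfig(n_genes=800, frac_patterned=0.0, noise_sd=0.2, seed=21)
    m, _ = generate_dataset(cfg)
    recs = fit_twoway_anova(log_transform(m, 0.0))
    for term in ("p_time", "p_drug", "p_interaction"):
        rate = np.mean([getattr(r, term) <= 0.01 for r in recs])
        assert rate < 0.05
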