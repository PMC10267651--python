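import filecmp

import numpy as np
import pytest
from scipy import stats

from connectomestats import SimulationConfig, generate_cohort, make_group_template
from connectomestats.simulate import _rng_for, sample_behavior, sample_subject


class TestConfig:
    def test_probability_ordering_enforced(self):
        with pytest.raises(ValueError, match="rich club"):
            SimulationConfig(p_rich=0.1, p_feeder=0.4, p_local=0.1)

    def test_hub_count_follows_fraction(self):
        cfg = SimulationConfig(n_nodes=50, hub_fraction=0.2, n_per_group=(3, 3))
        assert cfg.n_hubs == 10

    def test_disconnected_regime_rejected(self):
        cfg = SimulationConfig(
            n_nodes=200, p_rich=0.05, p_feeder=0.002, p_local=0.001, n_per_group=(3, 3)
        )
        with pytest.raises(ValueError, match="disconnected"):
            make_group_template(cfg)


class TestTemplate:
    def test_all_probabilities_one_gives_complete_graph(self):
        cfg = SimulationConfig(
            n_nodes=20, p_rich=1, p_feeder=1, p_local=1, rich_weight_multiplier=1,
            n_per_group=(3, 3),
        )
        template, _ = make_group_template(cfg)
        assert np.all(template.degree() == 19)

    def test_planted_hub_count(self):
        cfg = SimulationConfig(n_nodes=50, hub_fraction=0.2, n_per_group=(3, 3))
        _, truth = make_group_template(cfg)
        assert len(truth.planted_hub_ids) == 10

    def test_rich_weights_exceed_local(self):
        cfg = SimulationConfig(
            n_nodes=50, p_rich=0.9, p_feeder=0.4, p_local=0.1,
            rich_weight_multiplier=2.0, seed=5, n_per_group=(3, 3),
        )
        template, truth = make_group_template(cfg)
        hubs = np.isin(template.node_ids, sorted(truth.planted_hub_ids))
        w = template.weights
        rich = w[np.ix_(hubs, hubs)]
        local = w[np.ix_(~hubs, ~hubs)]
        assert rich[rich > 0].mean() / local[local > 0].mean() >= 1.5

    def test_block_degree_distribution_matches_bernoulli(self):
        """Chi-square goodness of fit for the three-block edge counts."""
        cfg = SimulationConfig(n_nodes=200, n_per_group=(3, 3), seed=0)
        counts = np.zeros(3)
        trials = np.zeros(3)
        h = cfg.n_hubs
        for rep in range(50):
            template, _ = make_group_template(cfg.replace(seed=rep))
            a = template.weights > 0
            iu = np.triu_indices(cfg.n_nodes, 1)
            hub = np.zeros(cfg.n_nodes, bool)
            hub[:h] = True
            kinds = hub[iu[0]].astype(int) + hub[iu[1]].astype(int)  # 0 local,1 feeder,2 rich
            for kind, p in zip(range(3), (cfg.p_local, cfg.p_feeder, cfg.p_rich)):
                sel = kinds == kind
                counts[kind] += a[iu][sel].sum()
                trials[kind] += sel.sum()
        expected = trials * np.array([cfg.p_local, cfg.p_feeder, cfg.p_rich])
        chi2 = np.sum((counts - expected) ** 2 / (expected * (1 - expected / trials)))
        # 3 binomial cells; generous bound on a chi2_3 variate
        assert chi2 < stats.chi2.isf(1e-4, 3)


class TestSampleSubject:
    def test_identity_settings_reproduce_template(self):
        cfg = SimulationConfig(
            n_nodes=30, subject_noise_sigma=0.0, edge_dropout=0.0,
            effect_attenuation=1.0, n_per_group=(3, 3),
        )
        template, _ = make_group_template(cfg)
        subj = sample_subject(template, cfg, "APD", np.random.default_rng(0))
        np.testing.assert_array_equal(subj.weights, template.weights)

    def test_attenuation_halves_effect_node_strength(self):
        cfg = SimulationConfig(
            n_nodes=30, subject_noise_sigma=0.0, edge_dropout=0.0,
            effect_attenuation=0.5, effect_node=10, n_per_group=(3, 3),
        )
        template, _ = make_group_template(cfg)
        pos = template.index_of(10)
        affected = sample_subject(template, cfg, "APD", np.random.default_rng(0))
        control = sample_subject(template, cfg, "HC", np.random.default_rng(0))
        assert affected.strength()[pos] == pytest.approx(0.5 * template.strength()[pos])
        np.testing.assert_array_equal(control.weights, template.weights)

    def test_dropout_rate_binomial(self):
        cfg = SimulationConfig(
            n_nodes=40, subject_noise_sigma=0.0, edge_dropout=0.1,
            effect_attenuation=1.0, n_per_group=(3, 3), seed=4,
        )
        template, _ = make_group_template(cfg)
        n_edges = (template.weights > 0).sum()
        rng = np.random.default_rng(123)
        dropped = [
            1.0 - (sample_subject(template, cfg, "HC", rng).weights > 0).sum() / n_edges
            for _ in range(300)
        ]
        assert np.mean(dropped) == pytest.approx(0.1, abs=0.02)

    def test_symmetry_preserved(self, small_cohort):
        cohort, _ = small_cohort
        for sid in cohort.subject_ids():
            w = cohort.connectomes[sid].weights
            np.testing.assert_array_equal(w, w.T)


class TestSampleBehavior:
    def _scores(self, rho, n, rng):
        cfg = SimulationConfig(behavior_target_r=rho, behavior_group="HC", n_per_group=(3, 3))
        apl = rng.normal(3.0, 0.4, 2 * n)
        groups = np.array(["APD"] * n + ["HC"] * n)
        scores = sample_behavior(apl, groups, cfg, rng)
        return np.corrcoef(scores[n:], apl[n:])[0, 1]

    def test_rho_one_gives_perfect_correlation(self):
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(behavior_target_r=0.999999, n_per_group=(3, 3))
        apl = rng.normal(3.0, 0.4, 20)
        groups = np.array(["APD"] * 10 + ["HC"] * 10)
        scores = sample_behavior(apl, groups, cfg, rng)
        assert abs(np.corrcoef(scores[10:], apl[10:])[0, 1]) > 0.999

    def test_null_rho_keeps_correlation_small(self):
        rng = np.random.default_rng(1)
        rs = [self._scores(0.0, 29, rng) for _ in range(200)]
        assert np.mean(np.abs(np.array(rs)) < 0.35) >= 0.93

    def test_target_rho_recovered_on_average(self):
        rng = np.random.default_rng(2)
        rs = [self._scores(0.62, 28, rng) for _ in range(300)]
        assert np.mean(rs) == pytest.approx(0.62, abs=0.05)


class TestGenerateCohort:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_nodes=20, n_per_group=(3, 3), seed=9)
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
        assert not cmp.diff_files
        sub = filecmp.dircmp(tmp_path / "a" / "matrices", tmp_path / "b" / "matrices")
        assert not sub.diff_files and len(sub.common_files) == 6

    def test_file_count_matches_cohort_size(self, tmp_path):
        cfg = SimulationConfig(n_nodes=20, n_per_group=(4, 5), seed=1)
        generate_cohort(cfg, out_dir=tmp_path)
        assert len(list((tmp_path / "matrices").glob("*.tsv"))) == 9

    def test_default_cohort_connected(self):
        cfg = SimulationConfig(seed=13, n_per_group=(5, 5))
        cohort, _ = generate_cohort(cfg)
        from scipy.sparse.csgraph import connected_components

        for sid in cohort.subject_ids():
            n_comp, _ = connected_components(cohort.connectomes[sid].weights > 0)
            assert n_comp == 1

    def test_effect_node_strength_ratio_equals_attenuation(self):
        cfg = SimulationConfig(
            n_nodes=40, n_per_group=(6, 6), subject_noise_sigma=0.0,
            edge_dropout=0.0, effect_attenuation=0.7, seed=2,
        )
        cohort, truth = generate_cohort(cfg)
        pos = truth.template.index_of(truth.effect_node)
        s_apd = cohort.weight_stack("APD").sum(axis=2)[:, pos].mean()
        s_hc = cohort.weight_stack("HC").sum(axis=2)[:, pos].mean()
        assert s_apd / s_hc == pytest.approx(0.7, rel=1e-12)

    def test_behavior_missing_counts(self):
        cfg = SimulationConfig(n_nodes=20, n_per_group=(5, 5), n_behavior_missing=(2, 1))
        cohort, _ = generate_cohort(cfg)
        m = cohort.manifest
        assert m[m["group"] == "APD"]["spatial_advantage"].isna().sum() == 2
        assert m[m["group"] == "HC"]["spatial_advantage"].isna().sum() == 1

    def test_age_confound_planted(self):
        cfg = SimulationConfig(n_nodes=20, n_per_group=(29, 29), seed=5)
        cohort, _ = generate_cohort(cfg)
        assert cohort.ages("HC").mean() > cohort.ages("APD").mean()

    def test_named_substreams_stable(self):
        cfg = SimulationConfig(seed=3, n_per_group=(3, 3))
        a = _rng_for(cfg, 10, 0).integers(0, 1000, 5)
        b = _rng_for(cfg, 10, 0).integers(0, 1000, 5)
        c = _rng_for(cfg, 10, 1).integers(0, 1000, 5)
        assert np.array_equal(a, b) and not np.array_equal(a, c)
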