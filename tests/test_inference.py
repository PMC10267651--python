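import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connectomestats import (
    SimulationConfig,
    chi_square_counts,
    cohort_nodal_metrics,
    demographics_table,
    generate_cohort,
    partial_correlation,
    perm_group_test,
)
from connectomestats.inference import (
    BehaviorCorrelationScan,
    NodalGroupTest,
    welch_t,
)

from oracles import partial_corr_formula


class TestPermGroupTest:
    def test_no_effect_gives_small_t_large_p(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 20)
        groups = np.array(["APD"] * 10 + ["HC"] * 10)
        ages = rng.uniform(8, 14, 20)
        t, p = perm_group_test(vals, groups, ages, n_perm=500, rng=rng)
        assert abs(t) < 2.5 and p > 0.01

    def test_exhaustive_matches_monte_carlo(self):
        """n=4+4: the full 70-partition null equals MC within binomial error."""
        rng = np.random.default_rng(1)
        vals = np.array([0.1, 0.5, 0.3, 0.9, 1.0, 1.4, 1.1, 0.8])
        groups = np.array(["APD"] * 4 + ["HC"] * 4)
        t_ex, p_ex = perm_group_test(vals, groups, None, exhaustive=True)
        t_mc, p_mc = perm_group_test(vals, groups, None, n_perm=10000, rng=rng)
        assert t_ex == t_mc
        se = np.sqrt(p_ex * (1 - p_ex) / 10000)
        assert abs(p_mc - p_ex) < 4 * se + 2e-4

    def test_null_p_uniform(self):
        """Null permutation p-values are uniform (KS not rejected at 0.01)."""
        rng = np.random.default_rng(2)
        groups = np.array(["APD"] * 8 + ["HC"] * 8)
        ages = rng.uniform(8, 14, 16)
        ps = []
        for _ in range(400):
            vals = rng.normal(0, 1, 16)
            _, p = perm_group_test(vals, groups, ages, n_perm=199, rng=rng)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_demeaning_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, 16)
        groups = np.array(["APD"] * 8 + ["HC"] * 8)
        ages = rng.uniform(8, 14, 16)
        t1, p1 = perm_group_test(vals, groups, ages, n_perm=300, rng=np.random.default_rng(7))
        t2, p2 = perm_group_test(vals, groups, ages + 100.0, n_perm=300, rng=np.random.default_rng(7))
        assert t1 == pytest.approx(t2, rel=1e-9) and p1 == p2

    def test_zero_variance_flagged(self):
        groups = np.array(["APD"] * 4 + ["HC"] * 4)
        t, p = perm_group_test(np.ones(8), groups, None, n_perm=100)
        assert (t, p) == (0.0, 1.0)

    def test_welch_direction_convention(self):
        vals = np.r_[np.full(5, 2.0) + np.r_[0, .1, -.1, .05, -.05], np.full(5, 1.0) + np.r_[0, .1, -.1, .05, -.05]]
        mask1 = np.array([True] * 5 + [False] * 5)
        assert welch_t(vals, mask1) > 0  # APD mean higher -> positive t


class TestPartialCorrelation:
    def test_constant_covariate_reduces_to_pearson(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = partial_correlation(x, y, np.full(30, 5.0))
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-9)

    def test_y_equal_to_covariate_degenerate_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        assert partial_correlation(x, z, z) == 0.0

    def test_textbook_formula_small_case(self):
        x = np.array([1.0, 2, 3, 5])
        y = np.array([2.0, 1, 4, 5])
        z = np.array([1.0, 2, 3, 4])
        assert partial_correlation(x, y, z) == pytest.approx(
            partial_corr_formula(x, y, z), rel=1e-9
        )

    def test_uncorrelated_covariate_converges_to_plain_r(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        assert partial_correlation(x, y, z) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.02)


@pytest.fixture(scope="module")
def effect_cohort():
    cfg = SimulationConfig(n_nodes=40, n_per_group=(12, 12), seed=31)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cohort_nodal_metrics(cohort)


class TestNodalScan:
    def test_bonferroni_factor(self, effect_cohort):
        cohort, truth, table = effect_cohort
        res = NodalGroupTest(cohort, table).fit(n_perm=200, rng=np.random.default_rng(0))
        assert res.bonferroni_factor == 40 * 4
        assert (res.table["p_bonf"] >= res.table["p_perm"] - 1e-12).all()

    def test_identical_groups_nothing_significant(self):
        cfg = SimulationConfig(
            n_nodes=30, n_per_group=(6, 6), seed=32, subject_noise_sigma=0.0,
            edge_dropout=0.0, effect_attenuation=1.0,
        )
        cohort, _ = generate_cohort(cfg)
        table = cohort_nodal_metrics(cohort)
        res = NodalGroupTest(cohort, table).fit(n_perm=100, rng=np.random.default_rng(0))
        assert res.table["p_bonf"].min() == 1.0

    def test_effect_node_tops_apl_ranking(self, effect_cohort):
        cohort, truth, table = effect_cohort
        res = NodalGroupTest(cohort, table).fit(n_perm=500, rng=np.random.default_rng(0))
        apl = res.table[res.table["metric"] == "apl"].sort_values("p_perm")
        top = apl.iloc[0]
        assert top["roi_id"] == truth.effect_node
        assert top["direction"] == "APD>HC"


class TestBehaviorScan:
    def test_planted_correlation_found(self):
        cfg = SimulationConfig(n_nodes=40, n_per_group=(20, 20), seed=33,
                               behavior_target_r=0.8)
        cohort, truth = generate_cohort(cfg)
        table = cohort_nodal_metrics(cohort)
        scan = BehaviorCorrelationScan(cohort, table)
        res = scan.fit(n_perm=500, rng=np.random.default_rng(0))
        top = res.top("HC", "spatial_advantage")
        assert top["roi_id"] == truth.reporter_node
        assert top["r"] > 0.5

    def test_all_missing_group_skipped(self):
        cfg = SimulationConfig(n_nodes=30, n_per_group=(6, 6), seed=34,
                               n_behavior_missing=(6, 0))
        cohort, _ = generate_cohort(cfg)
        table = cohort_nodal_metrics(cohort)
        res = BehaviorCorrelationScan(cohort, table).fit(n_perm=100, rng=np.random.default_rng(0))
        assert "APD" not in set(res.table["scope"])
        assert {"HC", "pooled"} <= set(res.table["scope"])


class TestDemographics:
    def test_balanced_gender_chi_square_zero(self):
        # the printed 14/15 vs 14/15 table
        chi2, p = chi_square_counts([[14, 15], [14, 15]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_any_balanced_table_is_zero(self):
        for n in (3, 10, 57):
            chi2, _ = chi_square_counts([[n, n + 1], [n, n + 1]])
            assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_handedness_style_counts_match_hand_computation(self):
        # (24,5) vs (27,2): Sum (O-E)^2/E with expected from the margins
        obs = np.array([[24, 5], [27, 2]], float)
        exp = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        by_hand = ((obs - exp) ** 2 / exp).sum()
        chi2, _ = chi_square_counts(obs)
        assert chi2 == pytest.approx(by_hand, rel=1e-12)

    def test_table_runs_on_synthetic_manifest(self, small_cohort):
        cohort, _ = small_cohort
        table = demographics_table(cohort.manifest)
        assert "age" in set(table["variable"])
        age_row = table[table["variable"] == "age"].iloc[0]
        assert age_row["apd_n"] == 8 and age_row["hc_n"] == 8
        assert 0 <= age_row["p_value"] <= 1

    def test_categorical_column(self):
        manifest = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(20)],
                "group": ["APD"] * 10 + ["HC"] * 10,
                "age": np.linspace(8, 14, 20),
                "gender": ["m", "f"] * 10,
            }
        )
        for c in ("total_advantage", "spatial_advantage", "talker_advantage", "high_cue", "low_cue"):
            manifest[c] = np.nan
        table = demographics_table(manifest, categorical=["gender"])
        row = table[table["variable"] == "gender"].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
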