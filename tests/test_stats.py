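import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gaitnirs import (
    ClinicalRecord,
    CohortSpec,
    channelwise_anova,
    channelwise_posthoc,
    generate_beta_cohort,
    load_brodmann_lookup,
    posthoc_paired_t,
    rm_anova,
    shapiro_wilk,
    significance_map,
    wilcoxon_exact,
)


def brute_force_signed_rank_p(diffs):
    """Independent oracle: direct iteration over every sign pattern."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    p_le = sum(w <= w_obs + 1e-12 for w in ws) / len(ws)
    p_ge = sum(w >= w_obs - 1e-12 for w in ws) / len(ws)
    return min(1.0, 2 * min(p_le, p_ge))


class TestRmAnova:
    def test_identical_sessions_give_zero_f(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova(x)
        assert res.F == 0.0

    def test_epsilon_bounds_for_three_sessions(self, rng):
        for _ in range(50):
            res = rm_anova(rng.normal(size=(6, 3)))
            assert 0.5 - 1e-12 <= res.epsilon <= 1.0 + 1e-12

    def test_matches_pingouin_on_random_table(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=(5, 3)) + rng.normal(size=(5, 1))
        mine = rm_anova(x)
        df = pd.DataFrame(
            {
                "s": np.repeat(range(5), 3),
                "t": list(range(3)) * 5,
                "y": x.ravel(),
            }
        )
        ref = pg.rm_anova(data=df, dv="y", within="t", subject="s", correction=True)
        assert mine.F == pytest.approx(ref["F"][0], abs=1e-8)
        assert mine.epsilon == pytest.approx(ref["eps"][0], abs=1e-8)
        assert mine.p_raw == pytest.approx(ref["p_GG_corr"][0], abs=1e-8)

    def test_incomplete_cases_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(x)

    def test_corrected_dfs_follow_epsilon(self, rng):
        x = rng.normal(size=(8, 3))
        res = rm_anova(x)
        assert res.df1 == pytest.approx(res.epsilon * 2)
        assert res.df2 == pytest.approx(res.epsilon * 2 * 7)


class TestPosthoc:
    def test_all_zero_differences(self):
        x = np.tile(np.arange(4.0)[:, None], (1, 2))
        res = posthoc_paired_t(x, ("T0", "T2"), family_size=1)
        assert res[0].t == 0.0 and res[0].p_adjusted == 1.0

    def test_bonferroni_multiplication_rule(self):
        # raw p 0.001 with family 40 -> adjusted 0.04
        assert min(1.0, 0.001 * 40) == pytest.approx(0.04)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 2))
        x[:, 1] += 5.0
        res = posthoc_paired_t(x, ("T0", "T2"), family_size=40)
        assert res[0].p_adjusted == pytest.approx(min(1.0, res[0].p_raw * 40))

    def test_matches_closed_form_t(self, rng):
        x = rng.normal(size=(8, 2))
        res = posthoc_paired_t(x, ("T0", "T2"), family_size=3)[0]
        d = x[:, 1] - x[:, 0]
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t == pytest.approx(t_oracle, abs=1e-10)

    def test_zero_variance_nonzero_mean_reported_undefined(self):
        x = np.zeros((5, 2))
        x[:, 1] = 1.0
        res = posthoc_paired_t(x, ("T0", "T2"), family_size=1)[0]
        assert res.undefined and res.t is None


class TestWilcoxon:
    def test_published_gmfm_comparison(self):
        # 8 participants, all improvements positive -> exact p = 2/256
        deltas = np.array([30.8, 27.0, 4.1, 48.3, 21.0, 51.9, 44.5, 31.4])
        res = wilcoxon_exact(np.zeros(8), deltas)
        assert res.p_exact == pytest.approx(2.0 / 256.0)
        assert round(res.p_exact, 3) == 0.008
        assert abs(res.z) == pytest.approx(2.521, abs=0.01)

    def test_symmetric_pair_gives_p_one(self):
        res = wilcoxon_exact(np.zeros(2), np.array([1.0, -1.0]))
        assert res.p_exact == 1.0

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_equals_brute_force_enumeration(self, n, rng):
        d = rng.normal(size=n)
        res = wilcoxon_exact(np.zeros(n), d)
        assert res.p_exact == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(10):
            d = rng.normal(size=9)
            res = wilcoxon_exact(np.zeros(9), d)
            ref = sps.wilcoxon(d, method="exact").pvalue
            assert res.p_exact == pytest.approx(ref, abs=1e-12)

    def test_all_zero_differences_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_exact(np.ones(5), np.ones(5))
        assert res.p == 1.0


class TestShapiro:
    def test_statistic_in_unit_interval(self, rng):
        w, _ = shapiro_wilk(rng.normal(size=8))
        assert 0 < w <= 1

    def test_null_p_roughly_uniform(self):
        ps = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            ps.append(shapiro_wilk(r.normal(size=8))[1])
        ks = sps.kstest(ps, "uniform").pvalue
        assert ks > 0.01

    def test_detects_heavy_skew(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            hits += shapiro_wilk(r.exponential(size=50))[1] < 0.05
        assert hits >= 45

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk(np.ones(10))


class TestSignificanceMap:
    def test_empty_inputs_give_empty_report(self):
        rep = significance_map([], [], load_brodmann_lookup())
        assert rep.anova.empty and rep.posthoc.empty

    def test_threshold_rule(self):
        from gaitnirs import AnovaResult

        res = AnovaResult(
            channel=12, chromophore="hbo", F=8.0, df1=1.6, df2=6.6,
            epsilon=0.8, p_raw=0.001, p_adjusted=0.04,
        )
        rep = significance_map([res], [], load_brodmann_lookup())
        row = rep.anova.iloc[0]
        assert bool(row.corrected_significant)
        assert row.brodmann == "46-Dorsolateral prefrontal cortex"

    def test_unknown_channel_rejected(self):
        from gaitnirs import AnovaResult

        res = AnovaResult(
            channel=99, chromophore="hbo", F=1.0, df1=2, df2=10,
            epsilon=1.0, p_raw=0.5, p_adjusted=1.0,
        )
        with pytest.raises(ValueError, match="99"):
            significance_map([res], [], load_brodmann_lookup())

    def test_planted_session_effect_recovered_specifically(self):
        # strong effect on 5 channels: they (and almost only they) survive
        planted = (3, 9, 17, 25, 31)
        tp = fp = 0
        seeds = 10
        for seed in range(seeds):
            spec = CohortSpec(
                n_subjects=10, seed=seed, informative_channels=planted,
                beta_step=0.4, beta_step_sd=0.05,
            )
            df, _ = generate_beta_cohort(spec, beta_noise_sd=0.05, subject_sd=0.1)
            res = channelwise_anova(df)
            hbo_sig = {
                r.channel for r in res if r.chromophore == "hbo" and r.p_adjusted < 0.05
            }
            tp += len(hbo_sig & set(planted))
            fp += len(hbo_sig - set(planted))
        assert tp >= 0.9 * seeds * len(planted)
        specificity = 1 - fp / (seeds * (34 - len(planted)))
        assert specificity >= 0.9


def test_clinical_record_validation():
    with pytest.raises(ValueError, match="GMFM"):
        ClinicalRecord(subject="S1", gmfcs=3, gmfm88={"T0": 120.0})
    with pytest.raises(ValueError, match="MAS"):
        ClinicalRecord(
            subject="S1", gmfcs=3, gmfm88={"T0": 50.0},
            mas={"hip": {"T0": 2.7}},
        )
    rec = ClinicalRecord(
        subject="S1", gmfcs=4, gmfm88={"T0": 16.0, "T2": 24.3},
        mas={"hip": {"T0": 1.5}},
    )
    assert rec.mas["hip"]["T0"] == 1.5
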