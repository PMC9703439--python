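"""Mixed ANOVA, aligned rank transform, sphericity, and participant tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from newstrf.io_core import CONDITIONS
from newstrf.group_stats import (
    aligned_rank_transform,
    chi2_independence,
    gg_epsilon,
    independent_t,
    mauchly_test,
    mixed_anova,
    posthoc_contrasts,
)
from newstrf.synthetic import EffectPlan, generate_ratings


def make_table(Y_by_group):
    """Long factorial table from {group: array (subjects x 3)}."""
    rows = []
    sid = 0
    for group, Y in Y_by_group.items():
        for subj_vals in np.atleast_2d(Y):
            sid += 1
            for cond, v in zip(CONDITIONS, subj_vals):
                rows.append({"subject": f"S{sid:03d}", "group": group,
                             "news": cond, "value": float(v)})
    return pd.DataFrame(rows)


def balanced_anova_oracle(Y1, Y2):
    """Textbook balanced two-way mixed ANOVA sums of squares, written out
    independently of the implementation."""
    Y = np.concatenate([Y1, Y2])          # (2n x k)
    n, k = Y1.shape[0], Y.shape[1]
    gmean = Y.mean()
    groups = [Y1, Y2]
    ss_a = sum(n * k * (Yg.mean() - gmean) ** 2 for Yg in groups)
    ss_b = sum(2 * n * (Y[:, j].mean() - gmean) ** 2 for j in range(k))
    ss_ab = 0.0
    for Yg in groups:
        for j in range(k):
            ss_ab += n * (Yg[:, j].mean() - Yg.mean() - Y[:, j].mean() + gmean) ** 2
    ss_subj = sum(k * ((Yg.mean(axis=1) - Yg.mean()) ** 2).sum() for Yg in groups)
    ss_total = ((Y - gmean) ** 2).sum()
    ss_err_w = ss_total - ss_a - ss_b - ss_ab - ss_subj
    F_a = (ss_a / 1) / (ss_subj / (2 * n - 2))
    F_b = (ss_b / (k - 1)) / (ss_err_w / ((2 * n - 2) * (k - 1)))
    F_ab = (ss_ab / (k - 1)) / (ss_err_w / ((2 * n - 2) * (k - 1)))
    return F_a, F_b, F_ab


class TestMixedAnova:
    def test_matches_hand_sums_of_squares_balanced(self):
        rng = np.random.default_rng(0)
        Y1 = rng.normal(0, 1, size=(3, 3)) + [0.0, 1.0, 2.0]
        Y2 = rng.normal(0.5, 1, size=(3, 3))
        res = {r.effect: r for r in mixed_anova(make_table({"depressed": Y1,
                                                            "non-depressed": Y2}))}
        F_a, F_b, F_ab = balanced_anova_oracle(Y1, Y2)
        assert res["Group"].F == pytest.approx(F_a, abs=1e-8)
        assert res["News"].F == pytest.approx(F_b, abs=1e-8)
        assert res["Group x News"].F == pytest.approx(F_ab, abs=1e-8)
        assert res["Group"].df2 == 4 and res["News"].df2 == 8

    def test_matches_pingouin_on_balanced_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        table = make_table({"depressed": rng.normal(size=(8, 3)),
                            "non-depressed": rng.normal(size=(8, 3))})
        res = {r.effect: r for r in mixed_anova(table)}
        out = pg.mixed_anova(data=table, dv="value", within="news",
                             subject="subject", between="group")
        pg_f = dict(zip(out["Source"], out["F"]))
        assert res["Group"].F == pytest.approx(pg_f["group"], rel=1e-6)
        assert res["News"].F == pytest.approx(pg_f["news"], rel=1e-6)
        assert res["Group x News"].F == pytest.approx(pg_f["Interaction"], rel=1e-6)

    def test_partial_eta_squared_definition(self):
        rng = np.random.default_rng(2)
        table = make_table({"depressed": rng.normal(size=(5, 3)),
                            "non-depressed": rng.normal(size=(5, 3))})
        for r in mixed_anova(table):
            assert 0.0 <= r.partial_eta_sq < 1.0

    def test_null_group_p_uniform_under_permutation(self):
        # permuted group labels => Group p-values ~ Uniform(0,1)
        rng = np.random.default_rng(3)
        n, k = 12, 3
        base = rng.normal(size=(2 * n, k))
        pvals = []
        for _ in range(1000):
            perm = rng.permutation(2 * n)
            table = make_table({"depressed": base[perm[:n]],
                                "non-depressed": base[perm[n:]]})
            res = {r.effect: r for r in mixed_anova(table)}
            pvals.append(res["Group"].p)
        ks = sstats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_zero_variance_reports_f_zero(self):
        Y = np.ones((3, 3))
        with pytest.warns(UserWarning, match="zero error variance"):
            res = mixed_anova(make_table({"depressed": Y, "non-depressed": Y}))
        assert all(r.F == 0.0 for r in res)

    def test_subject_with_missing_level_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        table = make_table({"depressed": rng.normal(size=(4, 3)),
                            "non-depressed": rng.normal(size=(4, 3))})
        table = table.drop(index=table.index[0])
        with pytest.warns(UserWarning, match="missing levels"):
            res = mixed_anova(table)
        assert {r.effect for r in res} == {"Group", "News", "Group x News"}


class TestSphericity:
    def test_spherical_covariance_epsilon_one(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(200, 3))  # iid columns => spherical
        table = make_table({"depressed": Y[:100], "non-depressed": Y[100:]})
        assert gg_epsilon(table) > 0.95
        _, p = mauchly_test(table)
        assert p > 0.05

    def test_epsilon_lower_bound_half_for_three_levels(self):
        rng = np.random.default_rng(1)
        for seed in range(20):
            r2 = np.random.default_rng(seed)
            A = r2.normal(size=(3, 3))
            Y = r2.normal(size=(12, 3)) @ A  # arbitrary covariance
            table = make_table({"depressed": Y[:6], "non-depressed": Y[6:]})
            eps = gg_epsilon(table)
            assert 0.5 - 1e-9 <= eps <= 1.0

    def test_matches_pingouin_epsilon(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(20, 3)) @ np.array([[1, 0.8, 0], [0, 1, 0], [0, 0, 2.0]])
        table = make_table({"depressed": Y[:10], "non-depressed": Y[10:]})
        # pooled (within-group) covariance vs pingouin's pooled mixed-design path
        wide = table.pivot(index="subject", columns="news", values="value")
        eps_pg = float(pg.epsilon(wide - wide.groupby(
            table.groupby("subject")["group"].first()).transform("mean"),
            correction="gg"))
        assert gg_epsilon(table) == pytest.approx(eps_pg, abs=0.02)


class TestAlignedRankTransform:
    def test_constant_data_all_midranks_equal(self):
        Y = np.full((4, 3), 2.0)
        table = make_table({"depressed": Y, "non-depressed": Y})
        art = aligned_rank_transform(table)
        for effect, t in art.items():
            assert t["value"].nunique() == 1

    def test_news_ranks_preserve_news_ordering_without_other_effects(self):
        # zero group and interaction effects: ART-for-News ranks order by news
        Y = np.tile([1.0, 2.0, 3.0], (6, 1))
        table = make_table({"depressed": Y[:3], "non-depressed": Y[3:]})
        art = aligned_rank_transform(table)["News"]
        means = art.groupby("news")["value"].mean()
        assert means["negative"] < means["neutral"] < means["positive"]

    def test_alignment_strips_other_effects(self):
        # pure additive group+news data: after ART for News, Group and
        # interaction F collapse to zero
        g_off = {"depressed": 5.0, "non-depressed": 0.0}
        rows = {g: np.tile([1.0, 2.0, 3.0], (4, 1)) + off
                for g, off in g_off.items()}
        table = make_table(rows)
        art = aligned_rank_transform(table)["News"]
        with pytest.warns(UserWarning, match="zero error variance"):
            res = {r.effect: r for r in mixed_anova(art)}
        assert res["Group"].F == pytest.approx(0.0, abs=1e-10)

    def test_interaction_f_calibrated_with_only_news_effect(self):
        # a pure News main effect must not inflate the ART interaction test
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            Y = rng.normal(size=(16, 3)) + [0.0, 1.0, 2.0]
            table = make_table({"depressed": Y[:8], "non-depressed": Y[8:]})
            art = aligned_rank_transform(table)["Group x News"]
            res = {r.effect: r for r in mixed_anova(art)}
            pvals.append(res["Group x News"].p)
        assert np.mean(np.array(pvals) < 0.05) < 0.12
        assert sstats.kstest(pvals, "uniform").pvalue > 0.001


class TestPosthoc:
    def _anova_stub(self, p_news=1.0, p_group=1.0, p_int=1.0):
        from newstrf.group_stats import ANOVAResult
        return [ANOVAResult("Group", 1, 1, 10, p_group, 0.1),
                ANOVAResult("News", 1, 2, 20, p_news, 0.1),
                ANOVAResult("Group x News", 1, 2, 20, p_int, 0.1)]

    def test_identical_paired_samples_t_zero_p_one(self):
        Y = np.tile([1.0, 1.0, 1.0], (5, 1)) + np.arange(5)[:, None]
        table = make_table({"depressed": Y, "non-depressed": Y})
        res = posthoc_contrasts(table, self._anova_stub(p_news=0.01))
        paired = [r for r in res if r.kind == "paired"]
        assert len(paired) == 3
        assert all(r.t == 0.0 and r.p_bonferroni == 1.0 for r in paired)

    def test_bonferroni_multiplies_by_family_size(self):
        rng = np.random.default_rng(0)
        Y1 = rng.normal(size=(10, 3)) + [0.0, 0.4, 0.8]
        Y2 = rng.normal(size=(10, 3))
        table = make_table({"depressed": Y1, "non-depressed": Y2})
        res = posthoc_contrasts(table, self._anova_stub(p_news=0.01))
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 3))

    def test_paired_t_matches_closed_form(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(8, 3))
        table = make_table({"depressed": Y[:4], "non-depressed": Y[4:]})
        res = posthoc_contrasts(table, self._anova_stub(p_news=0.001))
        r = [x for x in res if "negative vs neutral" in x.contrast][0]
        d = Y[:, 0] - Y[:, 1]
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert r.t == pytest.approx(t_expected, rel=1e-10)

    def test_interaction_triggers_per_group_and_between_group_tests(self):
        rng = np.random.default_rng(2)
        table = make_table({"depressed": rng.normal(size=(5, 3)),
                            "non-depressed": rng.normal(size=(5, 3))})
        res = posthoc_contrasts(table, self._anova_stub(p_int=0.01))
        kinds = [(r.kind, r.contrast) for r in res]
        assert sum(1 for k, _ in kinds if k == "paired") == 6   # 3 pairs x 2 groups
        assert sum(1 for k, _ in kinds if k == "unpaired") == 3  # per condition


class TestParticipantTests:
    def test_identical_column_proportions_chi2_zero(self):
        chi2, df, p, v = chi2_independence([[10, 20], [5, 10], [15, 30]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_2x2_hand_computation(self):
        obs = np.array([[10, 20], [20, 10]])
        chi2, df, p, v = chi2_independence(obs)
        # direct (O-E)^2/E with margin-derived expectations
        E = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert chi2 == pytest.approx((((obs - E) ** 2) / E).sum())
        assert df == 1

    def test_identical_samples_t_and_d_zero(self):
        x = np.arange(10.0)
        t, df, p, d = independent_t(x, x)
        assert t == 0.0 and d == 0.0 and df == 18

    def test_t_matches_closed_form(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(1.0, 2.0, size=15)
        t, df, p, d = independent_t(x, y)
        sp = np.sqrt(((11 * x.var(ddof=1)) + (14 * y.var(ddof=1))) / 25)
        t_expected = (x.mean() - y.mean()) / (sp * np.sqrt(1 / 12 + 1 / 15))
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert d == pytest.approx((x.mean() - y.mean()) / sp, rel=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=9), rng.normal(size=9)
        _, _, _, d0 = independent_t(x, y)
        t1, _, _, _ = independent_t(x + 3.0, y)
        assert t1 != 0.0
        sp = np.sqrt((x.var(ddof=1) * 8 + y.var(ddof=1) * 8) / 16)
        assert (x + 3.0).mean() - y.mean() == pytest.approx(x.mean() - y.mean() + 3.0)


class TestPowerDirection:
    def test_group_news_interaction_detected_at_default_effects(self):
        """At the generator's default effect sizes, measure-level N1 latency
        tables at study size detect the Group x News interaction in most
        replicates (latencies drawn at the measure level: configured
        population means + subject jitter + measurement noise)."""
        from newstrf.synthetic import EffectPlan, kernel_population_params, SUBJECT_LATENCY_SD_MS
        rng = np.random.default_rng(7)
        plan = EffectPlan()
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            rows = {}
            for group, n in (("depressed", 32), ("non-depressed", 103)):
                mus = [kernel_population_params(group, c, "N1", plan, 1.0)["peak_latency_ms"]
                       for c in CONDITIONS]
                jit = rng.normal(0, SUBJECT_LATENCY_SD_MS, size=(n, 1))
                noise = rng.normal(0, 10.0, size=(n, 3))  # DTW measurement noise
                rows[group] = np.asarray(mus)[None, :] + jit + noise
            res = {r.effect: r for r in mixed_anova(make_table(rows))}
            if res["Group x News"].p < 0.05:
                hits += 1
        assert hits > 0.5 * n_sims
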