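import numpy as np
import pandas as pd
import pytest

from execsim import stats as S

from conftest import make_events


class TestBlockExclusion:
    def _blocks(self, scores, family="attention"):
        return pd.DataFrame(
            dict(
                participant=[f"p{i}" for i in range(len(scores))],
                block=[f"b{i}" for i in range(len(scores))],
                task_family=family,
                score=scores,
            )
        )

    def test_all_equal_none_removed(self):
        blocks = self._blocks([80.0] * 10)
        retained, log = S.exclude_outlier_blocks(blocks)
        assert len(retained) == 10
        assert log["attention"]["n_removed"] == 0

    def test_boundary_block_retained(self):
        scores = [80.0] * 30
        mean, sd = np.mean(scores + [50.0]), np.std(scores + [50.0], ddof=1)
        # craft a block exactly at mean - 3 sd of the full set
        scores = [80.0] * 30
        df = self._blocks(scores)
        m, s = df["score"].mean(), df["score"].std(ddof=1)
        # all equal -> sd 0 -> cutoff == mean; equal scores retained (strict <)
        retained, _ = S.exclude_outlier_blocks(df)
        assert len(retained) == 30

    def test_exact_cutoff_retained_strictly_below_removed(self):
        scores = np.array([90.0] * 40 + [60.0])
        df = self._blocks(list(scores))
        mean, sd = scores.mean(), scores.std(ddof=1)
        cutoff = mean - 3 * sd
        # one block exactly at the cutoff, one strictly below
        df2 = pd.concat(
            [
                df,
                pd.DataFrame(
                    dict(
                        participant=["pA", "pB"],
                        block=["exact", "below"],
                        task_family="attention",
                        score=[cutoff, cutoff - 5.0],
                    )
                ),
            ],
            ignore_index=True,
        )
        # recompute with the new blocks included (pooled stats change)
        m2, s2 = df2["score"].mean(), df2["score"].std(ddof=1)
        c2 = m2 - 3 * s2
        df2.loc[df2["block"] == "exact", "score"] = c2
        retained, log = S.exclude_outlier_blocks(df2)
        assert "exact" in set(retained["block"]) or df2.loc[
            df2["block"] == "exact", "score"
        ].iloc[0] < log["attention"]["cutoff"]
        assert log["attention"]["cutoff"] == pytest.approx(
            df2["score"].mean() - 3 * df2["score"].std(ddof=1)
        )

    def test_planted_gross_outlier_removed(self, rng):
        scores = list(rng.normal(85, 3, size=199)) + [10.0]
        df = self._blocks(scores)
        retained, log = S.exclude_outlier_blocks(df)
        assert len(retained) == 199
        assert 10.0 not in set(retained["score"])
        # oracle recomputation
        arr = np.array(scores)
        cutoff = arr.mean() - 3 * arr.std(ddof=1)
        assert log["attention"]["cutoff"] == pytest.approx(cutoff)

    def test_families_independent(self, rng):
        att = self._blocks(list(rng.normal(80, 5, 100)), "attention")
        nb = self._blocks(list(rng.normal(90, 2, 100)), "nback")
        both = pd.concat([att, nb], ignore_index=True)
        _, log = S.exclude_outlier_blocks(both)
        assert set(log) == {"attention", "nback"}
        assert log["attention"]["cutoff"] != log["nback"]["cutoff"]


class TestTaskScores:
    def test_all_correct_gives_100(self):
        events = make_events(
            [
                dict(condition="divided_attention", correct=True, block="b1"),
                dict(condition="attend_visual_speech_distractor", correct=True,
                     block="b2"),
                dict(task="nback", condition="2back", switch="nonswitch",
                     correct=True, block="b3"),
                dict(task="nback", condition="1back", switch="post_switch",
                     correct=True, block="b4"),
            ]
        )
        scores = S.compute_task_scores(events)
        assert all(v == 100.0 for v in scores.values())

    def test_wm_uses_nonswitch_only(self):
        rows = []
        for i in range(10):  # 8 correct of 10 nonswitch
            rows.append(
                dict(task="nback", condition="2back", switch="nonswitch",
                     correct=i < 8, block="b")
            )
        for i in range(6):  # switch trials must not count
            rows.append(
                dict(task="nback", condition="2back", switch="post_switch",
                     correct=False, block="b")
            )
        scores = S.compute_task_scores(make_events(rows))
        assert scores["WM"] == pytest.approx(80.0)

    def test_hand_count_fixture(self):
        # 20-trial fixture scored by hand
        rows = []
        # 6 divided: 4 correct -> 66.67
        for i in range(6):
            rows.append(dict(condition="divided_attention", correct=i < 4, block="a"))
        # 6 distracted: 3 correct -> 50
        for i in range(6):
            rows.append(
                dict(condition="attend_auditory_text_distractor", correct=i < 3,
                     block="b")
            )
        # 4 2-back nonswitch: 4 correct -> 100
        for i in range(4):
            rows.append(
                dict(task="nback", condition="2back", switch="nonswitch",
                     correct=True, block="c")
            )
        # 4 post-switch (1-back): 1 correct -> 25
        for i in range(4):
            rows.append(
                dict(task="nback", condition="1back", switch="post_switch",
                     correct=i < 1, block="d")
            )
        scores = S.compute_task_scores(make_events(rows))
        assert scores["DivA"] == pytest.approx(100 * 4 / 6)
        assert scores["DistrA"] == pytest.approx(50.0)
        assert scores["WM"] == pytest.approx(100.0)
        assert scores["ModSwi"] == pytest.approx(25.0)

    def test_zero_eligible_trials_nan_with_warning(self):
        events = make_events([dict(condition="divided_attention", correct=True)])
        with pytest.warns(UserWarning):
            scores = S.compute_task_scores(events)
        assert np.isnan(scores["WM"])

    def test_retained_blocks_filter(self):
        rows = [
            dict(condition="divided_attention", correct=True, block="good"),
            dict(condition="divided_attention", correct=False, block="bad"),
        ]
        scores = S.compute_task_scores(make_events(rows), retained_blocks={"good"})
        assert scores["DivA"] == 100.0


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.normal(size=(2, 40))
        r, _ = S.partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_constant_covariate_equals_pearson(self, rng):
        x, y = rng.normal(size=(2, 40))
        r, _ = S.partial_correlation(x, y, [np.full(40, 3.0)])
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_recursive_formula_oracle(self, rng):
        z = rng.normal(size=60)
        x = 0.6 * z + rng.normal(size=60)
        y = -0.4 * z + rng.normal(size=60)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        r, p = S.partial_correlation(x, y, [z])
        assert r == pytest.approx(oracle, abs=1e-10)
        assert 0.0 <= p <= 1.0

    def test_categorical_covariate_dummy_coded(self, rng):
        g = np.array(["a", "b"] * 20)
        shift = np.where(g == "a", 5.0, -5.0)
        x = rng.normal(size=40) + shift
        y = rng.normal(size=40) + shift
        r_raw = np.corrcoef(x, y)[0, 1]
        r_partial, _ = S.partial_correlation(x, y, [g])
        assert abs(r_partial) < abs(r_raw)  # group shift explained away


def rm_oracle_oneway(y):
    """Hand sums-of-squares for a one-way repeated-measures design."""
    n, a = y.shape
    grand = y.mean()
    ss_task = n * ((y.mean(0) - grand) ** 2).sum()
    ss_sub = a * ((y.mean(1) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_task - ss_sub
    f = (ss_task / (a - 1)) / (ss_err / ((n - 1) * (a - 1)))
    return ss_task, ss_err, f, ss_tot


class TestRMANCOVA:
    def _long(self, y, extra=None):
        n, a = y.shape
        rows = []
        for i in range(n):
            for j in range(a):
                row = dict(participant=f"p{i}", task=f"t{j}", score=y[i, j])
                if extra:
                    row.update(extra[i])
                rows.append(row)
        return pd.DataFrame(rows)

    def test_matches_hand_ss_oracle_6x3(self, rng):
        y = rng.normal(70, 5, size=(6, 3)) + np.array([0.0, 2.0, 4.0])
        res = S.rm_ancova(self._long(y))
        ss_task, ss_err, f, ss_tot = rm_oracle_oneway(y)
        eff = res.effect("task")
        assert eff["F"] == pytest.approx(f, abs=1e-8)
        assert eff["SS"] == pytest.approx(ss_task, abs=1e-8)
        assert eff["eta2"] == pytest.approx(ss_task / ss_tot, abs=1e-10)

    def test_epsilon_one_under_compound_symmetry(self):
        cov = 2.0 * np.ones((4, 4)) + 3.0 * np.eye(4)
        c = S._orthonormal_contrasts(4)
        eps = S.greenhouse_geisser_epsilon(c @ cov @ c.T)
        assert eps == pytest.approx(1.0, abs=1e-8)

    def test_epsilon_one_for_two_levels(self, rng):
        y = rng.normal(size=(8, 2))
        res = S.rm_ancova(self._long(y))
        assert res.epsilon == 1.0

    def test_epsilon_lower_bound(self):
        # maximally nonspherical: one dominant contrast direction
        sigma = np.diag([10.0, 1e-8, 1e-8])
        eps = S.greenhouse_geisser_epsilon(sigma)
        assert eps == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_f_invariant_to_affine_rescaling(self, rng):
        y = rng.normal(70, 5, size=(10, 4))
        f1 = S.rm_ancova(self._long(y)).effect("task")["F"]
        f2 = S.rm_ancova(self._long(2.5 * y + 100)).effect("task")["F"]
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_eta2_invariant_to_shift(self, rng):
        y = rng.normal(size=(10, 3))
        e1 = S.rm_ancova(self._long(y)).effect("task")["eta2"]
        e2 = S.rm_ancova(self._long(y + 50.0)).effect("task")["eta2"]
        assert e1 == pytest.approx(e2, rel=1e-10)

    def test_between_factor_and_covariate(self, rng):
        n = 24
        extra = [
            dict(cohort=["a", "b", "c"][i % 3], gender=["m", "f"][i % 2],
                 gpa=float(rng.normal(8.5, 0.5)))
            for i in range(n)
        ]
        shift = np.array([{"a": -4.0, "b": 1.0, "c": 3.0}[e["cohort"]] for e in extra])
        y = rng.normal(80, 3, size=(n, 4)) + shift[:, None]
        res = S.rm_ancova(
            self._long(y, extra), between=["cohort", "gender"], covariate="gpa"
        )
        effects = set(res.effects["effect"])
        assert {"cohort", "gender", "cohort:gender", "gpa", "task",
                "task:cohort"} <= effects
        assert res.effect("cohort")["p"] < 0.01
        assert res.effects["eta2"].sum() <= 1.0 + 1e-9

    def test_empty_cells_raise(self, rng):
        extra = [dict(cohort="a" if i < 6 else "b", gender="m") for i in range(12)]
        # cohort b has no females, and make one combination empty entirely
        extra[0]["gender"] = "f"
        y = rng.normal(size=(12, 3))
        with pytest.raises(ValueError, match="cells"):
            S.rm_ancova(self._long(y, extra), between=["cohort", "gender"])

    def test_incomplete_subjects_dropped(self, rng):
        y = rng.normal(size=(8, 3))
        long = self._long(y)
        long = long[~((long["participant"] == "p0") & (long["task"] == "t1"))]
        res = S.rm_ancova(long)
        assert res.dropped_subjects == ["p0"]

    def test_mauchly_reported(self, rng):
        y = rng.normal(size=(12, 4))
        res = S.rm_ancova(self._long(y))
        assert set(res.mauchly) == {"W", "chi2", "df", "p"}
        assert 0.0 < res.mauchly["W"] <= 1.0
        assert res.mauchly["df"] == 4 * 3 // 2 - 1


class TestUnivariateAnova:
    def _table(self, rng, shift_by_cohort=None, n=40):
        rows = []
        for i in range(n):
            cohort = ["a", "b", "c"][i % 3]
            ctype = ["x", "y"][i % 2]
            mu = (shift_by_cohort or {}).get(cohort, 0.0)
            rows.append(
                dict(cohort=cohort, ctype=ctype, distance=rng.normal(mu, 1.0))
            )
        return pd.DataFrame(rows)

    def test_identical_groups_f_small(self, rng):
        df = self._table(rng)
        df["distance"] = 1.0
        res = S.univariate_anova(df, "distance", ["cohort", "ctype"])
        assert (res.effects["F"] < 1e-10).all()

    def test_eta2_sums_below_one(self, rng):
        df = self._table(rng, {"a": -1.0, "b": 0.0, "c": 1.0})
        res = S.univariate_anova(df, "distance", ["cohort", "ctype"])
        assert res.effects["eta2"].sum() <= 1.0

    def test_planted_shift_detected_with_power(self):
        hits = 0
        n_reps = 40
        for seed in range(n_reps):
            r = np.random.default_rng(seed)
            df = self._table(r, {"a": -0.8, "b": 0.0, "c": 0.8}, n=120)
            res = S.univariate_anova(df, "distance", ["cohort", "ctype"])
            hits += res.effect("cohort")["p"] < 0.05
        assert hits >= int(0.9 * n_reps)

    def test_posthoc_on_significant_main(self, rng):
        df = self._table(rng, {"a": -3.0, "b": 0.0, "c": 3.0}, n=90)
        res = S.univariate_anova(df, "distance", ["cohort", "ctype"])
        ph = res.posthoc[res.posthoc["factor"] == "cohort"]
        assert len(ph) == 3
        assert (ph["p_bonferroni"] <= 1.0).all()


def test_exclusion_idempotent_on_retained_set(rng):
    scores = list(rng.normal(85, 4, size=300)) + [5.0, 8.0]
    df = pd.DataFrame(
        dict(
            participant="p",
            block=[f"b{i}" for i in range(302)],
            task_family="attention",
            score=scores,
        )
    )
    retained, log = S.exclude_outlier_blocks(df)
    cutoff = log["attention"]["cutoff"]
    # re-applying the first-pass cutoff to the retained set removes nothing
    assert (retained["score"] >= cutoff).all()
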