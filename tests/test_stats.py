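"""Exclusion, stay probabilities, mixed ANOVA, and follow-up models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from twostep.agents import AgentSpec, simulate_session
from twostep.stats import (
    STAY_CELLS,
    STAY_COLUMNS,
    cohort_stay_table,
    compare_conditions,
    delta_ancova,
    delta_regression,
    exclude_perseverators,
    performance_summary,
    stay_anova,
    stay_probabilities,
)
from twostep.task import trials_to_frame

from conftest import make_trial_frame


def _mixed_frame(choices_by_subject, condition_by_subject):
    frames = []
    for sid, choices in choices_by_subject.items():
        n = len(choices)
        frames.append(
            make_trial_frame(
                choices,
                ["common"] * n,
                [0] * n,
                subject_id=sid,
                condition=condition_by_subject.get(sid, "control"),
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestExclusion:
    def test_perseverator_excluded(self, config):
        recs = simulate_session(
            AgentSpec(kind="perseverator"), config, seed=1, subject_id="p1"
        )
        retained, excluded = exclude_perseverators(trials_to_frame(recs))
        assert excluded == ["p1"]
        assert retained.empty

    def test_random_agent_retained(self, config):
        recs = simulate_session(
            AgentSpec(kind="random"), config, seed=1, subject_id="r1"
        )
        retained, excluded = exclude_perseverators(trials_to_frame(recs))
        assert excluded == []
        assert len(retained) == 240

    def test_boundary_is_strict(self):
        # 228/240 = 0.95 exactly -> retained; 229/240 -> excluded
        at = _mixed_frame({"b1": ["a1"] * 228 + ["a2"] * 12}, {})
        above = _mixed_frame({"b2": ["a1"] * 229 + ["a2"] * 11}, {})
        assert exclude_perseverators(at)[1] == []
        assert exclude_perseverators(above)[1] == ["b2"]


class TestStayProbabilities:
    def test_perseverator_stays_in_every_cell(self, config):
        recs = simulate_session(AgentSpec(kind="perseverator"), config, seed=4)
        table = stay_probabilities(trials_to_frame(recs))
        for cell, p in table.probs.items():
            if table.counts[cell]:
                assert p == 1.0

    def test_hand_enumerated_six_trials(self):
        # prev-trial cells:      t1->RC    t2->RR    t3->UC    t4->RC    t5->UR
        # stay (vs prev choice):  stay      shift     shift     stay      stay
        df = make_trial_frame(
            ["a1", "a1", "a2", "a1", "a1", "a1"],
            ["common", "rare", "common", "common", "rare", "common"],
            [100, 100, 0, 100, 0, 100],
        )
        t = stay_probabilities(df)
        assert t.probs[("rewarded", "common")] == 1.0  # 2 stays of 2
        assert t.counts[("rewarded", "common")] == 2
        assert t.probs[("rewarded", "rare")] == 0.0  # 1 shift of 1
        assert t.probs[("unrewarded", "common")] == 0.0
        assert t.probs[("unrewarded", "rare")] == 1.0
        assert sum(t.counts.values()) == len(df) - 1

    def test_strict_win_stay_lose_shift(self):
        rng = np.random.default_rng(0)
        outcomes = rng.choice([0, 100], size=100).tolist()
        transitions = rng.choice(["common", "rare"], size=100).tolist()
        choices = ["a1"]
        for prev_out, prev_choice in zip(outcomes, choices):
            if prev_out > 0:
                choices.append(prev_choice)
            else:
                choices.append("a2" if prev_choice == "a1" else "a1")
        df = make_trial_frame(choices[:100], transitions, outcomes)
        t = stay_probabilities(df)
        for (o, tr), p in t.probs.items():
            if t.counts[(o, tr)]:
                assert p == (1.0 if o == "rewarded" else 0.0)

    def test_cell_counts_sum_to_n_minus_one(self, control_session_frame):
        t = stay_probabilities(control_session_frame)
        assert sum(t.counts.values()) == len(control_session_frame) - 1


def _fixture_stay_table():
    """Seeded 8+8 stay table; the ANOVA on it was validated externally."""
    rng = np.random.default_rng(11)
    rows = []
    for i in range(16):
        cond = "control" if i < 8 else "stress"
        base = rng.uniform(0.3, 0.8)
        vals = np.clip(base + rng.normal(0, 0.12, 4), 0, 1)
        rows.append(
            {
                "subject_id": f"s{i:02d}",
                "condition": cond,
                **dict(zip(STAY_COLUMNS, vals)),
            }
        )
    return pd.DataFrame(rows)


class TestStayAnova:
    # Frozen from an independent split-plot fit (base-R aov, univariate
    # mixed-design partitioning) of the seeded fixture above.
    EXPECTED = {
        "condition": (1.763, 0.206),
        "outcome": (2.294, 0.152),
        "transition": (0.156, 0.699),
        "condition * outcome": (0.581, 0.459),
        "condition * transition": (1.023, 0.329),
        "outcome * transition": (0.124, 0.730),
        "condition * outcome * transition": (0.021, 0.888),
    }

    def test_matches_independent_split_plot_fit(self):
        table = stay_anova(_fixture_stay_table()).set_index("effect")
        for effect, (f_exp, p_exp) in self.EXPECTED.items():
            assert table.loc[effect, "F"] == pytest.approx(f_exp, abs=2e-3)
            assert table.loc[effect, "p"] == pytest.approx(p_exp, abs=1e-3)
            assert table.loc[effect, "df1"] == 1
            assert table.loc[effect, "df2"] == 14

    def test_three_way_f_equals_squared_t_of_double_difference(self):
        """With 2-level factors the three-way effect reduces to a two-sample
        t-test on the per-subject (reward x transition) double difference."""
        df = _fixture_stay_table()
        table = stay_anova(df).set_index("effect")
        contrast = (
            df["stay_rewarded_common"]
            - df["stay_rewarded_rare"]
            - df["stay_unrewarded_common"]
            + df["stay_unrewarded_rare"]
        ) / 2.0
        t, _ = sps.ttest_ind(
            contrast[df["condition"] == "control"],
            contrast[df["condition"] == "stress"],
        )
        assert table.loc["condition * outcome * transition", "F"] == pytest.approx(
            t**2, rel=1e-9
        )

    def test_permuted_labels_give_uniform_null_p(self):
        df = _fixture_stay_table()
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(200):
            perm = df.copy()
            perm["condition"] = rng.permutation(df["condition"].to_numpy())
            if perm["condition"].nunique() < 2:
                continue
            table = stay_anova(perm).set_index("effect")
            ps.append(table.loc["condition * outcome * transition", "p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_raises(self):
        rows = [
            {
                "subject_id": f"s{i}",
                "condition": "control" if i < 3 else "stress",
                **{c: 0.5 for c in STAY_COLUMNS},
            }
            for i in range(6)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            stay_anova(pd.DataFrame(rows))

    def test_empty_cell_subjects_dropped_with_warning(self):
        df = _fixture_stay_table()
        df.loc[0, "stay_rewarded_rare"] = np.nan
        with pytest.warns(UserWarning, match="empty stay cells"):
            table = stay_anova(df)
        assert (table["df2"] == 13).all()


class TestPerformance:
    def test_no_rewards_no_points(self, config):
        df = make_trial_frame(["a1", "a2"] * 10, ["common"] * 20, [0] * 20)
        s = performance_summary(df, config)
        assert s.total_points == 0

    def test_points_count_rewarded_trials_exactly(self, config, control_session_frame):
        s = performance_summary(control_session_frame, config)
        n_rewarded = int((control_session_frame["outcome"] > 0).sum())
        assert s.total_points == 100 * n_rewarded

    def test_always_advantageous_agent_scores_one(self, config):
        rows = []
        for b in range(1, 7):
            adv = config.advantageous_action(b) or "a1"
            for i in range(40):
                rows.append((adv, "common", 0, b))
        df = make_trial_frame(
            [r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows]
        )
        df["block"] = [r[3] for r in rows]
        df["trial"] = np.arange(1, 241)
        assert performance_summary(df, config).p_advantageous == 1.0

    def test_block1_not_scored(self, config):
        # advantageous only defined for blocks 2-6: 200 of 240 trials
        df = make_trial_frame(["a1"] * 240, ["common"] * 240, [0] * 240)
        df["block"] = np.repeat(np.arange(1, 7), 40)
        # a1 is advantageous in blocks 2, 4, 6 only -> 120/200
        assert performance_summary(df, config).p_advantageous == pytest.approx(0.6)


class TestCompareConditions:
    @staticmethod
    def _table(x, y):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(len(x) + len(y))],
                "condition": ["control"] * len(x) + ["stress"] * len(y),
                "v": list(x) + list(y),
            }
        )

    def test_identical_groups_are_null(self):
        out = compare_conditions(self._table([1, 2, 3], [1, 2, 3]), ["v"])
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_shifted_constant_groups_raise(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            compare_conditions(self._table([1, 1, 1], [2, 2, 2]), ["v"])

    def test_matches_scipy_on_real_data(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 22)
        out = compare_conditions(self._table(x, y), ["v"])
        t, p = sps.ttest_ind(x, y)
        assert out.loc[0, "t"] == pytest.approx(t)
        assert out.loc[0, "df"] == 40

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError, match="two subjects"):
            compare_conditions(self._table([1.0], [2.0, 3.0]), ["v"])


def _fits_frame(n, rng, treatment_effect=0.0, gamma_effect=0.5, noise=0.2):
    cond = np.array(["control"] * n + ["stress"] * n)
    gamma = rng.uniform(0.1, 0.9, 2 * n)
    treat = (cond == "stress").astype(float)
    y = gamma_effect * gamma + treatment_effect * treat + rng.normal(0, noise, 2 * n)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(2 * n)],
            "condition": cond,
            "gamma": gamma,
            "d_minus_mf": y,
        }
    )


class TestDeltaRegression:
    def test_null_treatment_coefficient_near_zero(self):
        fits = _fits_frame(100, np.random.default_rng(5), treatment_effect=0.0)
        out = delta_regression(fits).set_index("predictor")
        assert abs(out.loc["treatment", "B"]) < 0.1
        assert out.loc["gamma", "B"] == pytest.approx(0.5, abs=0.2)

    def test_recovers_planted_treatment_effect(self):
        fits = _fits_frame(100, np.random.default_rng(6), treatment_effect=-0.4)
        out = delta_regression(fits).set_index("predictor")
        assert out.loc["treatment", "B"] == pytest.approx(-0.4, abs=0.15)
        assert out.loc["treatment", "p"] < 0.001
        assert abs(out.loc["treatment", "beta"]) < 1.0

    def test_constant_gamma_raises(self):
        fits = _fits_frame(20, np.random.default_rng(7))
        fits["gamma"] = 0.5
        with pytest.raises(ValueError, match="collinear|constant"):
            delta_regression(fits)


class TestDeltaAncova:
    @staticmethod
    def _perf(fits, covariate):
        return pd.DataFrame(
            {"subject_id": fits["subject_id"], "p_advantageous": covariate}
        )

    def test_noise_covariate_leaves_condition_effect(self):
        rng = np.random.default_rng(8)
        fits = _fits_frame(50, rng, treatment_effect=-0.4, gamma_effect=0.0)
        perf = self._perf(fits, rng.uniform(0.4, 0.6, len(fits)))
        out = delta_ancova(fits, perf).set_index("Source")
        t_out = compare_conditions(fits, ["d_minus_mf"])
        # with an irrelevant covariate the adjusted F tracks the raw t^2
        assert out.loc["condition", "F"] == pytest.approx(
            t_out.loc[0, "t"] ** 2, rel=0.15
        )
        assert out.loc["condition", "p-unc" if "p-unc" in out.columns else "p_unc"] < 0.01

    def test_confound_fully_explained_by_covariate(self):
        rng = np.random.default_rng(9)
        fits = _fits_frame(50, rng, treatment_effect=0.0, gamma_effect=0.0, noise=1.0)
        # outcome is (almost exactly) the covariate; the condition term
        # explains nothing beyond it
        perf = self._perf(fits, fits["d_minus_mf"] + rng.normal(0, 1e-6, len(fits)))
        out = delta_ancova(fits, perf).set_index("Source")
        assert out.loc["condition", "F"] < 1e-3

    def test_constant_covariate_raises(self):
        fits = _fits_frame(10, np.random.default_rng(10))
        perf = self._perf(fits, np.full(len(fits), 0.5))
        with pytest.raises(ValueError, match="constant"):
            delta_ancova(fits, perf)


class TestCohortStayTable:
    def test_one_row_per_subject_with_condition(self, config):
        frames = [
            trials_to_frame(
                simulate_session(
                    AgentSpec(kind="random"),
                    config,
                    seed=i,
                    subject_id=f"r{i}",
                    condition="stress" if i % 2 else "control",
                )
            )
            for i in range(4)
        ]
        table = cohort_stay_table(pd.concat(frames, ignore_index=True))
        assert len(table) == 4
        assert set(table.columns) >= set(STAY_COLUMNS)
        assert table[list(STAY_COLUMNS)].notna().all().all()
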