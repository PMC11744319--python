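import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from stomaspec.stats import (CONTINUE, EXCLUDE, INCLUDE, PROMOTE, REMOVE,
                             chi_square_random_choice, fit_choice_model,
                             inclusion_filter, round_half_up, success_rate,
                             summarize_experiment, trainability_percent)


def records(rows):
    cols = ["individual", "group", "stage", "illumination", "combination",
            "choice_pos", "correct", "reinforcement"]
    return pd.DataFrame(rows, columns=cols)


def trial(ind="a", group="blue", stage="testing", illum="natural", comb="0.15/0.3",
          choice="left", correct=True, reinf=False):
    return (ind, group, stage, illum, comb, choice, correct, reinf)


class TestSuccessRates:
    def test_zero_correct_is_zero_percent(self):
        df = records([trial(correct=False) for _ in range(10)])
        s = success_rate(df)
        assert s.success_rate == 0.0 and s.n_trials == 10

    def test_empty_cell_is_explicit_not_zero(self):
        s = success_rate(records([]), group="red")
        assert s.empty and s.success_rate is None

    def test_reinforcement_and_no_choice_excluded(self):
        df = records([trial(correct=True),
                      trial(correct=True, reinf=True),
                      trial(choice=None, correct=None),
                      trial(correct=False)])
        s = success_rate(df)
        assert s.n_trials == 2 and s.n_correct == 1 and s.success_rate == 50.0

    def test_reporting_rounding_is_half_up(self):
        assert round_half_up(14.815) == 14.82
        assert round_half_up(100 * 59 / 83) == 71.08

    @pytest.mark.parametrize("passed,trained,expected", [
        (4, 27, 14.81), (8, 20, 40.0), (8, 22, 36.36)])
    def test_trainability_from_group_counts(self, passed, trained, expected):
        assert trainability_percent(passed, trained) == expected


class TestChiSquare:
    def test_perfect_fit(self):
        stat, p = chi_square_random_choice(10, 30)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # sum((O-E)^2/E) with E = (20/3, 40/3): 0.4
        stat, _ = chi_square_random_choice(8, 20)
        assert stat == pytest.approx(0.4)

    @pytest.mark.parametrize("correct,total", [(81, 107), (73, 99)])
    def test_strong_preference_beats_printed_bound(self, correct, total):
        _, p = chi_square_random_choice(correct, total)
        assert p < 0.0001

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_random_choice(5, 4)
        with pytest.raises(ValueError):
            chi_square_random_choice(0, 0)


class TestInclusionFilter:
    def test_training_five_of_six_promotes(self):
        assert inclusion_filter([1, 1, 1, 1, 1, 0], "training") == PROMOTE

    def test_training_midrange_continues(self):
        assert inclusion_filter([1, 0] * 5, "training") == CONTINUE

    def test_training_below_thirty_percent_removes(self):
        assert inclusion_filter([0, 0, 0, 0, 1, 0, 0, 0, 0, 0], "training") == REMOVE

    def test_priming_rules(self):
        assert inclusion_filter([1, 1, 1, 1, 0], "priming") == PROMOTE
        assert inclusion_filter([0, 1, 0, 0, 1, 0], "priming") == REMOVE
        assert inclusion_filter([1, 1], "priming") == CONTINUE

    def test_testing_natural_light_gate(self):
        assert inclusion_filter([1, 1, 0, 0, 0], "testing") == EXCLUDE  # 40%
        assert inclusion_filter([1, 1, 1, 0, 0], "testing") == INCLUDE  # 60%

    def test_short_history_continues(self):
        assert inclusion_filter([1, 1, 1], "training") == CONTINUE

    def test_pure_function_of_history(self):
        h = [1, 0, 1, 1, 1, 1, 0, 1]
        assert inclusion_filter(h, "training") == inclusion_filter(list(h), "training")

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            inclusion_filter([1], "resting")


def simulate_glmm(n_ind, n_tr, effect, sd=0.7, seed=0, base=0.8):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ind):
        u = rng.normal(0, sd)
        x = rng.integers(0, 2, n_tr)
        y = rng.random(n_tr) < 1 / (1 + np.exp(-(base + effect * x + u)))
        rows.append(pd.DataFrame({
            "individual": f"id{i:02d}", "stage": "testing",
            "illumination": np.where(x == 1, "tent", "natural"),
            "correct": y, "reinforcement": False,
            "choice_pos": "left", "combination": "0.15/0.3"}))
    return pd.concat(rows, ignore_index=True)


class TestChoiceModel:
    def test_single_individual_rejected(self):
        df = simulate_glmm(1, 50, 0.0, seed=3)
        with pytest.raises(ValueError, match="individuals"):
            fit_choice_model(df, fixed_effects=("illumination",))

    def test_recovers_known_illumination_effect(self):
        df = simulate_glmm(15, 150, -1.0, seed=7)
        fit = fit_choice_model(df, fixed_effects=("illumination",))
        assert fit.converged
        assert fit.coef("illumination[tent]") == pytest.approx(-1.0, abs=0.35)
        assert 0.3 < fit.random_intercept_sd < 1.3

    def test_ml_and_variational_routes_agree(self):
        df = simulate_glmm(12, 100, -0.8, seed=11)
        ml = fit_choice_model(df, fixed_effects=("illumination",), method="ml")
        vb = fit_choice_model(df, fixed_effects=("illumination",), method="vb")
        vb_term = [t for t in vb.params.index if "tent" in t][0]
        assert ml.coef("illumination[tent]") == pytest.approx(vb.params.loc[vb_term, "coef"],
                                                              abs=0.15)

    def test_matches_lme4_reference(self, tmp_path):
        # independent oracle: R lme4::glmer on the same data
        df = simulate_glmm(10, 80, -0.8, seed=21)
        fit = fit_choice_model(df, fixed_effects=("illumination",))
        csv = tmp_path / "d.csv"
        df.assign(correct=df["correct"].astype(int)).to_csv(csv, index=False)
        script = (
            f'd<-read.csv("{csv}");'
            'suppressMessages(library(lme4));'
            'm<-glmer(correct~illumination+(1|individual),d,family=binomial);'
            'cat(fixef(m)["illuminationtent"])'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                             timeout=300)
        assert out.returncode == 0, out.stderr
        assert fit.coef("illumination[tent]") == pytest.approx(float(out.stdout.split()[-1]),
                                                               abs=0.02)


class TestSummarize:
    def test_report_roundtrips_through_json(self):
        from stomaspec.experiment import ExperimentDesign, StagePlan, simulate_experiment
        from stomaspec.stats import ExperimentReport

        ds, fates = simulate_experiment(
            ExperimentDesign(n_per_group=3, plan=StagePlan(testing_days=4)), seed=2)
        rep = summarize_experiment(ds, fates)
        back = ExperimentReport.from_json(rep.to_json())
        pd.testing.assert_frame_equal(
            back.group_summaries, rep.group_summaries, check_dtype=False)
        assert "trainability_percent" in rep.inclusion_ledger.columns

    def test_empty_condition_absent_not_zero(self):
        df = records([trial()])
        rep = summarize_experiment(df)
        assert not (rep.group_summaries["n_trials"] == 0).any()
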