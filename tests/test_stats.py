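import numpy as np
import pandas as pd
import pytest

from conftest import make_report
from oculoread.simulate import SimulationConfig, simulate_experiment
from oculoread.stats import (
    SACCADE_TYPES,
    classify_saccades,
    duration_measures,
    event_probabilities,
    fixation_case_table,
    global_summary,
    word_length_class,
)


@pytest.mark.parametrize("length, cls", [(1, 3), (2, 3), (3, 3), (5, 5), (8, 8), (9, 8), (12, 8)])
def test_word_length_class_grouping(length, cls):
    assert word_length_class(length) == cls


def test_word_length_class_rejects_nonpositive():
    with pytest.raises(ValueError):
        word_length_class(0)


class TestClassification:
    def test_basic_taxonomy(self):
        rep = make_report([3, 4, 5, 5, 2, 3, 5])
        ev = classify_saccades(rep)
        assert list(ev["type"]) == [
            "forward",      # 3 -> 4
            "forward",      # 4 -> 5
            "refixation",   # 5 -> 5 (first pass)
            "regression",   # 5 -> 2
            "forward",      # 2 -> 3 (second pass movement, still next word)
            "skipping",     # 3 -> 5 (over word 4)
        ]

    def test_second_pass_leftward_within_word_is_regression(self):
        rep = make_report([2, 3, 2, 2], xs=[12.0, 18.0, 13.0, 11.0])
        ev = classify_saccades(rep)
        # word 2 was exited; moving left within it on the revisit is regressive
        assert list(ev["type"]) == ["forward", "regression", "regression"]
        rep2 = make_report([2, 3, 2, 2], xs=[12.0, 18.0, 11.0, 13.0])
        assert list(classify_saccades(rep2)["type"])[-1] == "refixation"

    def test_first_pass_flag_tracks_word_exit(self):
        rep = make_report([1, 2, 1, 2])
        ev = classify_saccades(rep)
        # three events; the last launches from the revisit of word 1
        assert list(ev["first_pass"]) == [True, True, False]

    def test_events_partition_fixation_pairs(self, toy_report):
        ev = classify_saccades(toy_report)
        assert len(ev) == len(toy_report) - 1
        assert ev["type"].isin(SACCADE_TYPES).all()

    def test_unassigned_word_raises(self, toy_report):
        toy_report.loc[2, "word_index"] = np.nan
        with pytest.raises(ValueError):
            classify_saccades(toy_report)


class TestGlobalSummary:
    def test_hand_counted_percentages(self, toy_report):
        ev = classify_saccades(toy_report)
        gs = global_summary(ev, toy_report)
        assert gs.pct_forward == pytest.approx(50.0)
        assert gs.pct_skipping == pytest.approx(0.0)
        assert gs.pct_refixation == pytest.approx(25.0)
        assert gs.pct_regression == pytest.approx(25.0)

    def test_all_forward(self):
        rep = make_report([1, 2, 3])
        gs = global_summary(classify_saccades(rep), rep)
        assert gs.pct_forward == 100.0

    def test_progressive_mean_length(self):
        rep = make_report([1, 2, 3], xs=[0.0, 6.0, 14.0])  # lengths 6 and 8
        gs = global_summary(classify_saccades(rep), rep)
        assert gs.mean_progressive_length == pytest.approx(7.0)

    def test_empty_input_gives_empty_marker(self):
        rep = make_report([])
        gs = global_summary(classify_saccades(rep), rep)
        assert gs.empty and gs.pct_forward is None


class TestFixationCases:
    def test_all_single(self):
        tab = fixation_case_table(make_report([1, 2, 3]))
        assert tab["single"] == 100.0 and tab["two"] == 0.0

    def test_hand_counted_cases(self):
        # 6 single, 3 double, 1 triple across two trials (10 fixated words)
        rep = pd.concat(
            [
                make_report([1, 1, 2, 3, 3, 4, 5], trial=1),
                make_report([1, 1, 1, 2, 3, 3, 4, 5], trial=2),
            ],
            ignore_index=True,
        )
        tab = fixation_case_table(rep)
        assert tab["single"] == pytest.approx(60.0)
        assert tab["two"] == pytest.approx(30.0)
        assert tab["multiple"] == pytest.approx(10.0)

    def test_rows_sum_to_100(self):
        cfg = SimulationConfig(n_subjects=1, n_trials=60, seed=2)
        fx, _ = simulate_experiment(cfg)
        assert fixation_case_table(fx).sum() == pytest.approx(100.0, abs=0.01)

    def test_second_pass_visits_do_not_count_by_default(self):
        # word 2 revisited after exit: first-pass count stays 1
        rep = make_report([1, 2, 3, 2, 4])
        tab = fixation_case_table(rep)
        assert tab["single"] == 100.0
        tab_all = fixation_case_table(rep, first_pass_only=False)
        assert tab_all["two"] > 0


class TestEventProbabilities:
    def test_hand_counted_refixation_probability(self):
        # 20 fixated medium words (the length-6 word 2), 4 refixated -> 0.20
        trials = []
        for t in range(20):
            seq = [1, 2, 2, 3] if t < 4 else [1, 2, 3]
            lengths = [3 if w != 2 else 6 for w in seq]
            trials.append(make_report(seq, trial=t + 1, word_lengths=lengths))
        rep = pd.concat(trials, ignore_index=True)
        words = rep[["subject", "session", "trial", "word_index", "word_length"]].drop_duplicates()
        probs = event_probabilities(rep, words)
        assert probs.loc[6, "p_refix"] == pytest.approx(4 / 20)

    def test_no_refixations_gives_zero_everywhere(self):
        rep = make_report([1, 2, 3], word_lengths=[5, 5, 5])
        words = rep[["subject", "session", "trial", "word_index", "word_length"]]
        probs = event_probabilities(rep, words)
        assert probs["p_refix"].dropna().eq(0).all()

    def test_empty_class_is_nan(self):
        rep = make_report([1, 2, 3], word_lengths=[5, 5, 5])
        words = rep[["subject", "session", "trial", "word_index", "word_length"]]
        probs = event_probabilities(rep, words)
        assert np.isnan(probs.loc[8, "p_refix"])

    def test_refixation_monotone_when_configured_table_is(self):
        table = {3: 0.05, 4: 0.08, 5: 0.12, 6: 0.18, 7: 0.25, 8: 0.35}
        cfg = SimulationConfig(n_subjects=1, n_trials=900, seed=13, p_refix=table)
        fx, words = simulate_experiment(cfg)
        probs = event_probabilities(fx, words)
        est = probs["p_refix"].dropna()
        assert (est.diff().dropna() > -0.03).all()  # non-decreasing up to noise


class TestDurations:
    def test_single_and_first_of_multiple_means(self):
        rep = pd.concat(
            [
                make_report([1, 2, 3], durations=[200, 300, 999], trial=1),
                make_report([1, 2, 2, 3], durations=[999, 400, 100, 999], trial=2),
            ],
            ignore_index=True,
        )
        dm = duration_measures(rep)
        # single-fixation words of length 5 (class 5): durations 200, 300, 999, 999, 999
        assert dm.loc[5, "single_fixation_ms"] == pytest.approx(
            np.mean([200, 300, 999, 999, 999])
        )
        # the only multiple-fixation word contributes its first duration, 400
        assert dm.loc[5, "first_of_multiple_ms"] == pytest.approx(400.0)

    def test_configured_single_fixation_mean_recovered(self):
        cfg = SimulationConfig(n_subjects=1, n_trials=400, seed=19)
        fx, _ = simulate_experiment(cfg)
        dm = duration_measures(fx)
        expected = np.exp(cfg.logmean_for("first") + cfg.duration_logsd**2 / 2)
        pooled = np.average(
            dm["single_fixation_ms"].dropna(),
            weights=dm.loc[dm["single_fixation_ms"].notna(), "n_single"],
        )
        n = dm["n_single"].sum()
        se = expected * 0.36 / np.sqrt(n)  # lognormal cv at sd 0.35
        assert pooled == pytest.approx(expected, abs=4 * se)
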