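import numpy as np
import pytest

from cogload.behavior import (
    accuracy,
    rt_fluctuation_spectrum,
    rt_indices,
    score_three_back,
    score_zero_back,
    summarize,
)
from cogload.io import TaskRun, Trial
from cogload.synthdata import synth_behavior


def run_from(digits, responses, condition, rts=None):
    rts = rts if rts is not None else [500.0] * len(digits)
    trials = [Trial(i, d, 3.0 * i, r, rt)
              for i, (d, r, rt) in enumerate(zip(digits, responses, rts))]
    return TaskRun(condition, trials)


class TestScoring:
    def test_three_back_hand_enumeration(self):
        digits = [5, 2, 7, 5, 9, 7]
        responses = [None, None, None, "match", "nonmatch", "match"]
        run = run_from(digits, ["nonmatch" if r is None else r for r in responses],
                       "three_back")
        correct, scorable = score_three_back(run)
        assert list(scorable) == [False, False, False, True, True, True]
        assert correct[3:].all()
        assert accuracy(run) == 1.0

    def test_three_back_inverted_responses(self):
        digits = [5, 2, 7, 5, 9, 7]
        inverted = ["match", "match", "match", "nonmatch", "match", "nonmatch"]
        run = run_from(digits, inverted, "three_back")
        assert accuracy(run) == 0.0

    def test_three_back_needs_four_trials(self):
        run = run_from([1, 2, 3], ["nonmatch"] * 3, "three_back")
        with pytest.raises(ValueError):
            score_three_back(run)

    @pytest.mark.parametrize("digit,response,expected", [
        (4, "even", True), (7, "even", False), (7, "odd", True), (0, "even", True),
    ])
    def test_zero_back_parity(self, digit, response, expected):
        run = run_from([digit], [response], "zero_back")
        correct, _ = score_zero_back(run)
        assert bool(correct[0]) is expected

    def test_zero_back_all_correct_200_trials(self):
        rng = np.random.default_rng(10)
        digits = rng.integers(0, 10, 200)
        responses = ["even" if d % 2 == 0 else "odd" for d in digits]
        run = run_from(digits, responses, "zero_back")
        assert accuracy(run) == 1.0

    def test_malformed_response_rejected(self):
        run = run_from([1, 2, 3, 4], ["yes", "no", "yes", "no"], "three_back")
        with pytest.raises(ValueError, match="malformed"):
            score_three_back(run)


class TestRtIndices:
    def test_mean_and_iqr_linear_interpolation(self):
        run = run_from([1] * 8, ["odd"] * 8, "zero_back",
                       rts=[400, 500, 600, 700, 400, 500, 600, 700])
        mean, iqr, n_omit = rt_indices(run)
        assert mean == pytest.approx(550.0)
        assert iqr == pytest.approx(150.0)  # Q3=625, Q1=475 under type-7
        assert n_omit == 0

    def test_constant_rts_zero_iqr(self):
        run = run_from([1] * 10, ["odd"] * 10, "zero_back", rts=[500.0] * 10)
        _, iqr, _ = rt_indices(run)
        assert iqr == 0.0

    def test_incorrect_trials_included_in_mean(self):
        digits = [2] * 10
        half_wrong = ["even"] * 5 + ["odd"] * 5
        run = run_from(digits, half_wrong, "zero_back", rts=[500.0] * 10)
        mean, _, _ = rt_indices(run)
        assert mean == pytest.approx(500.0)

    def test_omissions_excluded_and_counted(self):
        rts = [500.0] * 9 + [float("nan")]
        run = run_from([1] * 10, ["odd"] * 9 + ["none"], "zero_back", rts=rts)
        mean, _, n_omit = rt_indices(run)
        assert mean == pytest.approx(500.0)
        assert n_omit == 1

    def test_iqr_shift_and_scale(self):
        rng = np.random.default_rng(11)
        rts = 500 + 100 * rng.random(50)
        run1 = run_from([1] * 50, ["odd"] * 50, "zero_back", rts=list(rts))
        run2 = run_from([1] * 50, ["odd"] * 50, "zero_back", rts=list(3 * rts + 250))
        _, iqr1, _ = rt_indices(run1)
        _, iqr2, _ = rt_indices(run2)
        assert iqr2 == pytest.approx(3 * iqr1, rel=1e-9)


class TestRtFluctuation:
    def test_constant_series_index_zero(self):
        run = run_from([1] * 200, ["odd"] * 200, "zero_back", rts=[500.0] * 200)
        _, _, index = rt_fluctuation_spectrum(run)
        assert index == pytest.approx(0.0, abs=1e-18)

    def test_in_band_drift_dominates_fast_oscillation(self):
        t = 3.0 * np.arange(200)
        slow = 600 + 100 * np.sin(2 * np.pi * t / 50.0)   # 0.02 Hz, in band
        fast = 600 + 100 * np.sin(2 * np.pi * t * 0.1)    # 0.1 Hz, out of band
        run_slow = run_from([1] * 200, ["odd"] * 200, "zero_back", rts=list(slow))
        run_fast = run_from([1] * 200, ["odd"] * 200, "zero_back", rts=list(fast))
        _, _, i_slow = rt_fluctuation_spectrum(run_slow)
        _, _, i_fast = rt_fluctuation_spectrum(run_fast)
        assert i_slow >= 10 * i_fast

    def test_frequency_resolution_sufficient(self):
        run = synth_behavior(condition="zero_back", seed=1)
        freqs, _, _ = rt_fluctuation_spectrum(run)
        df = freqs[1] - freqs[0]
        assert df <= 0.005
        assert run.n_trials * run.isi_s == pytest.approx(600.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(12)
        rts = 500 + 50 * rng.standard_normal(200)
        r1 = run_from([1] * 200, ["odd"] * 200, "zero_back", rts=list(rts))
        r2 = run_from([1] * 200, ["odd"] * 200, "zero_back", rts=list(rts + 300))
        assert rt_fluctuation_spectrum(r1)[2] == pytest.approx(
            rt_fluctuation_spectrum(r2)[2], rel=1e-6)

    def test_excess_missing_rejected(self):
        rts = [500.0] * 150 + [float("nan")] * 50
        run = run_from([1] * 200, ["odd"] * 150 + ["none"] * 50, "zero_back", rts=rts)
        with pytest.raises(ValueError, match="lack a response"):
            rt_fluctuation_spectrum(run)


def test_summarize_fields_consistent():
    run = synth_behavior(condition="three_back", accuracy_true=0.9,
                         rt_drift_amp_ms=80.0, seed=13)
    summ = summarize(run)
    assert summ.condition == "three_back"
    assert 0.8 <= summ.accuracy <= 1.0
    assert summ.rt_iqr_ms > 0
    assert summ.n_scorable == 197
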