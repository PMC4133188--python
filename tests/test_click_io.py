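import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from penpress.click_io import (
    ClickTrain,
    detect_clicks,
    flow_from_clicks,
    read_click_table,
    suggest_truncation,
    write_click_table,
)
from penpress.errors import FormatError, InsufficientDataError, InvalidInputError
from penpress.synthetic import render_click_wav, simulate_injection
from penpress.units import UL, UL_PER_S


class TestDetectClicks:
    def test_silence_yields_empty_train(self):
        train = detect_clicks(np.zeros(48000), 48000.0)
        assert train.n_clicks == 0

    def test_known_impulse_times_recovered_within_1ms(self):
        truth = np.linspace(0.05, 2.0, 24)
        train = ClickTrain(truth)
        audio, rate = render_click_wav(train, sample_rate=44100, snr_db=20, seed=7)
        detected = detect_clicks(audio, rate)
        assert detected.n_clicks == 24
        assert np.max(np.abs(detected.times - truth)) < 1e-3

    def test_refractory_merges_close_impulses(self):
        rate = 48000.0
        audio = np.zeros(4800)
        for t in (0.050, 0.051):  # 1 ms apart
            i = int(t * rate)
            audio[i : i + 10] = 1.0
        audio += np.random.default_rng(0).normal(0, 1e-3, audio.size)
        train = detect_clicks(audio, rate, refractory=0.010)
        assert train.n_clicks == 1

    def test_nonfinite_audio_rejected(self):
        audio = np.zeros(1000)
        audio[500] = np.nan
        with pytest.raises(InvalidInputError):
            detect_clicks(audio, 8000.0)


class TestFlowFromClicks:
    def test_uniform_intervals_give_constant_flow(self):
        train = ClickTrain([0.0, 0.1, 0.2, 0.3], volume_per_click=10 * UL)
        flow = flow_from_clicks(train, truncate_tail=0)
        assert np.allclose(flow.Q, 100 * UL_PER_S)
        assert np.allclose(flow.t_mid, [0.05, 0.15, 0.25])

    def test_240uL_dose_has_23_intervals(self):
        times = np.cumsum(np.full(24, 0.09))
        flow = flow_from_clicks(ClickTrain(times), truncate_tail=0)
        assert len(flow) == 23

    def test_truncation_drops_trailing_intervals(self):
        times = np.arange(10) * 0.1
        flow = flow_from_clicks(ClickTrain(times), truncate_tail=2)
        assert len(flow) == 7
        assert flow.truncated_tail == 2

    def test_non_increasing_times_rejected(self):
        with pytest.raises(InvalidInputError):
            ClickTrain([0.0, 0.1, 0.1])

    def test_too_few_clicks_rejected(self):
        with pytest.raises(InsufficientDataError):
            flow_from_clicks(ClickTrain([0.0, 0.1]), truncate_tail=2)

    def test_volume_conservation(self):
        rng = np.random.default_rng(3)
        times = np.cumsum(rng.uniform(0.05, 0.15, size=30))
        train = ClickTrain(times)
        flow = flow_from_clicks(train, truncate_tail=0)
        assert np.isclose(np.sum(flow.Q * np.diff(times)), 29 * train.volume_per_click)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, scale):
        # stretching all intervals by c divides every Q by c
        times = np.array([0.0, 0.08, 0.2, 0.25, 0.4])
        q1 = flow_from_clicks(ClickTrain(times), 0).Q
        q2 = flow_from_clicks(ClickTrain(times * scale), 0).Q
        assert np.allclose(q2, q1 / scale)


class TestAudioToFlowPipeline:
    def test_detected_flow_matches_generating_profile_within_1pct(self, spring, geom, fluid):
        inj = simulate_injection(spring, "air", geom, fluid, dose=240 * UL,
                                 jitter_sd=0.0, seed=11)
        audio, rate = render_click_wav(inj.clicks, snr_db=25, seed=4)
        detected = detect_clicks(audio, rate)
        assert detected.n_clicks == inj.clicks.n_clicks
        flow = flow_from_clicks(detected, truncate_tail=0)
        q_true = np.interp(flow.t_mid, inj.t_grid, inj.Q_grid)
        assert np.max(np.abs(flow.Q / q_true - 1)) < 0.01


class TestClickTableIO:
    def test_round_trip_identity(self, tmp_path):
        train = ClickTrain(np.cumsum(np.full(24, 0.1)), subject_id="S01", medium="tissue")
        path = tmp_path / "clicks.csv"
        write_click_table(train, path)
        back = read_click_table(path)
        assert back.subject_id == "S01"
        assert back.medium == "tissue"
        assert np.allclose(back.times, train.times)

    def test_unknown_medium_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,medium,click_index,time_s\nS01,water,0,0.0\n")
        with pytest.raises(FormatError):
            read_click_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,click_index,time_s\nS01,0,0.0\n")
        with pytest.raises(FormatError):
            read_click_table(path)

    def test_shuffled_index_reordered_by_time(self, tmp_path):
        path = tmp_path / "shuffled.csv"
        path.write_text(
            "subject_id,medium,click_index,time_s\n"
            "S01,air,2,0.3\nS01,air,0,0.1\nS01,air,1,0.2\n"
        )
        train = read_click_table(path)
        assert np.allclose(train.times, [0.1, 0.2, 0.3])


class TestSuggestTruncation:
    def test_flags_trailing_flow_drop(self):
        # steady clicking, then two slow trailing intervals (force drop)
        times = np.concatenate([np.arange(10) * 0.1, [1.3, 1.8]])
        assert suggest_truncation(ClickTrain(times)) == 2

    def test_clean_train_not_flagged(self):
        times = np.arange(20) * 0.1
        assert suggest_truncation(ClickTrain(times)) == 0
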