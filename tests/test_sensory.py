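import numpy as np
import pytest

from ethophys import sensory, synth

FPS = 120.0


def _peth_from_raw(raw):
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[1]
    times = np.linspace(-10 + 0.025, 10 - 0.025, n)
    return sensory.PETH(rates=raw, raw=raw, times=times,
                        onsets=np.zeros(raw.shape[0]))


class TestPETH:
    def test_no_spikes_all_zero(self):
        ev = synth.EventTrain(onsets=np.array([30.0, 60.0]), duration_s=5.0,
                              session_duration_s=120.0)
        peth = sensory.compute_peth([], ev)
        assert peth.rates.shape == (2, 400)
        assert np.all(peth.rates == 0)

    def test_homogeneous_poisson_flat(self, rng):
        dur = 600.0
        rate = 5.0
        spikes = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
        ev = synth.gen_stimulus_session(duration_s=dur, seed=2)
        peth = sensory.compute_peth(spikes, ev)
        avg = peth.trial_average.mean()
        n_obs = peth.raw.size * 0.05          # seconds of data summed
        se = np.sqrt(rate / n_obs)
        assert abs(avg - rate) < 3 * se

    def test_edge_events_dropped_with_warning(self, rng):
        ev = synth.EventTrain(onsets=np.array([3.0, 50.0]), duration_s=5.0,
                              session_duration_s=100.0)
        with pytest.warns(UserWarning, match="dropped"):
            peth = sensory.compute_peth(np.sort(rng.uniform(0, 100, 200)), ev)
        assert peth.onsets.tolist() == [50.0]

    def test_smoothing_preserves_mean_rate(self, rng):
        dur = 400.0
        spikes = np.sort(rng.uniform(0, dur, 3000))
        ev = synth.EventTrain(onsets=np.array([100.0, 200.0, 300.0]),
                              duration_s=5.0, session_duration_s=dur)
        peth = sensory.compute_peth(spikes, ev)
        interior = slice(20, 380)
        raw_mean = peth.raw[:, interior].mean()
        smooth_mean = peth.rates[:, interior].mean()
        assert smooth_mean == pytest.approx(raw_mean, rel=0.01)


class TestSMI:
    def test_equal_windows_zero(self):
        raw = np.full((6, 400), 4.0)
        res = sensory.sound_modulation_index(_peth_from_raw(raw))
        assert res.index == 0.0
        assert res.direction == "none"

    def test_silent_baseline_gives_plus_one(self):
        raw = np.zeros((6, 400))
        raw[:, 210:220] = 10.0            # 0.5-1.0 s post onset
        res = sensory.sound_modulation_index(_peth_from_raw(raw))
        assert res.index == 1.0
        assert res.direction == "activated"

    def test_closed_form_minus_half(self):
        raw = np.zeros((8, 400))
        raw[:, 180:190] = 6.0             # baseline window (-1.0,-0.5) s
        raw[:, 210:220] = 2.0             # sound window
        res = sensory.sound_modulation_index(_peth_from_raw(raw))
        assert res.index == pytest.approx(-0.5)
        assert res.direction == "suppressed"

    def test_window_swap_antisymmetry(self, rng):
        raw = rng.uniform(0, 10, (10, 400))
        res = sensory.sound_modulation_index(_peth_from_raw(raw))
        flipped = _peth_from_raw(raw[:, ::-1])
        res_flip = sensory.sound_modulation_index(flipped)
        assert res_flip.index == pytest.approx(-res.index, abs=1e-12)

    def test_needs_five_trials(self):
        with pytest.raises(ValueError):
            sensory.sound_modulation_index(_peth_from_raw(np.ones((3, 400))))


class TestLMI:
    @staticmethod
    def _sessions(rng, rates, dur=240.0):
        spikes, speeds = {}, {}
        n = int(dur * FPS)
        for key, r in rates.items():
            spikes[key] = np.sort(rng.uniform(0, dur, rng.poisson(r * dur)))
            speeds[key] = np.full(n, 1.0)     # always quiescent
        return spikes, speeds

    def test_missing_session_named(self, rng):
        spikes, speeds = self._sessions(rng, {"light1": 5, "dark": 5})
        with pytest.raises(ValueError, match="light2"):
            sensory.luminance_modulation_index(spikes, speeds)

    def test_identical_rates_zero_index(self, rng):
        spikes, speeds = self._sessions(
            rng, {"light1": 5, "dark": 5, "light2": 5})
        res = sensory.luminance_modulation_index(spikes, speeds, seed=0)
        assert abs(res.index) < 0.2
        assert res.direction == "none"

    def test_dark_double_rate_positive_third(self):
        rng = np.random.default_rng(7)
        spikes, speeds = self._sessions(
            rng, {"light1": 5, "dark": 10, "light2": 5}, dur=600.0)
        res = sensory.luminance_modulation_index(spikes, speeds, seed=0)
        assert res.gate_passed
        assert res.index == pytest.approx(1 / 3, abs=0.06)
        assert res.direction == "activated"

    def test_unstable_light_sessions_gated(self, rng):
        spikes, speeds = self._sessions(
            rng, {"light1": 2, "dark": 2, "light2": 12}, dur=600.0)
        res = sensory.luminance_modulation_index(spikes, speeds, seed=0)
        assert not res.gate_passed
        assert res.direction == "none"

    def test_power_and_size(self, rng):
        detected_gain = detected_null = 0
        for k in range(8):
            spikes, speeds = self._sessions(
                rng, {"light1": 4, "dark": 10, "light2": 4}, dur=400.0)
            res = sensory.luminance_modulation_index(spikes, speeds, seed=k)
            detected_gain += res.direction != "none"
            spikes, speeds = self._sessions(
                rng, {"light1": 4, "dark": 4, "light2": 4}, dur=400.0)
            res = sensory.luminance_modulation_index(spikes, speeds, seed=k)
            detected_null += res.direction != "none"
        assert detected_gain >= 7
        assert detected_null <= 2


class TestQuiescenceWindows:
    def test_windows_avoid_fast_epochs(self):
        speed = np.full(4800, 1.0)
        speed[1200:2400] = 20.0
        starts, w = sensory.quiescence_windows(speed)
        assert w == 240
        for s in starts:
            assert (speed[s:s + w] <= 5.0).all()

    def test_windows_non_overlapping(self):
        starts, w = sensory.quiescence_windows(np.full(4800, 0.0))
        assert (np.diff(starts) >= w).all()


class TestNNDecoder:
    def test_train_equals_test_perfect(self, rng):
        X = rng.normal(size=(50, 12))
        lab = rng.integers(0, 2, 50)
        pred = sensory._nn_predict(X, lab, X)
        assert np.array_equal(pred, lab)

    def test_affine_invariance(self, rng):
        train = rng.normal(size=(40, 15))
        test = rng.normal(size=(30, 15))
        lab = rng.integers(0, 2, 40)
        base = sensory._nn_predict(train, lab, test)
        scaled = sensory._nn_predict(train, lab, 3.5 * test + 2.0)
        assert np.array_equal(base, scaled)

    def test_zero_variance_test_vector_skipped(self, rng):
        train = rng.normal(size=(10, 5))
        lab = np.zeros(10, int)
        test = np.vstack([np.full(5, 2.0), rng.normal(size=5)])
        pred = sensory._nn_predict(train, lab, test)
        assert pred[0] == -1 and pred[1] == 0

    def test_sound_gain_cells_decodable(self, rng):
        dur = 240.0
        ev = synth.gen_stimulus_session(duration_s=dur, seed=3)
        state_on = np.zeros(int(dur * FPS), bool)
        for onset in ev.onsets:
            a, b = int(onset * FPS), int((onset + ev.duration_s) * FPS)
            state_on[a:b] = True
        trains = []
        for u in range(25):
            base = rng.uniform(2.0, 10.0)
            gain = 3.0 if u % 2 == 0 else 0.3   # mixed up/down modulation
            p = np.where(state_on, base * gain, base) / FPS
            fires = rng.random(p.size) < p
            trains.append(np.flatnonzero(fires) / FPS)
        acc, null = sensory.nn_decode_sound(trains, ev, dur, n_cells=20,
                                            n_runs=5, n_shuffle=60, seed=0)
        assert acc > np.percentile(null, 97.5)

    def test_luminance_state_decodable(self, rng):
        dur = 180.0
        trains = {}
        for key, dark in (("light1", False), ("dark", True),
                          ("light2", False)):
            sess = []
            for u in range(25):
                base = rng.uniform(2.0, 10.0)
                gain = (3.0 if u % 2 == 0 else 0.3) if dark else 1.0
                n = rng.poisson(base * gain * dur)
                sess.append(np.sort(rng.uniform(0, dur, n)))
            trains[key] = sess
        durations = {k: dur for k in trains}
        acc, null = sensory.nn_decode_luminance(trains, durations,
                                                n_cells=20, n_runs=5,
                                                n_shuffle=60, seed=0)
        # test frames are all "light": a working decoder beats the null
        assert acc > np.percentile(null, 97.5)

    def test_label_randomized_within_null_band(self, rng):
        dur = 240.0
        ev = synth.gen_stimulus_session(duration_s=dur, seed=5)
        trains = [np.sort(rng.uniform(0, dur, 1200)) for _ in range(25)]
        acc, null = sensory.nn_decode_sound(trains, ev, dur, n_cells=20,
                                            n_runs=5, n_shuffle=60, seed=0)
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo <= acc <= hi
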