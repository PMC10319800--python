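import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter1d
from scipy.stats import poisson

from ethophys import connectivity as conn
from ethophys import synth


class TestClassifyRsFs:
    @staticmethod
    def _metadata(n=40, seed=0):
        cfg = synth.SynthConfig(duration_s=5.0, n_units=n, seed=seed,
                                fs_fraction=0.35)
        from ethophys.synth import _unit_metadata
        return _unit_metadata(cfg)

    def test_separated_clusters_fully_recovered(self):
        meta = self._metadata()
        labels = conn.classify_rs_fs(meta)
        assert (labels == meta["true_type"].to_numpy()).all()

    def test_duplicated_rows_same_label(self):
        meta = self._metadata(20)
        dup = pd.concat([meta, meta], ignore_index=True)
        labels = conn.classify_rs_fs(dup)
        assert (labels[:20] == labels[20:]).all()

    def test_feature_order_invariance(self):
        meta = self._metadata(30)
        a = conn.classify_rs_fs(meta, features=conn.WAVEFORM_FEATURES)
        b = conn.classify_rs_fs(meta, features=conn.WAVEFORM_FEATURES[::-1])
        assert (a == b).all()

    def test_needs_two_units(self):
        with pytest.raises(ValueError):
            conn.classify_rs_fs(self._metadata(1))


class TestCCG:
    def test_autocorrelogram_center(self, rng):
        train = np.sort(rng.uniform(0, 100, 500))
        ccg = conn.compute_ccg(train, train)
        center = conn.N_LAG_BINS // 2
        assert ccg.counts[center] >= train.size   # self-pairs at zero lag

    def test_direction_symmetry(self, rng):
        a = np.sort(rng.uniform(0, 60, 300))
        b = np.sort(rng.uniform(0, 60, 400))
        ab = conn.compute_ccg(a, b)
        ba = conn.compute_ccg(b, a)
        assert np.array_equal(ab.counts, ba.counts[::-1])

    def test_poisson_pair_mean_count(self):
        dets = []
        for seed in range(10):
            pre, post = synth.gen_coupled_pair(5.0, 2.0, 0.0, "exc", 600.0,
                                               seed=seed)
            ccg = conn.compute_ccg(pre, post)
            lam = pre.size * post.size * 0.0004 / 600.0
            dets.append(ccg.counts.mean() - lam)
        n_bins_total = 101 * 10
        lam0 = 5 * 5 * 0.0004 * 600
        se = np.sqrt(lam0 / n_bins_total)
        assert abs(np.mean(dets)) < 3 * se

    def test_total_count_matches_brute_force(self, rng):
        a = np.sort(rng.uniform(0, 5, 40))
        b = np.sort(rng.uniform(0, 5, 50))
        ccg = conn.compute_ccg(a, b)
        half_bin = 0.0002
        brute = sum(1 for ta in a for tb in b
                    if -0.0202 + 1e-12 < tb - ta <= 0.0202 - 1e-12)
        # edge effects only at exact half-bin boundaries (measure-zero)
        assert ccg.counts.sum() == brute

    def test_empty_train_flagged(self):
        with pytest.warns(UserWarning, match="empty"):
            ccg = conn.compute_ccg([], [1.0, 2.0])
        assert ccg.counts.sum() == 0


class TestBaseline:
    def test_hollow_zero_is_plain_gaussian(self, rng):
        counts = rng.poisson(20, 101).astype(float)
        base = conn.hollowed_gaussian_baseline(counts, hollow=0.0)
        ref = gaussian_filter1d(counts, 25.0, mode="mirror", truncate=4.0)
        assert np.allclose(base, ref, rtol=1e-6, atol=1e-6)

    def test_baseline_preserves_flat_level(self):
        base = conn.hollowed_gaussian_baseline(np.full(101, 12.0))
        assert np.allclose(base, 12.0)

    def test_poisson_tail_matches_scipy_asymptotics(self):
        for n, lam in [(30, 10.0), (5, 20.0), (100, 80.0)]:
            up, lo = conn._poisson_tails(n, lam)
            # continuity-corrected tails sit between the two exact tails
            assert poisson.sf(n, lam) <= up <= poisson.sf(n - 2, lam)
            assert poisson.cdf(n - 1, lam) <= lo <= poisson.cdf(n + 1, lam)


class TestDetection:
    def test_excitatory_pair_detected(self):
        pre, post = synth.gen_coupled_pair(5.0, 2.0, 0.1, "exc", 600.0, seed=3)
        ccg = conn.compute_ccg(pre, post, 0, 1)
        c = conn.detect_connection(ccg, {0: "RS", 1: "RS"})
        assert c is not None
        assert c.kind == "excitatory"
        assert 1.6 <= c.lag_ms <= 4.0
        assert c.pre == 0

    def test_inhibitory_pair_detected(self):
        pre, post = synth.gen_coupled_pair(10.0, 2.8, 0.9, "inh", 600.0,
                                           seed=5, post_rate_hz=40.0)
        ccg = conn.compute_ccg(pre, post, 0, 1)
        c = conn.detect_connection(ccg, {0: "FS", 1: "RS"})
        assert c is not None and c.kind == "inhibitory"

    def test_physiology_veto(self):
        pre, post = synth.gen_coupled_pair(5.0, 2.0, 0.2, "exc", 600.0, seed=3)
        ccg = conn.compute_ccg(pre, post, 0, 1)
        c = conn.detect_connection(ccg, {0: "FS", 1: "RS"})
        assert c is None or c.kind != "excitatory"

    def test_common_input_near_zero_lag(self, rng):
        # shared drive: both units get coincident spikes at +-0.8 ms of a
        # common event train
        dur = 600.0
        events = np.sort(rng.uniform(0, dur, 3000))
        a = np.sort(np.concatenate([rng.uniform(0, dur, 2000), events]))
        b = np.sort(np.concatenate([
            rng.uniform(0, dur, 2000),
            events + rng.normal(0.0008, 0.0002, events.size)]))
        ccg = conn.compute_ccg(a, b, 0, 1)
        c = conn.detect_connection(ccg, {0: "RS", 1: "RS"})
        assert c is not None
        assert c.kind == "common_input"
        assert c.lag_ms < 1.6

    def test_reverse_direction_found(self):
        pre, post = synth.gen_coupled_pair(5.0, 2.0, 0.1, "exc", 600.0, seed=8)
        # feed the trains swapped: the connection shows at negative lags
        ccg = conn.compute_ccg(post, pre, 7, 3)
        c = conn.detect_connection(ccg, {3: "RS", 7: "RS"})
        assert c is not None
        assert c.kind == "excitatory"
        assert c.pre == 3 and c.post == 7


class TestSynapticStrength:
    def test_closed_form(self):
        counts = np.full(101, 20.0)
        counts[55] = 120.0
        ccg = conn.CCG(counts=counts, lags_ms=(np.arange(101) - 50) * 0.4,
                       pre=0, post=1, n_pre=1000, n_post=5000)
        baseline = np.full(101, 20.0)
        ss = conn.synaptic_strength(ccg, baseline, 55)
        assert ss == pytest.approx(0.1)

    def test_peak_equals_baseline_zero(self):
        counts = np.full(101, 20.0)
        ccg = conn.CCG(counts=counts, lags_ms=(np.arange(101) - 50) * 0.4,
                       pre=0, post=1, n_pre=500, n_post=500)
        assert conn.synaptic_strength(ccg, np.full(101, 20.0), 10) == 0.0

    def test_monotone_in_transmission_probability(self):
        means = []
        for p in (0.05, 0.1, 0.2):
            ss = []
            for seed in range(5):
                pre, post = synth.gen_coupled_pair(5.0, 2.0, p, "exc", 600.0,
                                                   seed=seed)
                ccg = conn.compute_ccg(pre, post, 0, 1)
                ss.append(conn.synaptic_strength(ccg))
            means.append(np.mean(ss))
        assert means[0] < means[1] < means[2]


class TestFunctionalLabels:
    def test_dominant_score_wins(self):
        scores = {0: {"speed": 0.5, "back_pitch": 0.1},
                  1: {"speed": -0.2, "back_pitch": -0.1}}
        df, vecs = conn.functional_labels(scores)
        assert df.set_index("unit").loc[0, "label"] == "speed"
        assert df.set_index("unit").loc[1, "label"] == "unclassified"

    def test_groups_follow_covariate_kind(self):
        scores = {0: {"d_back_pitch": 0.4}, 1: {"neck_elevation": 0.4}}
        df, _ = conn.functional_labels(scores)
        by = df.set_index("unit")
        assert by.loc[0, "group"] == "movement"
        assert by.loc[1, "group"] == "posture"

    def test_self_distance_zero(self):
        scores = {0: {"speed": 0.5, "back_pitch": 0.1}}
        _, vecs = conn.functional_labels(scores)
        assert conn.functional_distance(vecs[0], vecs[0]) == 0.0


class TestCategoryNull:
    @staticmethod
    def _units(groups, rs_fs, seed=0):
        rng = np.random.default_rng(seed)
        n = len(groups)
        return pd.DataFrame({
            "unit": np.arange(n), "group": groups, "rs_fs": rs_fs,
            "ap_mm": rng.uniform(-6, -4, n),
            "ml_mm": rng.uniform(2, 3, n),
            "dv_mm": rng.uniform(0, 2, n)})

    def test_single_group_concentrates_null(self):
        units = self._units(["movement"] * 10, ["RS"] * 10)
        cons = [conn.Connection(0, 1, "excitatory", 2.0, 0.1, 1e-9),
                conn.Connection(2, 3, "excitatory", 2.4, 0.1, 1e-9)]
        obs, null, p = conn.category_shuffle_null(cons, units, n=200, seed=0)
        cats = list(conn.CONNECTION_CATEGORIES)
        mm = cats.index("movement->movement")
        assert obs[mm] == 2
        assert (null[:, mm] == 2).all()
        assert all(null[:, j].sum() == 0 for j in range(len(cats)) if j != mm)

    def test_overrepresented_category_small_p(self):
        groups = ["movement"] * 5 + ["posture"] * 15
        units = self._units(groups, ["RS"] * 20)
        cons = [conn.Connection(i, 10 + i, "excitatory", 2.0, 0.1, 1e-9)
                for i in range(5)]     # all movement->posture
        obs, null, p = conn.category_shuffle_null(cons, units, n=400, seed=1)
        assert p["movement->posture"] < 0.05

    def test_impossible_constraint_reported(self):
        units = self._units(["movement"] * 4, ["RS"] * 4)
        cons = [conn.Connection(0, 1, "inhibitory", 2.0, 0.1, 1e-9)]
        with pytest.raises(ValueError, match="inh"):
            conn.category_shuffle_null(cons, units, n=10, seed=0)
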