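"""Sensory modulation indices and nearest-neighbor population decoding.

Sound responsiveness: peri-event time histograms (PETHs) in 50 ms bins
over +-10 s around white-noise onsets; the sound modulation index (SMI)
contrasts the 500-1000 ms post-onset window with the 500-1000 ms
pre-onset baseline, tested trialwise with a Wilcoxon signed-rank test.
Luminance responsiveness: quiescence windows (<= 2 s, speed <= 5 cm/s)
matched in number across light1/dark/light2 sessions; the luminance
modulation index (LMI) contrasts dark with light1, gated on light1 vs
light2 showing no rate difference. Population decoding of the stimulus
or luminance state uses a nearest-neighbor rule on Pearson correlations
between 10 Hz Gaussian-smoothed ensemble vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import wilcoxon

__all__ = [
    "PETH",
    "ModulationResult",
    "compute_peth",
    "sound_modulation_index",
    "luminance_modulation_index",
    "quiescence_windows",
    "nn_decode_sound",
    "nn_decode_luminance",
]

PETH_BIN_S = 0.05
PETH_HALF_WINDOW_S = 10.0
PETH_SMOOTH_SD_BINS = 3.0


@dataclass
class PETH:
    rates: np.ndarray            # (n_trials, 400) smoothed rates, spk/s
    raw: np.ndarray              # unsmoothed rates
    times: np.ndarray            # bin centers relative to onset, s
    onsets: np.ndarray

    @property
    def trial_average(self):
        return self.rates.mean(axis=0)


@dataclass
class ModulationResult:
    index: float                 # in [-1, 1]
    p_value: float
    direction: str               # activated / suppressed / none
    kind: str                    # SMI or LMI
    gate_passed: bool = True


def compute_peth(spike_times, events, *, bin_s=PETH_BIN_S,
                 half_window_s=PETH_HALF_WINDOW_S,
                 smooth_sd_bins=PETH_SMOOTH_SD_BINS):
    """Trial x time PETH around event onsets, Gaussian-smoothed in time."""
    st = np.sort(np.asarray(spike_times, dtype=float))
    n_bins = int(round(2 * half_window_s / bin_s))
    edges = np.linspace(-half_window_s, half_window_s, n_bins + 1)
    keep = []
    for onset in events.onsets:
        if onset - half_window_s < 0 or onset + half_window_s > events.session_duration_s:
            warnings.warn("event too close to the session edge; trial dropped")
            continue
        keep.append(onset)
    if not keep:
        raise ValueError("no event lies fully inside the session window")
    raw = np.empty((len(keep), n_bins))
    for i, onset in enumerate(keep):
        counts, _ = np.histogram(st - onset, edges)
        raw[i] = counts / bin_s
    rates = gaussian_filter1d(raw, smooth_sd_bins, axis=1, mode="nearest")
    times = 0.5 * (edges[:-1] + edges[1:])
    return PETH(rates=rates, raw=raw, times=times, onsets=np.asarray(keep))


def _window_rates(peth, t0, t1):
    """Per-trial mean raw rate in [t0, t1)."""
    sel = (peth.times >= t0) & (peth.times < t1)
    return peth.raw[:, sel].mean(axis=1)


def _index_and_test(a, b, kind):
    """(mean(a) - mean(b)) / (mean(a) + mean(b)) with trialwise Wilcoxon."""
    ma, mb = float(np.mean(a)), float(np.mean(b))
    if ma + mb == 0:
        return ModulationResult(index=float("nan"), p_value=1.0,
                                direction="none", kind=kind)
    idx = (ma - mb) / (ma + mb)
    d = np.asarray(a, float) - np.asarray(b, float)
    if np.allclose(d, 0):
        p = 1.0
    else:
        p = float(wilcoxon(d, zero_method="wilcox").pvalue)
    direction = "none"
    if p < 0.05:
        direction = "activated" if idx > 0 else "suppressed"
    return ModulationResult(index=float(idx), p_value=p, direction=direction,
                            kind=kind)


def sound_modulation_index(peth, *, min_trials=5):
    """SMI: (sound - baseline) / (sound + baseline).

    sound = 500-1000 ms after onset, baseline = 1000-500 ms before onset,
    both from raw per-trial window rates; significance from the paired
    trialwise Wilcoxon signed-rank test (p < .05).
    """
    if peth.raw.shape[0] < min_trials:
        raise ValueError(f"need >= {min_trials} trials")
    sound = _window_rates(peth, 0.5, 1.0)
    base = _window_rates(peth, -1.0, -0.5)
    return _index_and_test(sound, base, "SMI")


def quiescence_windows(speed, *, fps=120.0, window_s=2.0, speed_max=5.0):
    """Non-overlapping <=2 s spans with speed <= 5 cm/s, greedy in time."""
    speed = np.asarray(speed, dtype=float)
    w = int(round(window_s * fps))
    ok = speed <= speed_max
    ok &= np.isfinite(speed)
    starts = []
    t = 0
    T = speed.size
    while t + w <= T:
        if ok[t:t + w].all():
            starts.append(t)
            t += w
        else:
            t += 1
    return np.asarray(starts, dtype=int), w


def _window_counts(spike_times, starts, w, fps):
    frames = np.floor(np.asarray(spike_times, float) * fps).astype(int)
    out = np.empty(starts.size)
    frames.sort()
    for i, s in enumerate(starts):
        out[i] = np.searchsorted(frames, s + w) - np.searchsorted(frames, s)
    return out / (w / fps)


def luminance_modulation_index(unit_spikes, speeds, *, fps=120.0, seed=0,
                               min_windows=5):
    """LMI: (dark - light1) / (dark + light1) over matched quiescence windows.

    ``unit_spikes`` and ``speeds`` are dicts with keys light1/dark/light2.
    Window counts are matched by subsampling to the scarcest session. The
    index is gated on light1 vs light2 showing no difference (p > 0.05).
    """
    for key in ("light1", "dark", "light2"):
        if key not in unit_spikes or key not in speeds:
            raise ValueError(f"missing session {key!r}")
    rng = np.random.default_rng(seed)
    wins = {}
    for key in ("light1", "dark", "light2"):
        starts, w = quiescence_windows(speeds[key], fps=fps)
        if starts.size < min_windows:
            raise ValueError(f"session {key!r} has {starts.size} quiescence "
                             f"windows; need >= {min_windows}")
        wins[key] = (starts, w)
    n = min(w[0].size for w in wins.values())
    rates = {}
    for key, (starts, w) in wins.items():
        sel = np.sort(rng.choice(starts.size, n, replace=False))
        rates[key] = _window_counts(unit_spikes[key], starts[sel], w, fps)

    gate = _index_and_test(rates["light1"], rates["light2"], "gate")
    res = _index_and_test(rates["dark"], rates["light1"], "LMI")
    if gate.p_value <= 0.05:
        return ModulationResult(index=res.index, p_value=res.p_value,
                                direction="none", kind="LMI",
                                gate_passed=False)
    return res


# ---------------------------------------------------------------------------
# nearest-neighbor ensemble decoding

def _ensemble_matrix(spike_trains, duration_s, *, hz=10.0, smooth_sd_bins=1.0):
    """(n_frames, n_cells) smoothed 10 Hz rate matrix."""
    n = int(np.floor(duration_s * hz))
    M = np.empty((n, len(spike_trains)))
    for i, st in enumerate(spike_trains):
        idx = np.floor(np.asarray(st, float) * hz).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        M[:, i] = gaussian_filter1d(
            np.bincount(idx, minlength=n).astype(float), smooth_sd_bins,
            mode="nearest")
    return M


def _nn_predict(train_X, train_lab, test_X):
    """Label of the max-Pearson training vector for each test vector.

    Ties resolve to the earliest training index; zero-variance test
    vectors are skipped (returned as -1).
    """
    tr = train_X - train_X.mean(axis=1, keepdims=True)
    tr_norm = np.linalg.norm(tr, axis=1)
    good_tr = tr_norm > 0
    tr = tr[good_tr]
    tr /= tr_norm[good_tr][:, None]
    lab = train_lab[good_tr]
    te = test_X - test_X.mean(axis=1, keepdims=True)
    te_norm = np.linalg.norm(te, axis=1)
    pred = np.full(test_X.shape[0], -1)
    ok = te_norm > 0
    corr = (te[ok] / te_norm[ok][:, None]) @ tr.T
    pred[ok] = lab[np.argmax(corr, axis=1)]
    return pred


def nn_decode_sound(spike_trains, events, duration_s, *, n_cells=20,
                    n_runs=100, n_shuffle=1000, seed=0, hz=10.0):
    """3-fold nearest-neighbor decoding of sound on/off.

    Returns (accuracy, null_accuracies): mean over ``n_runs`` random cell
    subsamples; the null shuffles the subsampled spike trains of the first
    run with circular time shifts.
    """
    from .tuning import draw_shifts

    rng = np.random.default_rng(seed)
    n = int(np.floor(duration_s * hz))
    t = np.arange(n) / hz
    state = np.zeros(n, dtype=int)
    for onset in events.onsets:
        state[(t >= onset) & (t < onset + events.duration_s)] = 1

    M_all = _ensemble_matrix(spike_trains, duration_s, hz=hz)
    n_avail = M_all.shape[1]
    if n_avail < n_cells:
        raise ValueError(f"need {n_cells} cells, have {n_avail}")

    folds = np.array_split(np.arange(n), 3)

    def run_accuracy(M):
        correct = 0
        for k in range(3):
            test = folds[k]
            train = np.concatenate([folds[j] for j in range(3) if j != k])
            pred = _nn_predict(M[train], state[train], M[test])
            correct += np.sum(pred == state[test])
        return correct / n

    accs = np.empty(n_runs)
    first_cells = None
    for r in range(n_runs):
        cells = rng.choice(n_avail, n_cells, replace=False)
        if first_cells is None:
            first_cells = cells
        accs[r] = run_accuracy(M_all[:, cells])

    null = np.empty(n_shuffle)
    sub = [np.asarray(spike_trains[c], float) for c in first_cells]
    for s in range(n_shuffle):
        shifts = draw_shifts(rng, len(sub), duration_s)
        shifted = [np.mod(st + sh, duration_s) for st, sh in zip(sub, shifts)]
        null[s] = run_accuracy(_ensemble_matrix(shifted, duration_s, hz=hz))
    return float(accs.mean()), null


def nn_decode_luminance(spike_trains_by_session, durations, *, n_cells=20,
                        n_runs=100, n_shuffle=1000, seed=0, hz=10.0):
    """Nearest-neighbor light-vs-dark decoding across sessions.

    Training = last quarter of light1 + first quarter of dark; test =
    second half of light2 (scored as "light"). The null permutes ensemble
    vectors across the training set (shifting spike trains cannot remove a
    session-wide rate difference).
    """
    rng = np.random.default_rng(seed)
    mats = {k: _ensemble_matrix(spike_trains_by_session[k], durations[k], hz=hz)
            for k in ("light1", "dark", "light2")}
    n_avail = mats["light1"].shape[1]
    if n_avail < n_cells:
        raise ValueError(f"need {n_cells} cells, have {n_avail}")

    l1 = mats["light1"]
    dk = mats["dark"]
    l2 = mats["light2"]
    train_X_full = np.vstack([l1[-(l1.shape[0] // 4):],
                              dk[:dk.shape[0] // 4]])
    train_lab = np.concatenate([np.zeros(l1.shape[0] // 4, int),
                                np.ones(dk.shape[0] // 4, int)])
    test_X_full = l2[l2.shape[0] // 2:]
    true_label = 0   # light

    accs = np.empty(n_runs)
    first = None
    for r in range(n_runs):
        cells = rng.choice(n_avail, n_cells, replace=False)
        if first is None:
            first = cells
        pred = _nn_predict(train_X_full[:, cells], train_lab,
                           test_X_full[:, cells])
        accs[r] = np.mean(pred == true_label)

    null = np.empty(n_shuffle)
    trX = train_X_full[:, first]
    teX = test_X_full[:, first]
    for s in range(n_shuffle):
        perm = rng.permutation(train_lab.size)
        pred = _nn_predict(trX[perm], train_lab, teX)
        null[s] = np.mean(pred == true_label)
    return float(accs.mean()), null
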