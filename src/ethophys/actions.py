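"""Action encoding and decoding over an ethogram labeling.

A unit *encodes* an action when its rate inside the action is an extreme
of a 1000-fold circular time-shift null at a Bonferroni-corrected level,
and, directionally consistently, in both halves (even vs odd frames
within the action) at the 2.5/97.5 percent level. Population decoding is
a naive Bayes classifier over 400 ms windows (50 bins of 8.33 ms): per
cell an independent binomial likelihood on binarized bin counts, with a
categorical prior taken from action occupancies of other sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tuning import draw_shifts

__all__ = [
    "ActionRateProfile",
    "action_rate_profile",
    "classify_action_encoding",
    "NaiveBayesActionDecoder",
    "DecodeResult",
    "decode_actions",
    "transition_matrix",
]


@dataclass
class ActionRateProfile:
    """Per-action occupancies and rates for one unit."""

    actions: np.ndarray
    occupancy_s: np.ndarray
    counts: np.ndarray
    rate: np.ndarray                 # spk/s
    half_rates: np.ndarray           # (n_actions, 2): even/odd frame halves


def _frame_counts(spike_times, n_frames, fps):
    idx = np.floor(np.asarray(spike_times, dtype=float) * fps).astype(int)
    idx = idx[(idx >= 0) & (idx < n_frames)]
    return idx


def _half_masks(labels, actions):
    """Even/odd frame parity within each action's own frame sequence."""
    T = labels.size
    order = np.zeros(T, dtype=np.int64)
    for a in actions:
        m = labels == a
        order[m] = np.arange(m.sum())
    return order % 2 == 0


def action_rate_profile(spike_times, labels, fps=120.0):
    labels = np.asarray(labels)
    actions = np.unique(labels[labels >= 0])
    occ_frames = np.array([(labels == a).sum() for a in actions], dtype=float)
    even = _half_masks(labels, actions)
    frames = _frame_counts(spike_times, labels.size, fps)
    counts = np.array([np.sum(labels[frames] == a) for a in actions], float)
    half = np.empty((actions.size, 2))
    for j, a in enumerate(actions):
        sel = labels[frames] == a
        e = even[frames][sel]
        occ_e = (even & (labels == a)).sum() / fps
        occ_o = (~even & (labels == a)).sum() / fps
        half[j, 0] = e.sum() / occ_e if occ_e > 0 else np.nan
        half[j, 1] = (~e).sum() / occ_o if occ_o > 0 else np.nan
    occ = occ_frames / fps
    return ActionRateProfile(actions=actions, occupancy_s=occ, counts=counts,
                             rate=counts / occ, half_rates=half)


def classify_action_encoding(spike_times, labels, *, fps=120.0, n_shuffle=1000,
                             seed=0, alpha=0.01, duration_s=None):
    """Set of actions a unit encodes, against a circular-shift null.

    Criterion (i): the full-session rate in the action lies outside the
    two-sided ``alpha``-level empirical null, Bonferroni-corrected by the
    number of actions tested. Criterion (ii): both within-action halves
    lie outside the 2.5/97.5 percent envelope, on the matching side.
    Returns a DataFrame (action, rate, direction, encoded).
    """
    labels = np.asarray(labels)
    if duration_s is None:
        duration_s = labels.size / fps
    prof = action_rate_profile(spike_times, labels, fps)
    actions = prof.actions
    K = actions.size
    if K == 0:
        return pd.DataFrame(columns=["action", "rate", "direction", "encoded"])
    even = _half_masks(labels, actions)

    act_idx = np.full(labels.size, -1)
    for j, a in enumerate(actions):
        act_idx[labels == a] = j
    occ = prof.occupancy_s
    occ_e = np.array([(even & (labels == a)).sum() / fps for a in actions])
    occ_o = np.array([(~even & (labels == a)).sum() / fps for a in actions])

    rng = np.random.default_rng(seed)
    shifts = draw_shifts(rng, n_shuffle, duration_s)
    null = np.empty((n_shuffle, K))
    null_e = np.empty((n_shuffle, K))
    null_o = np.empty((n_shuffle, K))
    st = np.asarray(spike_times, dtype=float)
    for i, sh in enumerate(shifts):
        frames = _frame_counts(np.mod(st + sh, duration_s), labels.size, fps)
        ai = act_idx[frames]
        sel = ai >= 0
        c = np.bincount(ai[sel], minlength=K)
        null[i] = c / occ
        ce = np.bincount(ai[sel & even[frames]], minlength=K)
        with np.errstate(invalid="ignore", divide="ignore"):
            null_e[i] = np.where(occ_e > 0, ce / occ_e, np.nan)
            null_o[i] = np.where(occ_o > 0, (c - ce) / occ_o, np.nan)

    tail = 100.0 * alpha / (2.0 * K)       # Bonferroni-corrected, per side
    lo = np.nanpercentile(null, tail, axis=0)
    hi = np.nanpercentile(null, 100.0 - tail, axis=0)
    lo_e = np.nanpercentile(null_e, 2.5, axis=0)
    hi_e = np.nanpercentile(null_e, 97.5, axis=0)
    lo_o = np.nanpercentile(null_o, 2.5, axis=0)
    hi_o = np.nanpercentile(null_o, 97.5, axis=0)

    rows = []
    for j, a in enumerate(actions):
        r = prof.rate[j]
        he, ho = prof.half_rates[j]
        up = r > hi[j] and he > hi_e[j] and ho > hi_o[j]
        down = r < lo[j] and he < lo_e[j] and ho < lo_o[j]
        direction = "activated" if up else ("suppressed" if down else "none")
        rows.append({"action": int(a), "rate": r, "direction": direction,
                     "encoded": bool(up or down)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# naive Bayes decoding

@dataclass
class DecodeResult:
    actions: np.ndarray
    accuracy: np.ndarray             # per action
    confusion: np.ndarray            # (n_actions, n_actions) true x decoded
    baseline_accuracy: np.ndarray    # prior-only decoder, per action
    prior: np.ndarray
    flags: list = field(default_factory=list)

    @property
    def mean_accuracy(self):
        return float(np.mean(self.accuracy))

    @property
    def mean_baseline(self):
        return float(np.mean(self.baseline_accuracy))

    def summary(self):
        lines = [f"Naive Bayes action decoding: {self.actions.size} actions, "
                 f"mean accuracy {self.mean_accuracy:.3f} "
                 f"(prior-only {self.mean_baseline:.3f})"]
        for a, acc, b in zip(self.actions, self.accuracy,
                             self.baseline_accuracy):
            lines.append(f"  action {a}: {acc:.2f} (prior {b:.2f})")
        return "\n".join(lines)


class NaiveBayesActionDecoder:
    """Binomial naive Bayes over binarized 8.33 ms spike-count windows."""

    def __init__(self, *, fps=120.0, min_occupancy_s=16.0, sample_bins=50,
                 n_samples=20, min_cells=10):
        self.fps = fps
        self.min_occupancy_s = min_occupancy_s
        self.sample_bins = sample_bins
        self.n_samples = n_samples
        self.min_cells = min_cells

    def run(self, spike_trains, labels, *, prior_occupancies=None, seed=0,
            duration_s=None):
        """Hold out ``n_samples`` windows per eligible action and decode.

        ``prior_occupancies``: list of {action: seconds} dicts from other
        sessions that set the categorical prior; defaults to the training
        occupancy (flagged) when absent.
        """
        if len(spike_trains) < self.min_cells:
            raise ValueError(
                f"need more than {self.min_cells} simultaneously recorded "
                f"cells, got {len(spike_trains)}")
        labels = np.asarray(labels)
        T = labels.size
        fps = self.fps
        rng = np.random.default_rng(seed)
        flags = []

        Y = np.zeros((len(spike_trains), T), dtype=np.int8)
        for i, st in enumerate(spike_trains):
            Y[i, _frame_counts(st, T, fps)] = 1

        ids, counts = np.unique(labels[labels >= 0], return_counts=True)
        occ = counts / fps
        eligible = ids[occ > self.min_occupancy_s]
        if eligible.size == 0:
            raise ValueError("no action exceeds the occupancy floor")

        # held-out windows: contiguous 50-bin spans inside bouts >= 400 ms
        test_windows = {}
        test_mask = np.zeros(T, dtype=bool)
        w = self.sample_bins
        for a in eligible:
            bouts = _bouts(labels, a)
            starts = [s for s, e in bouts for s in range(s, e - w + 1)]
            if not starts:
                flags.append(f"action {a}: no bout of >= {w} bins; skipped")
                continue
            chosen = []
            starts = np.array(starts)
            rng.shuffle(starts)
            for s in starts:
                if len(chosen) >= self.n_samples:
                    break
                if not test_mask[s:s + w].any():
                    chosen.append(s)
                    test_mask[s:s + w] = True
            if len(chosen) < self.n_samples:
                flags.append(f"action {a}: only {len(chosen)} held-out samples")
            test_windows[a] = chosen
        eligible = np.array(sorted(test_windows))
        K = eligible.size

        train = ~test_mask
        p_hat = np.empty((len(spike_trains), K))
        for j, a in enumerate(eligible):
            m = train & (labels == a)
            nb = m.sum()
            if nb == 0:
                p_hat[:, j] = 0.5
                flags.append(f"action {a}: no training bins")
                continue
            p = Y[:, m].mean(axis=1)
            floor = 1.0 / (2.0 * nb)
            p_hat[:, j] = np.clip(p, floor, 1.0 - floor)

        if prior_occupancies:
            prior = np.zeros(K)
            for occ_table in prior_occupancies:
                for j, a in enumerate(eligible):
                    prior[j] += occ_table.get(int(a), 0.0)
            if prior.sum() == 0:
                flags.append("prior sessions lack these actions; uniform prior")
                prior = np.ones(K)
        else:
            flags.append("no prior sessions given; training occupancy used")
            prior = np.array([(train & (labels == a)).sum() for a in eligible],
                             dtype=float)
        prior = prior / prior.sum()
        log_prior = np.log(np.maximum(prior, 1e-300))

        logp = np.log(p_hat)
        log1mp = np.log1p(-p_hat)
        confusion = np.zeros((K, K), dtype=int)
        base_correct = np.zeros(K)
        n_per = np.zeros(K)
        prior_argmax = int(np.argmax(prior))
        for j, a in enumerate(eligible):
            for s in test_windows[a]:
                k = Y[:, s:s + w].sum(axis=1)        # active bins per cell
                score = log_prior + (k @ logp) + ((w - k) @ log1mp)
                confusion[j, int(np.argmax(score))] += 1
                base_correct[j] += (prior_argmax == j)
                n_per[j] += 1
        acc = np.where(n_per > 0, np.diag(confusion) / np.maximum(n_per, 1), np.nan)
        base = np.where(n_per > 0, base_correct / np.maximum(n_per, 1), np.nan)
        return DecodeResult(actions=eligible, accuracy=acc, confusion=confusion,
                            baseline_accuracy=base, prior=prior, flags=flags)


def decode_actions(spike_trains, labels, *, prior_occupancies=None, seed=0,
                   **kwargs):
    """Functional wrapper around :class:`NaiveBayesActionDecoder`."""
    dec = NaiveBayesActionDecoder(**kwargs)
    return dec.run(spike_trains, labels, prior_occupancies=prior_occupancies,
                   seed=seed)


# ---------------------------------------------------------------------------

def _bouts(labels, action):
    """(start, end) frame spans of contiguous runs of ``action``."""
    m = np.asarray(labels) == action
    d = np.diff(np.concatenate(([0], m.view(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def transition_matrix(labels):
    """Bout-level action transition probabilities (self-transitions excluded).

    Returns (actions, P) with P row-stochastic where defined.
    """
    labels = np.asarray(labels)
    seq = labels[np.concatenate(([True], np.diff(labels) != 0))]
    seq = seq[seq >= 0]
    actions = np.unique(seq)
    K = actions.size
    if K == 1:
        warnings.warn("single action; degenerate 1x1 transition matrix")
        return actions, np.ones((1, 1))
    index = {a: i for i, a in enumerate(actions)}
    P = np.zeros((K, K))
    for a, b in zip(seq[:-1], seq[1:]):
        if a != b:
            P[index[a], index[b]] += 1
    sums = P.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        P = np.where(sums > 0, P / sums, np.nan)
    return actions, P
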