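"""Tuning curves over behavioral covariates with shift-shuffle nulls.

Rate maps are spike counts divided by occupancy per covariate bin, masked
at a 400 ms occupancy floor and smoothed with a Gaussian of one bin s.d.
whose kernel is truncated and renormalized at invalid bins so smoothing
never bleeds across unoccupied regions. Significance machinery is the
field-standard circular time-shift shuffle: the spike train is rotated by
a uniform draw from +-[15, 60] s (preserving rate and ISI structure) and
the statistic of interest recomputed, 1000 times by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "TuningCurve",
    "ShuffleBand",
    "BIN_RULES",
    "bin_edges",
    "tuning_curve",
    "rate_map_2d",
    "shift_shuffle",
    "skaggs_information",
    "stability_test",
    "spikes_to_frames",
    "circular_shift",
]

MIN_OCCUPANCY_S = 0.4

#: covariate name -> (rule, bin size); "angular" uses degrees,
#: "movement" uses 36 equal bins over an occupancy-trimmed range
BIN_RULES = {
    "allo_head_pitch": ("angular", 5.0),
    "allo_head_azimuth": ("angular", 5.0),
    "allo_head_roll": ("angular", 5.0),
    "ego_head_pitch": ("angular", 5.0),
    "ego_head_azimuth": ("angular", 5.0),
    "ego_head_roll": ("angular", 5.0),
    "back_pitch": ("angular", 2.5),
    "back_azimuth": ("angular", 2.5),
    "body_direction": ("angular", 5.0),
    "neck_elevation": ("linear", 1.0),
    "speed": ("movement", 36),
    "d_allo_head_pitch": ("movement", 36),
    "d_allo_head_azimuth": ("movement", 36),
    "d_allo_head_roll": ("movement", 36),
    "d_ego_head_pitch": ("movement", 36),
    "d_ego_head_azimuth": ("movement", 36),
    "d_ego_head_roll": ("movement", 36),
    "d_back_pitch": ("movement", 36),
    "d_back_azimuth": ("movement", 36),
    "d_neck_elevation": ("movement", 36),
    "position": ("position", 6.67),
    "self_motion": ("self_motion", 3.0),
}


@dataclass
class TuningCurve:
    covariate: str
    edges: np.ndarray
    occupancy: np.ndarray        # seconds per bin
    counts: np.ndarray
    rate: np.ndarray             # spk/s, NaN on invalid bins
    smoothed: np.ndarray
    valid: np.ndarray

    @property
    def centers(self):
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class ShuffleBand:
    """Null distributions from circular time-shift shuffles."""

    per_bin: np.ndarray          # (n_shuffle, n_bins) shuffled rates
    stats: dict                  # statistic name -> (n_shuffle,) array
    shifts: np.ndarray

    def envelope(self, level):
        """Per-bin percentile envelope (e.g. level=99)."""
        return np.nanpercentile(self.per_bin, level, axis=0)


def bin_edges(covariate, values, fps=120.0):
    """Deterministic bin edges for a named covariate.

    Angular variables use fixed-width degree bins (2.5 deg for the back,
    5 deg otherwise) covering the wrapped circle for azimuths or the
    occupied range (rounded out to whole bins) for the rest. Movement
    variables use 36 equal bins over a range trimmed until first and last
    bin hold at least 400 ms of data. Neck elevation uses 1 cm bins;
    position 6.67 cm; self-motion 3 cm/s (per axis).
    """
    if covariate not in BIN_RULES:
        raise ValueError(
            f"unknown covariate {covariate!r}; valid: {sorted(BIN_RULES)}")
    rule, size = BIN_RULES[covariate]
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to bin")

    if rule == "angular":
        if "azimuth" in covariate and "back" not in covariate or covariate == "body_direction":
            return np.arange(-180.0, 180.0 + size / 2, size)
        lo = np.floor(v.min() / size) * size
        hi = np.ceil(v.max() / size) * size
        if hi <= lo:
            hi = lo + size
        return np.arange(lo, hi + size / 2, size)
    if rule == "linear":
        lo = np.floor(v.min() / size) * size
        hi = np.ceil(v.max() / size) * size
        if hi <= lo:
            hi = lo + size
        return np.arange(lo, hi + size / 2, size)
    if rule == "movement":
        return _trimmed_equal_edges(v, int(size), fps)
    if rule in ("position", "self_motion"):
        lo = np.floor(v.min() / size) * size
        hi = np.ceil(v.max() / size) * size
        if hi <= lo:
            hi = lo + size
        return np.arange(lo, hi + size / 2, size)
    raise AssertionError(rule)


def _trimmed_equal_edges(v, n_bins, fps, min_occ=MIN_OCCUPANCY_S):
    """36 equal bins, range trimmed so terminal bins hold >= 400 ms."""
    min_count = int(np.ceil(min_occ * fps))
    vs = np.sort(v)
    # pre-trim: the terminal bins cannot satisfy the floor unless at least
    # min_count points sit at or beyond each edge's side
    lo = float(vs[min(min_count - 1, vs.size - 1)] if vs.size > min_count
               else vs[0])
    hi = float(vs[max(vs.size - min_count, 0)] if vs.size > min_count
               else vs[-1])
    lo, hi = min(lo, hi), max(lo, hi)
    for _ in range(500):
        if hi <= lo:
            break
        edges = np.linspace(lo, hi, n_bins + 1)
        counts, _ = np.histogram(v, edges)
        ok_lo = counts[0] >= min_count
        ok_hi = counts[-1] >= min_count
        if ok_lo and ok_hi:
            return edges
        width = edges[1] - edges[0]
        if not ok_lo:
            lo += width * 0.5
        if not ok_hi:
            hi -= width * 0.5
    return np.linspace(lo, hi, n_bins + 1)


def spikes_to_frames(spike_times, n_frames, fps=120.0):
    """Spike times -> frame indices, clipped to the session."""
    idx = np.floor(np.asarray(spike_times) * fps).astype(int)
    return idx[(idx >= 0) & (idx < n_frames)]


def circular_shift(spike_times, shift_s, duration_s):
    """Circularly time-shift a spike train within [0, duration)."""
    return np.sort(np.mod(np.asarray(spike_times) + shift_s, duration_s))


def _masked_smooth(rate, valid, sigma=1.0):
    """Gaussian smoothing restricted to valid bins (renormalized kernel)."""
    filled = np.where(valid, rate, 0.0)
    num = gaussian_filter1d(filled, sigma, mode="constant")
    den = gaussian_filter1d(valid.astype(float), sigma, mode="constant")
    out = np.full(rate.shape, np.nan)
    nz = valid & (den > 0)
    out[nz] = num[nz] / den[nz]
    return out


def tuning_curve(spike_times, feature, edges, fps=120.0, covariate=""):
    """Occupancy-normalized, occupancy-masked, smoothed rate map."""
    feature = np.asarray(feature, dtype=float)
    binidx = np.digitize(feature, edges) - 1
    in_range = (binidx >= 0) & (binidx < len(edges) - 1) & np.isfinite(feature)
    n_bins = len(edges) - 1
    occ_counts = np.bincount(binidx[in_range], minlength=n_bins)
    occupancy = occ_counts / fps
    if occupancy.sum() == 0:
        raise ValueError("zero total occupancy in the requested range")

    frames = spikes_to_frames(spike_times, feature.size, fps)
    frames = frames[in_range[frames]]
    counts = np.bincount(binidx[frames], minlength=n_bins)

    valid = occupancy >= MIN_OCCUPANCY_S
    rate = np.full(n_bins, np.nan)
    rate[valid] = counts[valid] / occupancy[valid]
    smoothed = _masked_smooth(rate, valid)
    return TuningCurve(covariate=covariate, edges=np.asarray(edges),
                       occupancy=occupancy, counts=counts, rate=rate,
                       smoothed=smoothed, valid=valid)


def rate_map_2d(spike_times, x, y, edges_x, edges_y, fps=120.0):
    """Occupancy-masked 2D rate map (position or self-motion)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fin = np.isfinite(x) & np.isfinite(y)
    occ, _, _ = np.histogram2d(x[fin], y[fin], [edges_x, edges_y])
    occ /= fps
    frames = spikes_to_frames(spike_times, x.size, fps)
    frames = frames[fin[frames]]
    cnt, _, _ = np.histogram2d(x[frames], y[frames], [edges_x, edges_y])
    valid = occ >= MIN_OCCUPANCY_S
    rate = np.full(occ.shape, np.nan)
    rate[valid] = cnt[valid] / occ[valid]
    return rate, occ, valid


def draw_shifts(rng, n, duration_s, lo=15.0, hi=60.0):
    """Uniform shifts over +-[lo, hi] s, shrunk if the session is short."""
    import warnings
    if duration_s / 2 < hi:
        hi_eff = max(duration_s / 2, lo + 1e-9)
        if hi_eff < hi:
            warnings.warn("session shorter than max shift; range shrunk")
        hi = hi_eff
        lo = min(lo, hi / 2)
    mag = rng.uniform(lo, hi, n)
    sign = rng.choice([-1.0, 1.0], n)
    return mag * sign


def skaggs_information(curve):
    """Information rate per spike (bits/spike) over valid bins.

    I = sum_i p_i (lam_i / lam_bar) log2(lam_i / lam_bar), with p_i the
    occupancy share and lam_bar the occupancy-weighted mean rate. Zero for
    a constant curve and for silent cells.
    """
    occ = curve.occupancy[curve.valid]
    lam = curve.rate[curve.valid]
    if occ.size < 2:
        raise ValueError("need >= 2 valid bins")
    p = occ / occ.sum()
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return 0.0
    ratio = lam / lam_bar
    terms = np.where(ratio > 0, p * ratio * np.log2(np.maximum(ratio, 1e-300)), 0.0)
    return float(np.sum(terms))


def _even_odd_curves(spike_times, feature, edges, fps):
    T = np.asarray(feature).size
    minute_idx = (np.arange(T) // int(60 * fps))
    even = minute_idx % 2 == 0
    curves = []
    for sel in (even, ~even):
        feat = np.where(sel, feature, np.nan)
        curves.append(tuning_curve(spike_times, feat, edges, fps))
    return curves


def _stability_r(spike_times, feature, edges, fps):
    c_even, c_odd = _even_odd_curves(spike_times, feature, edges, fps)
    both = c_even.valid & c_odd.valid
    if both.sum() < 2:
        return np.nan
    a, b = c_even.rate[both], c_odd.rate[both]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def shift_shuffle(spike_times, feature, edges, *, n=1000, seed=0, fps=120.0,
                  duration_s=None, stats=("info", "stability")):
    """Circular-shift shuffle null of the tuning curve and its statistics.

    Each replicate rotates the spike train by a uniform draw from
    +-[15, 60] s (spike count conserved), recomputes the rate map, and
    evaluates the requested statistics ("info" = information per spike,
    "stability" = even/odd-minute curve correlation).
    """
    feature = np.asarray(feature, dtype=float)
    if duration_s is None:
        duration_s = feature.size / fps
    rng = np.random.default_rng(seed)
    shifts = draw_shifts(rng, n, duration_s)
    n_bins = len(edges) - 1
    per_bin = np.full((n, n_bins), np.nan)
    out_stats = {k: np.full(n, np.nan) for k in stats}

    # the feature (hence occupancy) is fixed across replicates: precompute
    binidx = np.digitize(feature, edges) - 1
    in_range = (binidx >= 0) & (binidx < n_bins) & np.isfinite(feature)
    occ = np.bincount(binidx[in_range], minlength=n_bins) / fps
    valid = occ >= MIN_OCCUPANCY_S
    p_occ = occ[valid] / occ[valid].sum() if valid.sum() >= 2 else None
    minute_idx = np.arange(feature.size) // int(60 * fps)
    halves = []
    for sel in (minute_idx % 2 == 0, minute_idx % 2 == 1):
        ir = in_range & sel
        o = np.bincount(binidx[ir], minlength=n_bins) / fps
        halves.append((sel, o, o >= MIN_OCCUPANCY_S))
    both_valid = halves[0][2] & halves[1][2]

    spike_times = np.asarray(spike_times, dtype=float)
    for i, sh in enumerate(shifts):
        shifted = np.mod(spike_times + sh, duration_s)
        frames = np.floor(shifted * fps).astype(int)
        frames = frames[(frames >= 0) & (frames < feature.size)]
        frames = frames[in_range[frames]]
        counts = np.bincount(binidx[frames], minlength=n_bins)
        rate = np.full(n_bins, np.nan)
        rate[valid] = counts[valid] / occ[valid]
        per_bin[i] = rate
        if "info" in out_stats and p_occ is not None:
            lam = rate[valid]
            lam_bar = float(np.sum(p_occ * lam))
            if lam_bar > 0:
                ratio = lam / lam_bar
                out_stats["info"][i] = float(np.sum(np.where(
                    ratio > 0, p_occ * ratio * np.log2(np.maximum(ratio, 1e-300)),
                    0.0)))
            else:
                out_stats["info"][i] = 0.0
        if "stability" in out_stats and both_valid.sum() >= 2:
            rr = []
            for sel, o, v in halves:
                c = np.bincount(binidx[frames[sel[frames]]], minlength=n_bins)
                rr.append(c[both_valid] / o[both_valid])
            a, b = rr
            if a.std() > 0 and b.std() > 0:
                out_stats["stability"][i] = float(np.corrcoef(a, b)[0, 1])
    return ShuffleBand(per_bin=per_bin, stats=out_stats, shifts=shifts)


def stability_test(spike_times, feature, edges, band, *, fps=120.0,
                   percentile=95.0):
    """Even/odd-minute tuning stability against the shuffle null.

    Returns (stable, r): stable if the even/odd Pearson correlation over
    jointly valid bins exceeds the given percentile of the shuffled
    correlations. Undefined correlations report unstable with r = NaN.
    """
    T = np.asarray(feature).size
    if T / fps < 240:
        raise ValueError("stability test needs a session of >= 4 minutes")
    r = _stability_r(spike_times, feature, edges, fps)
    null = band.stats["stability"]
    null = null[np.isfinite(null)]
    if not np.isfinite(r) or null.size == 0:
        return False, float("nan")
    thresh = np.percentile(null, percentile)
    return bool(r > thresh), r
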