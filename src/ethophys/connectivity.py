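"""Monosynaptic connection detection from spike-train cross-correlograms.

Coincidence counts in 0.4 ms bins over lags in [-20, +20] ms are compared
to a slow baseline obtained by convolving the CCG with a partially
hollowed Gaussian kernel (sd 10 ms = 25 bins, hollow fraction 60%). Bins
are tested against the baseline with a continuity-corrected Poisson tail;
a pair is called synaptic when two consecutive bins exceed the 99.9999th
(excitatory) or fall below the 0.0001th (inhibitory) percentile inside
the 1.6-4 ms monosynaptic window with no threshold crossing inside
0-1.6 ms; an extremum inside 0-1.6 ms with two passing bins is instead
labeled common input. Excitatory presynaptic units must be regular
spiking (RS) and inhibitory ones fast spiking (FS), as classified by
2-means on waveform shape features. Synaptic strength is the baseline-
subtracted extremal coincidence count normalized by the smaller of the
two spike counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "CCG",
    "Connection",
    "CCG_BIN_MS",
    "classify_rs_fs",
    "compute_ccg",
    "hollowed_gaussian_baseline",
    "detect_connection",
    "synaptic_strength",
    "functional_labels",
    "category_shuffle_null",
]

CCG_BIN_MS = 0.4
CCG_MAX_LAG_MS = 20.0
N_LAG_BINS = 101                       # centers -20 .. +20 ms
SYNAPTIC_WINDOW_MS = (1.6, 4.0)
ALPHA_TAIL = 1e-6
HOLLOW_SD_BINS = 25.0                  # 10 ms at 0.4 ms bins
HOLLOW_FRACTION = 0.6

WAVEFORM_FEATURES = ("spike_width_ms", "peak_to_trough_ratio", "fwhm_ms",
                     "end_slope")


@dataclass
class CCG:
    counts: np.ndarray                 # (101,) coincidences per lag bin
    lags_ms: np.ndarray
    pre: int
    post: int
    n_pre: int
    n_post: int


@dataclass
class Connection:
    pre: int
    post: int
    kind: str                          # excitatory / inhibitory / common_input
    lag_ms: float
    strength: float
    p_value: float
    category: str = ""


def classify_rs_fs(metadata, features=WAVEFORM_FEATURES):
    """RS/FS split by 2-means on standardized waveform shape features.

    The cluster with the smaller mean spike width is FS. Returns an array
    of "RS"/"FS" per unit (row order preserved).
    """
    from sklearn.cluster import KMeans

    X = np.column_stack([np.asarray(metadata[f], dtype=float)
                         for f in sorted(features)])
    if X.shape[0] < 2:
        raise ValueError("need at least 2 units to split RS/FS")
    Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(Xz)
    width = np.asarray(metadata["spike_width_ms"], dtype=float)
    mean_width = [width[km.labels_ == k].mean() for k in (0, 1)]
    fs_cluster = int(np.argmin(mean_width))
    return np.where(km.labels_ == fs_cluster, "FS", "RS")


def compute_ccg(pre_times, post_times, pre=0, post=1):
    """Cross-correlogram: post-spike counts at each lag relative to pre.

    Lag bins are 0.4 ms wide, centered on -20 .. +20 ms (101 bins).
    """
    pre_times = np.sort(np.asarray(pre_times, dtype=float))
    post_times = np.sort(np.asarray(post_times, dtype=float))
    lags = (np.arange(N_LAG_BINS) - N_LAG_BINS // 2) * CCG_BIN_MS * 1e-3
    counts = np.zeros(N_LAG_BINS, dtype=np.int64)
    if pre_times.size and post_times.size:
        half = CCG_BIN_MS * 1e-3 / 2
        lo_edge = lags[0] - half
        window = lags[-1] + half
        lo = np.searchsorted(post_times, pre_times + lo_edge)
        hi = np.searchsorted(post_times, pre_times + window)
        m = hi - lo
        keep = m > 0
        if keep.any():
            total = int(m[keep].sum())
            flat = (np.repeat(lo[keep], m[keep])
                    + np.arange(total)
                    - np.repeat(np.cumsum(m[keep]) - m[keep], m[keep]))
            d = post_times[flat] - np.repeat(pre_times[keep], m[keep])
            idx = np.round(d / (CCG_BIN_MS * 1e-3)).astype(int) + N_LAG_BINS // 2
            inside = (idx >= 0) & (idx < N_LAG_BINS)
            counts += np.bincount(idx[inside], minlength=N_LAG_BINS)
    else:
        warnings.warn("empty spike train; all-zero CCG")
    return CCG(counts=counts, lags_ms=lags * 1e3, pre=pre, post=post,
               n_pre=pre_times.size, n_post=post_times.size)


def hollowed_gaussian_baseline(counts, *, sd_bins=HOLLOW_SD_BINS,
                               hollow=HOLLOW_FRACTION):
    """Slow CCG baseline: convolution with a partially hollowed Gaussian.

    The kernel is a Gaussian of ``sd_bins``, its central weight multiplied
    by (1 - hollow) and the kernel renormalized; edges are handled by
    reflection. hollow = 0 reduces to plain Gaussian smoothing.
    """
    counts = np.asarray(counts, dtype=float)
    half = int(np.ceil(4 * sd_bins))
    xs = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (xs / sd_bins) ** 2)
    kern[half] *= (1.0 - hollow)
    kern /= kern.sum()
    padded = np.concatenate([counts[half:0:-1], counts, counts[-2:-half - 2:-1]])
    return np.convolve(padded, kern, mode="valid")


def _poisson_tails(n, lam):
    """Continuity-corrected Poisson tail probabilities for count n at rate lam.

    Upper: P(X >= n) ~ P(n - 0.5, lam); lower: P(X <= n) ~ Q(n + 0.5, lam),
    via the regularized incomplete gamma functions.
    """
    lam = max(float(lam), 1e-300)
    upper = special.gammainc(max(n - 0.5, 1e-12), lam)
    lower = special.gammaincc(n + 0.5, lam)
    return float(upper), float(lower)


def _passing(counts, baseline, idx, mode):
    """Indices (within idx) whose tail probability beats the 1e-6 threshold."""
    out = []
    for i in idx:
        lam = baseline[i]
        if lam <= 0:
            continue   # cannot form a Poisson rate; bin skipped
        up, lo = _poisson_tails(counts[i], lam)
        p = up if mode == "exc" else lo
        if p < ALPHA_TAIL:
            out.append(i)
    return np.asarray(out, dtype=int)


def detect_connection(ccg, rs_fs=None, *, enforce_physiology=True):
    """Classify a CCG as excitatory / inhibitory / common input / none.

    Both lag signs are tested (positive lags = pre leads). Physiological
    plausibility requires an RS presynaptic unit for excitatory and an FS
    one for inhibitory calls, when labels are supplied.
    """
    counts = ccg.counts.astype(float)
    baseline = hollowed_gaussian_baseline(counts)
    lags = ccg.lags_ms
    center = N_LAG_BINS // 2
    results = []
    for sign in (+1, -1):
        if sign > 0:
            syn = np.flatnonzero((lags >= SYNAPTIC_WINDOW_MS[0])
                                 & (lags <= SYNAPTIC_WINDOW_MS[1]))
            near = np.flatnonzero((lags > 0) & (lags < SYNAPTIC_WINDOW_MS[0]))
            pre, post = ccg.pre, ccg.post
        else:
            syn = np.flatnonzero((lags <= -SYNAPTIC_WINDOW_MS[0])
                                 & (lags >= -SYNAPTIC_WINDOW_MS[1]))
            near = np.flatnonzero((lags < 0) & (lags > -SYNAPTIC_WINDOW_MS[0]))
            pre, post = ccg.post, ccg.pre
        for mode, kind in (("exc", "excitatory"), ("inh", "inhibitory")):
            if enforce_physiology and rs_fs is not None:
                wanted = "RS" if mode == "exc" else "FS"
                if rs_fs[pre] != wanted:
                    continue
            hits = _passing(counts, baseline, syn, mode)
            near_hits = _passing(counts, baseline, near, mode)
            consec = _two_consecutive(hits)
            if consec is not None and near_hits.size == 0:
                extremal = _extremal_bin(counts, baseline, consec, mode)
                up, lo = _poisson_tails(counts[extremal], baseline[extremal])
                results.append(Connection(
                    pre=pre, post=post, kind=kind,
                    lag_ms=abs(float(lags[extremal])),
                    strength=synaptic_strength(ccg, baseline, extremal),
                    p_value=up if mode == "exc" else lo))
            else:
                # extremum inside 0-1.6 ms with two passing bins: common input
                near_consec = _two_consecutive(
                    np.sort(np.concatenate([near_hits, hits])))
                if near_hits.size and near_consec is not None:
                    zone = np.concatenate([near, syn])
                    ext = _extremal_bin(counts, baseline, zone, mode)
                    if ext in near:
                        up, lo = _poisson_tails(counts[ext], baseline[ext])
                        results.append(Connection(
                            pre=pre, post=post, kind="common_input",
                            lag_ms=abs(float(lags[ext])),
                            strength=synaptic_strength(ccg, baseline, ext),
                            p_value=up if mode == "exc" else lo))
    if not results:
        return None
    return min(results, key=lambda c: (c.p_value, c.pre))


def _two_consecutive(idx):
    """First pair of adjacent bin indices in idx, else None."""
    if idx.size < 2:
        return None
    d = np.diff(idx)
    pos = np.flatnonzero(d == 1)
    if pos.size == 0:
        return None
    return idx[pos[0]], idx[pos[0] + 1]


def _extremal_bin(counts, baseline, idx, mode):
    idx = np.asarray(idx)
    dev = counts[idx] - baseline[idx]
    return int(idx[np.argmax(dev)] if mode == "exc" else idx[np.argmin(dev)])


def synaptic_strength(ccg, baseline=None, bin_index=None):
    """|peak/trough count - baseline| / min(n_pre, n_post)."""
    if baseline is None:
        baseline = hollowed_gaussian_baseline(ccg.counts)
    if bin_index is None:
        dev = np.abs(ccg.counts - baseline)
        bin_index = int(np.argmax(dev))
    m = min(ccg.n_pre, ccg.n_post)
    if m == 0:
        raise ValueError("cannot normalize by a zero spike count")
    return float(abs(ccg.counts[bin_index] - baseline[bin_index]) / m)


# ---------------------------------------------------------------------------
# functional labels and category statistics

#: covariate -> coarse functional group used for connection categories
def _covariate_group(name):
    if name.startswith("d_") or name in ("speed", "self_motion"):
        return "movement"
    return "posture"


#: finer 11-way grouping of the behavioral covariates
COVARIATE_CATEGORY = {
    "allo_head_pitch": "allocentric head posture",
    "allo_head_azimuth": "allocentric head posture",
    "allo_head_roll": "allocentric head posture",
    "ego_head_pitch": "egocentric head posture",
    "ego_head_azimuth": "egocentric head posture",
    "ego_head_roll": "egocentric head posture",
    "back_pitch": "back posture",
    "back_azimuth": "back posture",
    "neck_elevation": "neck elevation",
    "d_allo_head_pitch": "allocentric head movement",
    "d_allo_head_azimuth": "allocentric head movement",
    "d_allo_head_roll": "allocentric head movement",
    "d_ego_head_pitch": "egocentric head movement",
    "d_ego_head_azimuth": "egocentric head movement",
    "d_ego_head_roll": "egocentric head movement",
    "d_back_pitch": "back movement",
    "d_back_azimuth": "back movement",
    "d_neck_elevation": "neck movement",
    "body_direction": "position",
    "position": "position",
    "speed": "speed-related",
    "self_motion": "speed-related",
}


def functional_labels(single_cov_scores, modulation=None):
    """Best-fit covariate, category and functional vector per unit.

    ``single_cov_scores``: {unit: {covariate: mean cross-validated LLR}}.
    ``modulation``: optional {unit: {"SMI": ModulationResult, "LMI": ...}}.
    Returns a DataFrame (unit, label, category, group, sensory) plus the
    functional vectors (covariate scores + SMI/LMI indices and p-values).
    """
    rows = []
    vectors = {}
    for unit, scores in single_cov_scores.items():
        if not scores:
            label, cat = "unclassified", "unclassified"
            vec_scores = {}
        else:
            vec_scores = dict(scores)
            best = max(scores, key=scores.get)
            if scores[best] <= 0:
                label, cat = "unclassified", "unclassified"
            else:
                label = best
                cat = COVARIATE_CATEGORY.get(best, "unclassified")
        sensory = False
        smi = lmi = float("nan")
        smi_p = lmi_p = float("nan")
        if modulation and unit in modulation:
            mods = modulation[unit]
            if "SMI" in mods:
                smi, smi_p = mods["SMI"].index, mods["SMI"].p_value
                sensory |= mods["SMI"].direction != "none"
            if "LMI" in mods:
                lmi, lmi_p = mods["LMI"].index, mods["LMI"].p_value
                sensory |= mods["LMI"].direction != "none"
        group = ("sensory" if sensory else
                 "unclassified" if label == "unclassified" else
                 _covariate_group(label))
        rows.append({"unit": unit, "label": label, "category": cat,
                     "group": group})
        vec = dict(vec_scores)
        vec.update(SMI=smi, SMI_p=smi_p, LMI=lmi, LMI_p=lmi_p)
        vectors[unit] = vec
    return pd.DataFrame(rows), vectors


def functional_distance(vec_a, vec_b):
    """Euclidean distance between two functional vectors (shared keys)."""
    keys = sorted(set(vec_a) & set(vec_b))
    a = np.array([vec_a[k] for k in keys], dtype=float)
    b = np.array([vec_b[k] for k in keys], dtype=float)
    fin = np.isfinite(a) & np.isfinite(b)
    return float(np.linalg.norm(a[fin] - b[fin]))


CONNECTION_CATEGORIES = (
    "movement->sensory", "posture->sensory", "movement->movement",
    "movement->posture", "posture->movement", "posture->posture",
)


def _pair_category(pre_group, post_group):
    if pre_group in ("movement", "posture"):
        if post_group == "sensory":
            return f"{pre_group}->sensory"
        if post_group in ("movement", "posture"):
            return f"{pre_group}->{post_group}"
    return None


def categorize_connections(connections, unit_groups):
    """Attach the 6-way functional category to each synaptic connection."""
    out = []
    for c in connections:
        if c.kind == "common_input":
            out.append(c)
            continue
        cat = _pair_category(unit_groups.get(c.pre), unit_groups.get(c.post))
        c.category = cat or ""
        out.append(c)
    return out


def category_shuffle_null(connections, units, *, n=1000, seed=0):
    """Observed 6-category counts vs constrained random re-pairings.

    ``units``: DataFrame with unit, group, rs_fs, and 3D position columns
    (ap_mm, ml_mm, dv_mm). Each replicate draws as many excitatory and
    inhibitory pairs as observed, uniformly among physiologically
    plausible pairs (RS pre for excitatory, FS pre for inhibitory) whose
    anatomical distance does not exceed the maximum observed one.
    Returns (observed counts, null count matrix, empirical p per category).
    """
    rng = np.random.default_rng(seed)
    units = pd.DataFrame(units).reset_index(drop=True)
    pos = units[["ap_mm", "ml_mm", "dv_mm"]].to_numpy(float)
    uid = units["unit"].to_numpy()
    index = {u: i for i, u in enumerate(uid)}
    groups = dict(zip(units["unit"], units["group"]))
    rs_fs = units["rs_fs"].to_numpy()

    syn = [c for c in connections if c.kind in ("excitatory", "inhibitory")]
    if not syn:
        raise ValueError("no synaptic connections to categorize")
    d_obs = [np.linalg.norm(pos[index[c.pre]] - pos[index[c.post]])
             for c in syn]
    d_max = max(d_obs)
    n_exc = sum(c.kind == "excitatory" for c in syn)
    n_inh = len(syn) - n_exc

    def count_cats(pairs):
        counts = dict.fromkeys(CONNECTION_CATEGORIES, 0)
        for pre, post in pairs:
            cat = _pair_category(groups.get(pre), groups.get(post))
            if cat:
                counts[cat] += 1
        return np.array([counts[c] for c in CONNECTION_CATEGORIES])

    observed = count_cats([(c.pre, c.post) for c in syn])

    # enumerate plausible ordered pairs per sign
    nu = len(uid)
    d2 = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    plaus = {}
    for sign, wanted in (("exc", "RS"), ("inh", "FS")):
        pre_ok = rs_fs == wanted
        cand = [(i, j) for i in range(nu) for j in range(nu)
                if i != j and pre_ok[i] and d2[i, j] <= d_max + 1e-12]
        if (sign == "exc" and n_exc > 0 and not cand) or \
           (sign == "inh" and n_inh > 0 and not cand):
            raise ValueError(
                f"no physiologically plausible {sign} pairs within the "
                f"observed anatomical distance ({d_max:.2f} mm)")
        plaus[sign] = cand

    null = np.empty((n, len(CONNECTION_CATEGORIES)), dtype=int)
    for r in range(n):
        pairs = []
        for sign, n_need in (("exc", n_exc), ("inh", n_inh)):
            if n_need == 0:
                continue
            pick = rng.integers(0, len(plaus[sign]), n_need)
            pairs.extend((uid[plaus[sign][p][0]], uid[plaus[sign][p][1]])
                         for p in pick)
        null[r] = count_cats(pairs)

    p_emp = ((null >= observed).sum(axis=0) + 1) / (n + 1)
    return observed, null, dict(zip(CONNECTION_CATEGORIES, p_emp))
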