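"""Unsupervised ethogram: wavelet features, 2D embedding, watershed actions.

Seven behavioral signals (six postural parameters plus running speed) are
detrended with cubic splines (knots every 2 s), transformed with Morlet
wavelets at 18 geometrically spaced frequencies between 0.5 and 20 Hz, and
concatenated with the z-scored smoothed signals into a 133-dimensional
feature vector per frame. Vectors are downsampled to 1 Hz for embedding:
PCA retains the leading components covering 97% of the variance, t-SNE
(Euclidean metric, perplexity 200) maps them to 2D, and a watershed
transform of the additive inverse of the Gaussian-smoothed occupancy PMF
on a 60x60 lattice defines discrete actions. New time points are labeled
by their nearest training point in the retained PC space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.interpolate import LSQUnivariateSpline
from scipy.ndimage import gaussian_filter
from skimage.segmentation import watershed

__all__ = [
    "ETHOGRAM_SIGNALS",
    "FeatureMatrix",
    "ActionMap",
    "ActionLabels",
    "wavelet_frequencies",
    "detrend_and_spectrogram",
    "build_feature_matrix",
    "embed_and_segment",
    "assign_actions",
]

#: the 7 ethogram input signals: 6 postural parameters + running speed
ETHOGRAM_SIGNALS = (
    "ego_head_pitch", "ego_head_azimuth", "ego_head_roll",
    "back_pitch", "back_azimuth", "neck_elevation", "speed",
)

#: exponential-map alternative for the 3D head-relative-to-body signals
ETHOGRAM_SIGNALS_EXPMAP = (
    "ego3_x", "ego3_y", "ego3_z",
    "back_pitch", "back_azimuth", "neck_elevation", "speed",
)

N_FREQS = 18
F_MIN, F_MAX = 0.5, 20.0


def wavelet_frequencies(n=N_FREQS, fmin=F_MIN, fmax=F_MAX):
    """Geometric (dyadically spaced) frequency grid from fmin to fmax Hz."""
    k = np.arange(n)
    return fmin * (fmax / fmin) ** (k / (n - 1))


@dataclass
class FeatureMatrix:
    values: np.ndarray           # (n, 133)
    frame_index: np.ndarray      # provenance: source 120 Hz frame per row
    session_id: np.ndarray       # provenance: source session per row
    fps: float = 120.0

    @property
    def n(self):
        return self.values.shape[0]


@dataclass
class ActionMap:
    components: np.ndarray       # (k, 133) PCA basis
    mean: np.ndarray             # (133,) feature mean removed before PCA
    n_components: int
    explained_variance_ratio: np.ndarray
    embedding: np.ndarray        # (n, 2) t-SNE coordinates of training rows
    train_pcs: np.ndarray        # (n, k) training rows in PC space
    train_labels: np.ndarray     # (n,) action id per training row
    pmf: np.ndarray              # (60, 60) smoothed occupancy PMF
    lattice_labels: np.ndarray   # (60, 60) watershed region id per cell
    bounds: tuple                # embedding bounding box (x0, x1, y0, y1)
    seed: int
    perplexity: float
    n_actions: int

    def save(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            for name in ("components", "mean", "explained_variance_ratio",
                         "embedding", "train_pcs", "train_labels", "pmf",
                         "lattice_labels"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs.update(n_components=self.n_components, seed=self.seed,
                           perplexity=self.perplexity,
                           n_actions=self.n_actions, bounds=self.bounds)

    @classmethod
    def load(cls, path):
        import h5py
        with h5py.File(path, "r") as f:
            kw = {name: f[name][...]
                  for name in ("components", "mean", "explained_variance_ratio",
                               "embedding", "train_pcs", "train_labels", "pmf",
                               "lattice_labels")}
            return cls(n_components=int(f.attrs["n_components"]),
                       seed=int(f.attrs["seed"]),
                       perplexity=float(f.attrs["perplexity"]),
                       n_actions=int(f.attrs["n_actions"]),
                       bounds=tuple(f.attrs["bounds"]), **kw)


@dataclass
class ActionLabels:
    labels: np.ndarray           # action id per 120 Hz frame (-1 = unlabeled)
    occupancy_s: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.occupancy_s:
            fps = 120.0
            ids, counts = np.unique(self.labels[self.labels >= 0],
                                    return_counts=True)
            self.occupancy_s = {int(i): float(c) / fps
                                for i, c in zip(ids, counts)}


# ---------------------------------------------------------------------------

def _spline_smooth(signal, fps, knot_hz=0.5):
    """Cubic-spline fit with equally spaced knots every 1/knot_hz seconds."""
    n = signal.size
    t = np.arange(n) / fps
    spacing = 1.0 / knot_hz
    knots = np.arange(spacing, t[-1] - spacing / 2, spacing)
    if knots.size == 0:
        return np.full(n, signal.mean())
    spl = LSQUnivariateSpline(t, signal, knots, k=3)
    return spl(t)


def detrend_and_spectrogram(signal, fps=120.0):
    """Spline detrend + Morlet sqrt-PSD, both rescaled for pooling.

    Returns ``(smoothed_z, spectrogram)`` where ``smoothed_z`` is the
    z-scored spline fit and ``spectrogram`` is (n, 18): the square root of
    the wavelet power of the residual at each frequency, centered and
    divided by the variance of the smoothed signal (floored at a machine-
    safe epsilon for constant signals).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2 * fps:
        raise ValueError("need at least 2 s of frames")
    if np.isnan(x).any():
        # mask-interpolate interior gaps; hold ends
        idx = np.arange(x.size)
        fin = np.isfinite(x)
        x = np.interp(idx, idx[fin], x[fin])
    if np.ptp(x) < 1e-10 * max(1.0, np.abs(x).max()):
        # constant signal: nothing but numerical noise to transform
        return np.zeros(x.size), np.zeros((x.size, N_FREQS))
    smooth = _spline_smooth(x, fps)
    resid = x - smooth

    freqs = wavelet_frequencies()
    wavelet = "cmor1.5-1.0"
    scales = pywt.frequency2scale(wavelet, freqs / fps)
    coef, _ = pywt.cwt(resid, scales, wavelet, sampling_period=1.0 / fps)
    power = np.sqrt(np.abs(coef).T)              # (n, 18) sqrt-PSD magnitude

    # divisor floored at a fraction of the raw-signal variance: a signal
    # whose slow component is near-constant must not blow up its wavelet
    # block (the floor only engages for near-stationary signals)
    var = max(float(np.var(smooth)), 0.05 * float(np.var(x)), 1e-12)
    spec = (power - power.mean(axis=0)) / var

    sd = smooth.std()
    smoothed_z = (smooth - smooth.mean()) / (sd if sd > 0 else 1.0)
    return smoothed_z, spec


def build_feature_matrix(feature_tables, downsample_hz=1.0, *, fps=120.0,
                         signals=ETHOGRAM_SIGNALS):
    """Pooled 133-dim wavelet feature matrix, decimated to ``downsample_hz``.

    ``feature_tables`` is one posture-feature DataFrame or a list of them
    (pooling across sessions/animals). Rows retain (session, frame)
    provenance so action labels can be propagated back to 120 Hz frames.
    """
    if not isinstance(feature_tables, (list, tuple)):
        feature_tables = [feature_tables]
    step = max(1, int(round(fps / downsample_hz)))
    rows, frames, sessions = [], [], []
    for s_id, table in enumerate(feature_tables):
        for name in signals:
            if name not in table.columns:
                raise ValueError(f"missing ethogram signal {name!r}")
        cols = []
        for name in signals:
            smoothed, spec = detrend_and_spectrogram(
                table[name].to_numpy(float), fps)
            cols.append(np.column_stack([smoothed, spec]))
        feat = np.concatenate(cols, axis=1)      # (T, 7*19) = (T, 133)
        sel = np.arange(0, feat.shape[0], step)
        rows.append(feat[sel])
        frames.append(sel)
        sessions.append(np.full(sel.size, s_id))
    values = np.concatenate(rows, axis=0)
    assert values.shape[1] == len(signals) * (1 + N_FREQS)
    return FeatureMatrix(values=values,
                         frame_index=np.concatenate(frames),
                         session_id=np.concatenate(sessions), fps=fps)


def embed_and_segment(matrix, *, perplexity=200.0, variance_target=0.97,
                      lattice=60, smooth_sigma=1.0, pad_cells=2, seed=0):
    """PCA -> t-SNE -> occupancy PMF -> watershed action map."""
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    X = matrix.values
    n = X.shape[0]
    if n < 3 * perplexity:
        new_p = max(5.0, n / 3.0 - 1.0)
        warnings.warn(f"too few rows for perplexity {perplexity}; "
                      f"using {new_p:.0f}")
        perplexity = new_p

    pca = PCA(svd_solver="full", random_state=seed)
    pcs_full = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
    k = min(k, X.shape[1])
    pcs = pcs_full[:, :k]

    tsne = TSNE(n_components=2, metric="euclidean", perplexity=perplexity,
                random_state=seed, init="pca")
    emb = tsne.fit_transform(pcs)

    x0, x1 = emb[:, 0].min(), emb[:, 0].max()
    y0, y1 = emb[:, 1].min(), emb[:, 1].max()
    # pad so no mass sits on the lattice border before smoothing
    dx = (x1 - x0) / (lattice - 2 * pad_cells)
    dy = (y1 - y0) / (lattice - 2 * pad_cells)
    x0 -= pad_cells * dx
    x1 += pad_cells * dx
    y0 -= pad_cells * dy
    y1 += pad_cells * dy
    H, xe, ye = np.histogram2d(emb[:, 0], emb[:, 1], bins=lattice,
                               range=[[x0, x1], [y0, y1]])
    pmf = gaussian_filter(H, smooth_sigma)
    pmf /= pmf.sum()

    # watershed of -pmf, 8-connected, seeded from local maxima of the pmf
    lattice_labels = watershed(-pmf, connectivity=2)
    n_actions = int(lattice_labels.max())

    ix = np.clip(np.digitize(emb[:, 0], xe) - 1, 0, lattice - 1)
    iy = np.clip(np.digitize(emb[:, 1], ye) - 1, 0, lattice - 1)
    train_labels = lattice_labels[ix, iy]

    return ActionMap(components=pca.components_[:k], mean=pca.mean_,
                     n_components=k, explained_variance_ratio=evr,
                     embedding=emb, train_pcs=pcs, train_labels=train_labels,
                     pmf=pmf, lattice_labels=lattice_labels,
                     bounds=(x0, x1, y0, y1), seed=seed,
                     perplexity=perplexity, n_actions=n_actions)


def assign_actions(features, action_map, *, fps=120.0, signals=ETHOGRAM_SIGNALS,
                   feature_matrix=None, chunk=2000):
    """Label every 120 Hz frame by its nearest training point in PC space.

    ``features`` is a posture-feature table; the full-rate (undecimated)
    wavelet features are projected onto the retained PCs and each frame
    takes the action label of the closest training row (ties break to the
    lower action id via argmin order).
    """
    if action_map.train_pcs.size == 0:
        raise ValueError("empty action map")
    if feature_matrix is None:
        feature_matrix = build_feature_matrix([features], downsample_hz=fps,
                                              fps=fps, signals=signals)
    X = feature_matrix.values
    pcs = (X - action_map.mean) @ action_map.components.T
    train = action_map.train_pcs
    train_sq = np.einsum("ij,ij->i", train, train)
    labels = np.empty(pcs.shape[0], dtype=int)
    for lo in range(0, pcs.shape[0], chunk):
        block = pcs[lo:lo + chunk]
        d2 = train_sq[None, :] - 2.0 * block @ train.T
        nearest = np.argmin(d2, axis=1)
        labels[lo:lo + chunk] = action_map.train_labels[nearest]
    return ActionLabels(labels=labels)
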