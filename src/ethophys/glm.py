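"""Bernoulli GLM on one-hot behavioral covariates with forward selection.

The spike train is binarized in 8.33 ms bins (one tracking frame); the
probability of firing in bin t is sigma(X_t' beta) where X_t concatenates
an intercept with one-hot blocks, one per behavioral covariate (15
occupancy-balanced bins for 1-D features, 10 cm cells for position, 5 cm/s
cells for planar self-motion). Models are estimated by maximizing the
Bernoulli log-likelihood with an L1 penalty (weight 1e-4, intercept
unpenalized) and compared by 10-fold blocked cross-validation: folds are
contiguous spans of time bins, candidate covariates are ranked by the mean
held-out log-likelihood ratio per test-fold spike, and a candidate enters
the model only if a one-sided Wilcoxon signed-rank test over the 10 paired
held-out log-likelihoods rejects at alpha = 0.01. Covariate contributions
are summarized by the relative log-likelihood ratio (share of the full
model's held-out gain over the intercept model lost when the covariate is
removed) and prediction quality by McFadden's pseudo-R2 averaged over
folds.

The one-hot design never materializes: each covariate is stored as a per-
frame bin code, so the linear predictor and the gradient reduce to fancy
indexing and bincount, and the Hessian to a set of diagonal blocks plus
small cross-block tables. Optimization is a damped Newton iteration with
backtracking line search; the L1 term enters through its standard smooth
surrogate (exact far below the likelihood scale at this lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

__all__ = [
    "GLM_COVARIATES",
    "DesignMatrix",
    "binarize_spikes",
    "build_design_matrix",
    "BernoulliGLM",
    "BernoulliGLMResults",
    "ForwardSelection",
    "SelectionResult",
    "forward_select",
    "single_covariate_scores",
]

#: default covariate registry: 9 postural + 9 derivatives + body direction,
#: speed, planar position and self-motion
GLM_COVARIATES = (
    "allo_head_pitch", "allo_head_azimuth", "allo_head_roll",
    "ego_head_pitch", "ego_head_azimuth", "ego_head_roll",
    "back_pitch", "back_azimuth", "neck_elevation",
    "d_allo_head_pitch", "d_allo_head_azimuth", "d_allo_head_roll",
    "d_ego_head_pitch", "d_ego_head_azimuth", "d_ego_head_roll",
    "d_back_pitch", "d_back_azimuth", "d_neck_elevation",
    "body_direction", "speed", "position", "self_motion",
)


@dataclass
class DesignMatrix:
    """Indexed one-hot design: per-covariate bin codes, -1 where missing."""

    codes: dict
    n_bins: dict
    T: int
    valid: np.ndarray            # rows where every covariate is defined

    @property
    def covariates(self):
        return tuple(self.codes)

    def block_size(self, name):
        return self.n_bins[name]


def binarize_spikes(spike_times, duration_s, fps=120.0):
    """y_t = 1 iff the unit fires at least once in frame t."""
    T = int(np.ceil(duration_s * fps))
    y = np.zeros(T, dtype=np.int8)
    idx = np.floor(np.asarray(spike_times, dtype=float) * fps).astype(int)
    idx = idx[(idx >= 0) & (idx < T)]
    if idx.size == 0:
        warnings.warn("empty spike train; y is all zeros")
    y[idx] = 1
    return y


def _quantile_codes(x, n_bins):
    fin = np.isfinite(x)
    qs = np.quantile(x[fin], np.linspace(0, 1, n_bins + 1)[1:-1])
    qs = np.unique(qs)
    codes = np.full(x.shape, -1, dtype=np.int32)
    codes[fin] = np.searchsorted(qs, x[fin], side="right")
    return codes, len(qs) + 1


def _equal_width_codes(x, n_bins):
    fin = np.isfinite(x)
    lo, hi = x[fin].min(), x[fin].max()
    codes = np.full(x.shape, -1, dtype=np.int32)
    codes[fin] = np.clip(((x[fin] - lo) / max(hi - lo, 1e-12) * n_bins).astype(int),
                         0, n_bins - 1)
    return codes, n_bins


def _grid_codes(x, y, bin_size):
    fin = np.isfinite(x) & np.isfinite(y)
    cx = np.floor(x / bin_size)
    cy = np.floor(y / bin_size)
    lox = np.nanmin(cx[fin]) if fin.any() else 0
    loy = np.nanmin(cy[fin]) if fin.any() else 0
    nx = int(np.nanmax(cx[fin]) - lox) + 1
    ny = int(np.nanmax(cy[fin]) - loy) + 1
    codes = np.full(x.shape, -1, dtype=np.int32)
    codes[fin] = ((cx[fin] - lox) * ny + (cy[fin] - loy)).astype(np.int32)
    return codes, nx * ny


def build_design_matrix(features, covariates=GLM_COVARIATES, *, n_bins_1d=15,
                        binning="quantile", position_bin_cm=10.0,
                        selfmotion_bin=5.0, joint_selfmotion=True):
    """Factorize the feature table into per-covariate one-hot bin codes.

    1-D covariates get ``n_bins_1d`` occupancy-balanced (quantile) bins by
    default, or equal-width bins with ``binning="width"``. Position and
    self-motion are joint 2-D grids (10 cm and 5 cm/s cells). Covariates
    that collapse to a single occupied bin are dropped with a warning;
    rows with any missing covariate are flagged invalid.
    """
    codes = {}
    n_bins = {}
    T = len(features)
    make_1d = _quantile_codes if binning == "quantile" else _equal_width_codes
    for name in covariates:
        if name == "position":
            c, nb = _grid_codes(features["position_x"].to_numpy(float),
                                features["position_y"].to_numpy(float),
                                position_bin_cm)
        elif name == "self_motion":
            if joint_selfmotion:
                c, nb = _grid_codes(features["self_motion_x"].to_numpy(float),
                                    features["self_motion_y"].to_numpy(float),
                                    selfmotion_bin)
            else:
                c, nb = make_1d(features["self_motion_x"].to_numpy(float),
                                n_bins_1d)
        else:
            if name not in features.columns:
                raise KeyError(f"feature table is missing covariate {name!r}")
            c, nb = make_1d(features[name].to_numpy(float), n_bins_1d)
        occupied = np.unique(c[c >= 0])
        if occupied.size <= 1:
            warnings.warn(f"covariate {name!r} occupies a single bin; dropped")
            continue
        # compress to occupied bins only (keeps blocks small for 2-D grids)
        remap = -np.ones(nb, dtype=np.int32)
        remap[occupied] = np.arange(occupied.size, dtype=np.int32)
        c = np.where(c >= 0, remap[np.clip(c, 0, nb - 1)], -1).astype(np.int32)
        codes[name] = c
        n_bins[name] = int(occupied.size)
    valid = np.ones(T, dtype=bool)
    for c in codes.values():
        valid &= c >= 0
    return DesignMatrix(codes=codes, n_bins=n_bins, T=T, valid=valid)


# ---------------------------------------------------------------------------
# model fitting

_L1_EPS = 1e-6


def _fit_packed(codes, sizes, y, lam, *, maxiter=500, tol=1e-6, warm=None):
    """L1-penalized Bernoulli-GLM fit over gathered bin-code arrays.

    The penalty lam * sum sqrt(beta^2 + eps^2) is the standard smooth L1
    surrogate (eps = 1e-6, i.e. exact to ~lam*eps, far below the
    likelihood scale), which keeps the objective twice differentiable for
    the Newton iteration; the objective is per-observation scaled so the
    gradient tolerance is scale-free. Returns (x, n_iter, converged) with
    x = [b0, beta].
    """
    Tn = y.size
    if Tn == 0:
        raise ValueError("no valid rows to fit on")
    offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    P = int(offsets[-1])
    ybar = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    if P == 0:
        # intercept-only MLE is closed form (intercept is unpenalized)
        x = np.array([np.log(ybar / (1 - ybar))])
        return x, 0, True
    lam_t = lam / Tn
    ysum = float(y.sum())
    yc = [np.bincount(c, weights=y, minlength=s)
          for c, s in zip(codes, sizes)]

    def eta_of(x):
        eta = np.full(Tn, x[0])
        beta = x[1:]
        for c, o, s in zip(codes, offsets[:-1], sizes):
            eta += beta[o:o + s][c]
        return eta

    def f_of(x, eta):
        ll = float(np.dot(y, eta)) - float(np.sum(np.logaddexp(0.0, eta)))
        root = np.sqrt(x[1:] * x[1:] + _L1_EPS * _L1_EPS)
        return -ll / Tn + lam_t * float(np.sum(root))

    x = np.zeros(1 + P)
    x[0] = np.log(ybar / (1 - ybar))
    if warm is not None and warm.size == x.size:
        x = warm.copy()

    # damped Newton: the one-hot blocks make the Hessian a set of diagonal
    # blocks plus small cross-block tables, all built with bincount
    eta = eta_of(x)
    f = f_of(x, eta)
    converged = False
    nit = 0
    for nit in range(1, maxiter + 1):
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        beta = x[1:]
        root = np.sqrt(beta * beta + _L1_EPS * _L1_EPS)
        g = np.empty(1 + P)
        g[0] = (p.sum() - ysum) / Tn
        for yk, c, o, s in zip(yc, codes, offsets[:-1], sizes):
            g[1 + o:1 + o + s] = -(yk - np.bincount(c, weights=p, minlength=s)) / Tn
        g[1:] += lam_t * beta / root
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        H = np.zeros((1 + P, 1 + P))
        H[0, 0] = w.sum() / Tn
        wsums = []
        for c, o, s in zip(codes, offsets[:-1], sizes):
            ws = np.bincount(c, weights=w, minlength=s) / Tn
            wsums.append(ws)
            H[0, 1 + o:1 + o + s] = ws
            H[1 + o:1 + o + s, 0] = ws
            H[1 + o:1 + o + s, 1 + o:1 + o + s] = np.diag(ws)
        for i in range(len(codes)):
            for j in range(i + 1, len(codes)):
                si, sj = sizes[i], sizes[j]
                cross = np.bincount(codes[i].astype(np.int64) * sj + codes[j],
                                    weights=w, minlength=si * sj)
                blk = (cross / Tn).reshape(si, sj)
                oi, oj = 1 + offsets[i], 1 + offsets[j]
                H[oi:oi + si, oj:oj + sj] = blk
                H[oj:oj + sj, oi:oi + si] = blk.T
        ridge = 1e-7 * max(H[0, 0], 1e-12)
        H[np.diag_indices_from(H)] += ridge
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = -g / max(H[0, 0], 1e-12)
        # backtracking line search
        t_step = 1.0
        for _ in range(25):
            x_new = x + t_step * step
            eta_new = eta_of(x_new)
            f_new = f_of(x_new, eta_new)
            if f_new <= f + 1e-4 * t_step * float(np.dot(g, step)):
                break
            t_step *= 0.5
        if f_new > f - 1e-15 and t_step < 1e-6:
            break
        x, eta, f = x_new, eta_new, f_new
    return x, nit, converged


class BernoulliGLMResults:
    """Fitted parameters plus log-likelihood evaluation on arbitrary rows."""

    def __init__(self, model, beta0, betas, converged, n_iter):
        self.model = model
        self.intercept = float(beta0)
        self.coefs = betas              # dict: covariate -> (N_i,) array
        self.converged = bool(converged)
        self.n_iter = int(n_iter)

    def loglik(self, rows):
        """Bernoulli log-likelihood on the given absolute row indices."""
        d = self.model.design
        y = self.model.y
        eta = np.full(rows.size, self.intercept)
        for name, b in self.coefs.items():
            eta += b[d.codes[name][rows]]
        yy = y[rows]
        # sum y*eta - log(1+exp(eta)), stable
        return float(np.sum(yy * eta) - np.sum(np.logaddexp(0.0, eta)))

    def predict(self, rows):
        d = self.model.design
        eta = np.full(rows.size, self.intercept)
        for name, b in self.coefs.items():
            eta += b[d.codes[name][rows]]
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self):
        lines = [f"BernoulliGLM: intercept {self.intercept:+.4f}, "
                 f"{len(self.coefs)} covariate blocks, "
                 f"converged={self.converged} ({self.n_iter} iter)"]
        for name, b in self.coefs.items():
            lines.append(f"  {name}: {b.size} bins, |beta|max {np.abs(b).max():.3f}")
        return "\n".join(lines)


class BernoulliGLM:
    """Bernoulli GLM over an indexed one-hot design.

    Parameters
    ----------
    y : (T,) 0/1 array
    design : DesignMatrix
    covariates : sequence of covariate names to include (the model M)
    lam : float
        L1 penalty weight on the block coefficients (intercept unpenalized),
        applied to the summed log-likelihood.
    """

    def __init__(self, y, design, covariates=(), lam=1e-4):
        self.y = np.asarray(y)
        self.design = design
        if self.y.size != design.T:
            raise ValueError("y and design length mismatch")
        self.covariates = tuple(covariates)
        for n in self.covariates:
            if n not in design.codes:
                raise KeyError(f"covariate {n!r} not in design")
        self.lam = float(lam)

    def fit(self, rows=None, *, maxiter=500, tol=1e-6, warm=None):
        d = self.design
        rows = np.flatnonzero(d.valid) if rows is None else np.asarray(rows)
        y = self.y[rows].astype(float)
        names = self.covariates
        codes = [d.codes[n][rows] for n in names]
        sizes = [d.n_bins[n] for n in names]
        x, nit, success = _fit_packed(codes, sizes, y, self.lam,
                                      maxiter=maxiter, tol=tol, warm=warm)
        offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
        P = offsets[-1]
        beta = x[1:]
        betas = {n: beta[o:o + s].copy()
                 for n, o, s in zip(names, offsets[:-1], sizes)}
        out = BernoulliGLMResults(self, x[0], betas, success, nit)
        out._raw = x
        return out


# ---------------------------------------------------------------------------
# cross-validated forward selection

@dataclass
class SelectionResult:
    """Outcome of cross-validated forward model selection for one unit."""

    selected: list
    fold_loglik: pd.DataFrame        # rows: folds; cols: model labels
    n_spikes_test: np.ndarray
    rllr: dict = field(default_factory=dict)
    pseudo_r2: float = float("nan")
    step_pvalues: list = field(default_factory=list)
    llr_trace: list = field(default_factory=list)  # step-1 score tables
    unclassified: bool = False
    flags: list = field(default_factory=list)

    def summary(self):
        lines = ["Forward selection" + (" (unclassified)" if self.unclassified
                                        else "")]
        for i, (name, p) in enumerate(zip(self.selected, self.step_pvalues)):
            r = self.rllr.get(name, float("nan"))
            lines.append(f"  {i + 1}. {name}: Wilcoxon p={p:.4g}, rLLR={r:.3f}")
        lines.append(f"  mean pseudo-R2 = {self.pseudo_r2:.4f}")
        return "\n".join(lines)


class ForwardSelection:
    """Greedy covariate selection with blocked 10-fold cross-validation."""

    def __init__(self, y, design, *, candidates=None, k_folds=10, alpha=0.01,
                 lam=1e-4, min_spikes=100):
        self.y = np.asarray(y)
        self.design = design
        self.candidates = tuple(candidates or design.covariates)
        self.k_folds = k_folds
        self.alpha = alpha
        self.lam = lam
        self.min_spikes = min_spikes

    def _prepare(self):
        d = self.design
        self._rows = np.flatnonzero(d.valid)
        self._yv = self.y[self._rows].astype(float)
        self._G = {n: d.codes[n][self._rows] for n in self.candidates}
        n = self._rows.size
        k = self.k_folds
        self._fold_bounds = [(i * n // k, (i + 1) * n // k) for i in range(k)]
        self._train_cache = {}
        self._ytrain = [np.concatenate((self._yv[:lo], self._yv[hi:]))
                        for lo, hi in self._fold_bounds]

    def _train_codes(self, name, a):
        hit = self._train_cache.get((name, a))
        if hit is None:
            lo, hi = self._fold_bounds[a]
            g = self._G[name]
            hit = np.concatenate((g[:lo], g[hi:]))
            self._train_cache[(name, a)] = hit
        return hit

    def _cv_loglik(self, covariates, warm_cache=None):
        """Held-out log-likelihood per fold for one model."""
        d = self.design
        names = tuple(covariates)
        sizes = [d.n_bins[n] for n in names]
        offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
        P = int(offsets[-1])
        out = np.empty(self.k_folds)
        warm = None if warm_cache is None else warm_cache.get(names)
        for a, (lo, hi) in enumerate(self._fold_bounds):
            codes = [self._train_codes(n, a) for n in names]
            x, _, _ = _fit_packed(codes, sizes, self._ytrain[a], self.lam,
                                  warm=warm)
            warm = x
            beta = x[1:]
            eta = np.full(hi - lo, x[0])
            for n, o, s in zip(names, offsets[:-1], sizes):
                eta += beta[o:o + s][self._G[n][lo:hi]]
            yt = self._yv[lo:hi]
            out[a] = float(np.dot(yt, eta) - np.sum(np.logaddexp(0.0, eta)))
        if warm_cache is not None and warm is not None:
            warm_cache[names] = warm
        return out

    def fit(self):
        self._prepare()
        y = self.y
        n_spk = np.array([self._yv[lo:hi].sum()
                          for lo, hi in self._fold_bounds], dtype=float)
        fold_ok = n_spk > 0
        flags = []
        if not fold_ok.all():
            flags.append(f"{(~fold_ok).sum()} folds with zero test spikes dropped")

        table = {}
        total_spikes = int(self._yv.sum())
        if total_spikes < self.min_spikes:
            res = SelectionResult(selected=[], fold_loglik=pd.DataFrame(),
                                  n_spikes_test=n_spk, unclassified=True,
                                  flags=["too few spikes"])
            return res

        warm_cache = {}
        ll0 = self._cv_loglik(())
        table["M0"] = ll0
        selected = []
        ll_current = ll0.copy()
        pvals = []
        trace = []
        while True:
            remaining = [c for c in self.candidates if c not in selected]
            if not remaining:
                break
            scores = {}
            fold_ll = {}
            for cand in remaining:
                ll = self._cv_loglik(tuple(selected + [cand]), warm_cache)
                fold_ll[cand] = ll
                with np.errstate(invalid="ignore", divide="ignore"):
                    llr = (ll - ll0) / n_spk
                scores[cand] = float(np.nanmean(llr[fold_ok]))
            trace.append(dict(scores))
            best = max(remaining, key=lambda c: scores[c])
            ll_best = fold_ll[best]
            keep = fold_ok & np.isfinite(ll_best) & np.isfinite(ll_current)
            if keep.sum() < 3:
                flags.append("too few usable folds for the Wilcoxon test")
                break
            diffs = ll_best[keep] - ll_current[keep]
            if np.allclose(diffs, 0):
                break
            p = wilcoxon(diffs, alternative="greater",
                         zero_method="wilcox").pvalue
            if p < self.alpha:
                selected.append(best)
                pvals.append(float(p))
                ll_current = ll_best
                table["+".join(selected)] = ll_best
            else:
                break

        res = SelectionResult(
            selected=selected,
            fold_loglik=pd.DataFrame(table),
            n_spikes_test=n_spk,
            step_pvalues=pvals,
            llr_trace=trace,
            unclassified=len(selected) == 0,
            flags=flags,
        )
        if selected:
            self._finalize(res, ll0)
        return res

    def _finalize(self, res, ll0):
        """rLLR per selected covariate and mean pseudo-R2 of the full model."""
        full = tuple(res.selected)
        ll_full = res.fold_loglik["+".join(res.selected)].to_numpy()
        lbar_full = ll_full.mean()
        lbar_0 = ll0.mean()
        denom = lbar_full - lbar_0
        for name in res.selected:
            if len(res.selected) == 1:
                partial = ll0
            else:
                others = tuple(c for c in full if c != name)
                partial = self._cv_loglik(others)
            if denom <= 0:
                res.rllr[name] = float("nan")
                res.flags.append("rLLR undefined: full model no better than intercept")
            else:
                res.rllr[name] = float((lbar_full - partial.mean()) / denom)
        keep = ll0 != 0
        if not keep.all():
            res.flags.append("folds with zero intercept log-likelihood dropped")
        res.pseudo_r2 = float(np.mean(1.0 - ll_full[keep] / ll0[keep]))


def forward_select(y, design, *, k_folds=10, alpha=0.01, lam=1e-4,
                   candidates=None, min_spikes=100):
    """Functional wrapper around :class:`ForwardSelection`."""
    return ForwardSelection(y, design, candidates=candidates, k_folds=k_folds,
                            alpha=alpha, lam=lam, min_spikes=min_spikes).fit()


def single_covariate_scores(y, design, *, k_folds=10, lam=1e-4,
                            candidates=None):
    """Mean held-out LLR per test-fold spike of every single-covariate model.

    The per-unit "best variable" used for functional labeling: each
    candidate is fit alone against the intercept model with the same
    blocked folds; the score is the fold-average of
    (l(M|y^a) - l(M0|y^a)) / n_spikes^a.
    """
    sel = ForwardSelection(y, design, candidates=candidates, k_folds=k_folds,
                           lam=lam)
    sel._prepare()
    n_spk = np.array([sel._yv[lo:hi].sum()
                      for lo, hi in sel._fold_bounds], dtype=float)
    ok = n_spk > 0
    ll0 = sel._cv_loglik(())
    scores = {}
    for cand in (candidates or design.covariates):
        ll = sel._cv_loglik((cand,))
        with np.errstate(invalid="ignore", divide="ignore"):
            llr = (ll - ll0) / n_spk
        scores[cand] = float(np.nanmean(llr[ok]))
    return scores
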