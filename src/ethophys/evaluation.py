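"""End-to-end recovery and calibration batteries on synthetic sessions.

Each function builds its own synthetic inputs from a seed, runs one stage
of the analysis stack, and reports recovery or calibration summaries.
They back both the validation test suite and the reproduction script, so
problem sizes are arguments with the package's standard study conditions
as defaults.
"""

from __future__ import annotations

import numpy as np

from . import actions, connectivity, ethogram, glm, popstats, synth, tuning

__all__ = [
    "worked_statistics",
    "glm_recovery",
    "glm_null_calibration",
    "connectivity_detection",
    "connectivity_false_positives",
    "ethogram_recovery",
    "decoder_gain",
    "stability_null_calibration",
]

#: 1-D covariates with well-separated signatures used for recovery cells
RECOVERY_COVARIATES = (
    "allo_head_pitch", "allo_head_roll", "back_azimuth", "neck_elevation",
    "speed", "body_direction", "allo_head_azimuth", "back_pitch",
    "d_allo_head_azimuth", "ego_head_azimuth",
)

_TUNING_CENTERS = {
    "allo_head_pitch": (-20.0, 15.0, False),
    "allo_head_roll": (10.0, 15.0, False),
    "back_azimuth": (5.0, 8.0, False),
    "neck_elevation": (10.0, 3.0, False),
    "speed": (18.0, 6.0, False),
    "body_direction": (0.0, 30.0, True),
    "allo_head_azimuth": (90.0, 30.0, True),
    "back_pitch": (5.0, 6.0, False),
    "d_allo_head_azimuth": (60.0, 40.0, False),
    "ego_head_azimuth": (-15.0, 12.0, False),
}


def worked_statistics():
    """The cohort statistics with in-text reference values."""
    chi2_stat, df, chi2_p = popstats.chi2_gof([106, 16], "uniform")
    return {
        "chi2_heterogeneous_v2l": chi2_stat,
        "chi2_df": df,
        "binom_p_a2d": popstats.binomial_one_sided(14, 18),
        "binom_p_a1": popstats.binomial_one_sided(8, 13),
        "heterogeneous_pct": 100.0 * 106 / 122,
    }


def _tuning_specs_for(n_cells, gain):
    specs = []
    for u in range(n_cells):
        cov = RECOVERY_COVARIATES[u % len(RECOVERY_COVARIATES)]
        center, width, circ = _TUNING_CENTERS[cov]
        specs.append(synth.TuningSpec(unit=u, covariate=cov, center=center,
                                      width=width, gain=gain, circular=circ))
    return specs


def glm_recovery(seed=0, *, n_cells=20, duration_s=1200.0, gain=2.5,
                 base_rate_hz=5.0):
    """Single-covariate cells: does forward selection pick the truth first?

    Returns dict with ``first_pick_rate`` (fraction of cells whose first
    selected covariate is the generating one) and per-cell detail.
    """
    specs = _tuning_specs_for(n_cells, gain)
    cfg = synth.SynthConfig(duration_s=duration_s, n_units=n_cells, seed=seed,
                            base_rate_hz=base_rate_hz, tuning_specs=specs)
    _, feats, spikes, _, _ = synth.make_session(cfg)
    design = glm.build_design_matrix(feats)
    detail = []
    hits = 0
    for u in range(n_cells):
        y = glm.binarize_spikes(spikes.spike_times[u], spikes.duration_s)
        res = glm.forward_select(y, design)
        first = res.selected[0] if res.selected else None
        truth = specs[u].covariate
        hits += first == truth
        detail.append({"unit": u, "truth": truth, "selected": res.selected,
                       "pseudo_r2": res.pseudo_r2})
    return {"first_pick_rate": hits / n_cells, "detail": detail}


def glm_null_calibration(seed=0, *, n_cells=50, duration_s=300.0,
                         base_rate_hz=5.0):
    """Untuned Bernoulli cells: fraction left unclassified by selection."""
    cfg = synth.SynthConfig(duration_s=duration_s, n_units=n_cells, seed=seed,
                            base_rate_hz=base_rate_hz)
    _, feats, spikes, _, _ = synth.make_session(cfg)
    design = glm.build_design_matrix(feats)
    unclassified = 0
    for u in range(n_cells):
        y = glm.binarize_spikes(spikes.spike_times[u], spikes.duration_s)
        res = glm.forward_select(y, design)
        unclassified += res.unclassified
    return {"unclassified_rate": unclassified / n_cells}


def connectivity_detection(seed=0, *, n_pairs=50, rate_hz=5.0, lag_ms=2.0,
                           p_trans=0.1, duration_s=600.0):
    """Excitatory coupled pairs: detection and lag-localization rates."""
    rs_fs = {0: "RS", 1: "RS"}
    detected = lag_in_window = 0
    rng = np.random.default_rng(seed)
    for k in range(n_pairs):
        pair_seed = int(rng.integers(0, 2**31 - 1))
        pre, post = synth.gen_coupled_pair(rate_hz, lag_ms, p_trans, "exc",
                                           duration_s, pair_seed)
        ccg = connectivity.compute_ccg(pre, post, 0, 1)
        c = connectivity.detect_connection(ccg, rs_fs)
        if c is not None and c.kind == "excitatory":
            detected += 1
            if 1.6 <= c.lag_ms <= 4.0:
                lag_in_window += 1
    return {"detection_rate": detected / n_pairs,
            "lag_in_window_rate": lag_in_window / n_pairs}


def connectivity_false_positives(seed=0, *, n_pairs=1000, rate_hz=5.0,
                                 duration_s=600.0):
    """Independent Poisson pairs through the full detection pipeline."""
    rs_fs = {0: "RS", 1: "RS"}
    fp = 0
    rng = np.random.default_rng(seed)
    for k in range(n_pairs):
        pair_seed = int(rng.integers(0, 2**31 - 1))
        pre, post = synth.gen_coupled_pair(rate_hz, 2.0, 0.0, "exc",
                                           duration_s, pair_seed)
        ccg = connectivity.compute_ccg(pre, post, 0, 1)
        c = connectivity.detect_connection(ccg, rs_fs)
        if c is not None and c.kind in ("excitatory", "inhibitory"):
            fp += 1
    return {"false_positives": fp, "n_pairs": n_pairs}


def ethogram_recovery(seed=0, *, duration_s=600.0, downsample_hz=2.0,
                      perplexity=100.0):
    """Two scripted regimes through the full embedding/watershed pipeline.

    Purity: each watershed action is assigned its majority ground-truth
    regime; the score is the fraction of frames whose action's majority
    regime matches their own.
    """
    cfg = synth.SynthConfig(duration_s=duration_s, seed=seed, n_units=1)
    _, feats, _, _, truth = synth.make_session(
        cfg, script=synth.two_regime_script())
    fm = ethogram.build_feature_matrix([feats], downsample_hz=downsample_hz)
    amap = ethogram.embed_and_segment(fm, perplexity=perplexity, seed=seed)
    labels = ethogram.assign_actions(feats, amap)
    reg = truth.regime
    maj = {}
    train_reg = reg[fm.frame_index]
    for a in range(1, amap.n_actions + 1):
        m = amap.train_labels == a
        if m.any():
            vals, cnt = np.unique(train_reg[m], return_counts=True)
            maj[a] = int(vals[np.argmax(cnt)])
    pred = np.array([maj.get(l, -1) for l in labels.labels])
    return {
        "n_actions": amap.n_actions,
        "purity": float(np.mean(pred == reg)),
        "pmf_total": float(amap.pmf.sum()),
    }


def decoder_gain(seed=0, *, n_units=60, n_actions=6, duration_s=600.0,
                 gain=3.0):
    """Naive Bayes decoding of scripted actions vs the prior-only baseline."""
    labels, trains, _ = synth.gen_action_tuned_ensemble(
        n_units, n_actions, duration_s, seed, gain=gain)
    res = actions.decode_actions(trains, labels, seed=seed)
    return {
        "mean_accuracy": res.mean_accuracy,
        "baseline_accuracy": res.mean_baseline,
        "gain_over_prior": res.mean_accuracy - res.mean_baseline,
        "n_actions_decoded": int(res.actions.size),
    }


def stability_null_calibration(seed=0, *, n_cells=100, duration_s=300.0,
                               rate_hz=5.0, n_shuffle=250):
    """Fraction of homogeneous Poisson cells called 'stable' (target ~5%)."""
    rng = np.random.default_rng(seed)
    cfg = synth.SynthConfig(duration_s=duration_s, seed=seed, n_units=1)
    _, feats, _, _, _ = synth.make_session(cfg)
    feature = feats["allo_head_pitch"].to_numpy()
    edges = tuning.bin_edges("allo_head_pitch", feature)
    flagged = 0
    for k in range(n_cells):
        n_spk = rng.poisson(rate_hz * duration_s)
        st = np.sort(rng.uniform(0, duration_s, n_spk))
        band = tuning.shift_shuffle(st, feature, edges, n=n_shuffle,
                                    seed=int(rng.integers(2**31 - 1)),
                                    stats=("stability",))
        stable, _ = tuning.stability_test(st, feature, edges, band)
        flagged += stable
    return {"stable_fraction": flagged / n_cells}
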