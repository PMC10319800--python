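import numpy as np
import pytest

from ethophys import glm, synth


@pytest.fixture(scope="session")
def small_session():
    """240 s default-script session with two tuned units and one untuned."""
    cfg = synth.SynthConfig(
        duration_s=240.0, n_units=3, seed=7, base_rate_hz=5.0,
        tuning_specs=[
            synth.TuningSpec(unit=0, covariate="allo_head_pitch",
                             center=-20.0, width=15.0, gain=2.5),
            synth.TuningSpec(unit=1, covariate="neck_elevation",
                             center=10.0, width=3.0, gain=2.5),
        ])
    session, feats, spikes, events, truth = synth.make_session(cfg)
    return dict(cfg=cfg, session=session, features=feats, spikes=spikes,
                events=events, truth=truth)


@pytest.fixture(scope="session")
def small_design(small_session):
    return glm.build_design_matrix(small_session["features"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
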