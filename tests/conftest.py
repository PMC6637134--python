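import numpy as np
import pytest

import vistrack as vt


@pytest.fixture(scope="session")
def short_trial():
    """A 60-frame rendered trial: locomotion at 2 px/frame, freeze at 30."""
    script = vt.freeze_script(onset_frame=30, n_frames=60, locomotion_speed=2.0, seed=5)
    return vt.render_synthetic_trial(script, seed=5)


@pytest.fixture(scope="session")
def tracked_short_trial(short_trial):
    """Speed quantiles tracked from the rendered short trial."""
    from vistrack import pipeline

    quant = pipeline.track_trial(
        short_trial.frames, short_trial.background, trial_seed=5
    )
    return quant


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
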