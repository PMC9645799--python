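import numpy as np
import pytest

import palpmetrics as pm


@pytest.fixture(scope="session")
def layout():
    return pm.default_layout()


@pytest.fixture(scope="session")
def profiles():
    return pm.default_profiles()


@pytest.fixture(scope="session")
def lp_trial(profiles, layout):
    """One standard low-performer trial with ground truth."""
    return pm.generate_trial(
        profiles["LP"], layout, seed=12345, trial_id="lp0", grs=(5, 4)
    )


@pytest.fixture(scope="session")
def lp_resampled(lp_trial):
    bundle, gt = lp_trial
    return pm.resample_to_grid(bundle, 100.0), gt


def make_bundle(channels, trial_id="t", fistula_id=1, stb=0, manual_window=None,
                grs=(6, 5)):
    """Minimal bundle from a dict of name -> (t, v)."""
    chans = {
        name: pm.ChannelSeries(name, t, v) for name, (t, v) in channels.items()
    }
    return pm.TrialBundle(
        trial_id=trial_id,
        subject_id="s",
        fistula_id=fistula_id,
        skin="thin",
        vibration="low",
        grs_palpation=grs[0],
        grs_overall=grs[1],
        stb=stb,
        channels=chans,
        manual_window=manual_window,
    )


def full_bundle(duration=20.0, rate=100.0, **overrides):
    """A complete quiet bundle on a uniform grid; channels overridable as (t, v)."""
    t = np.arange(0.0, duration, 1.0 / rate)
    z = np.zeros_like(t)
    channels = {
        "force_thumb": (t, z.copy()),
        "force_index": (t, z.copy()),
        "force_middle": (t, z.copy()),
        "finger_x": (t, z.copy()),
        "finger_y": (t, z.copy()),
        "finger_z": (t, z.copy()),
        "needle_x": (t, np.full_like(t, 150.0)),
        "needle_y": (t, z.copy()),
        "needle_z": (t, np.full_like(t, 15.0)),
        "flashback": (t, z.copy()),
    }
    channels.update(overrides)
    return make_bundle(channels)
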