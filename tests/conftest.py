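import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from vepmap.forward_model import HeadModel, make_standard_montage, leadfield
from vepmap.vep_pipeline import EvokedResponse


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def montage(head):
    return make_standard_montage(outer_radius=head.outer_radius)


@pytest.fixture(scope="session")
def single_dipole_evoked(head, montage):
    """Noiseless single-dipole evoked plus its ground truth."""
    pos = np.array([25.0, -50.0, 8.0])
    u = np.array([0.3, -0.8, 0.52])
    u = u / np.linalg.norm(u)
    times = -100 + np.arange(275) * 4.0
    moment = 25 * np.exp(-0.5 * ((times - 100) / 15) ** 2)
    gains = leadfield(head, montage, pos).gains @ u
    ev = EvokedResponse(
        data=np.outer(gains, moment),
        sfreq=250.0,
        t0_offset_ms=-100.0,
        labels=list(montage.labels),
        condition="synthetic",
        n_trials_averaged=1,
        montage=montage,
    )
    return ev, {"position": pos, "orientation": u, "moment": moment,
                "times_ms": times, "gain": gains}


@pytest.fixture(scope="session")
def slow_lr_noiseless(head, montage):
    """Noiseless slow-motion lower-right scenario through preprocessing."""
    from vepmap import vep_pipeline as vp
    from vepmap.synthetic_data import ScenarioSpec, simulate_vep_session

    scenario = ScenarioSpec(speed="slow", quadrant="LR", seed=21,
                            snr=np.inf, n_trials=3)
    raw, truth = simulate_vep_session(scenario, head, montage)
    evoked = vp.rereference(vp.lowpass(vp.baseline_average(vp.epoch(raw))))
    return evoked, truth


@pytest.fixture(scope="session")
def slow_lr_model(slow_lr_noiseless, head, montage):
    """Sequential fit of the noiseless scenario (shared by several tests)."""
    from vepmap.dipole_fit import default_windows, fit_sequential

    evoked, truth = slow_lr_noiseless
    model = fit_sequential(evoked, default_windows("slow"), head, montage,
                           seed=33)
    return model, evoked, truth
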