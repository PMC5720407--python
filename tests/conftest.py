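import numpy as np
import pytest

import matchdose as md
from matchdose import simulator


@pytest.fixture(scope="session")
def nine_knot_curve():
    """Monotone 9-point calibration: dose = 50k cGy at od = 0.2k, k=1..9."""
    return md.build_curve([(0.2 * k, 50.0 * k) for k in range(1, 10)], unit="cGy")


@pytest.fixture(scope="session")
def default_curve():
    return simulator.default_calibration_curve(match_dose=1.0)


@pytest.fixture(scope="session")
def jaw_jaw_sim():
    cfg = md.match_config("jaw-jaw", noise_sigma=0.005, seed=11)
    return md.simulate_match(cfg)


@pytest.fixture(scope="session")
def mlc45_noiseless():
    """The 45-degree match under study conditions: 0.5 cm leaves, zero
    under-leaf transmission, sigma 0.2 cm, equal weights, no noise."""
    cfg = md.match_config("jaw-mlc-45", leaf_width=0.5, leaf_transmission=0.0,
                          noise_sigma=0.0)
    return md.simulate_match(cfg)


@pytest.fixture(scope="session")
def mlc0_noiseless():
    cfg = md.match_config("jaw-mlc-0", leaf_width=0.5, noise_sigma=0.0)
    return md.simulate_match(cfg)


def analyze(img, truth, **kw):
    return md.analyze_image(img, fiducials=md.FiducialPair(*truth.fiducials), **kw)
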