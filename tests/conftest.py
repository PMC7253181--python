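import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import puffsd as P

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Camera model shared by the simulation-backed tests.
GAIN = 5.0
BLACK = 100.0
READ = 1.5
LEVELS = (20.0, 50.0, 100.0, 200.0, 400.0)


@pytest.fixture(scope="session")
def params():
    return P.FilterParams()


@pytest.fixture(scope="session")
def noise_series():
    """Uniform-intensity calibration ladder (fluorescein-style)."""
    return P.simulate_noise_series(GAIN, BLACK, READ, LEVELS,
                                   shape=(300, 96, 96), seed=101)


@pytest.fixture(scope="session")
def calibration(noise_series, params):
    return P.calibrate_noise_scale(noise_series, params)


@pytest.fixture(scope="session")
def spatial_calibration(noise_series, params):
    return P.calibrate_noise_scale(noise_series, params, mode="spatial")


@pytest.fixture(scope="session")
def flurry_recording(calibration):
    """A global rise with active puff sites, plus its SD stack and traces."""
    sites = [P.PuffSite(y=y, x=x)
             for y, x in [(14, 14), (14, 34), (24, 24), (34, 14), (34, 34), (20, 30)]]
    config = P.SyntheticConfig(shape=(1500, 48, 48), puff_sites=sites,
                               global_rise=P.GlobalRise(onset_s=2.0))
    movie, truth = P.simulate_movie(config, seed=8)
    mask = np.zeros((48, 48), dtype=bool)
    mask[8:-8, 8:-8] = True
    sd = P.temporal_sd_stack(movie, calibration=calibration)
    return {"config": config, "movie": movie, "truth": truth, "mask": mask,
            "sd": sd, "sd_trace": sd.trace(mask)}
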