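import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import myothermo as mt

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants():
    return mt.DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def reference_anoxia():
    """Packaged reference cohort means/SDs, anoxia phase."""
    return mt.load_reference_cohort("anoxia")


@pytest.fixture(scope="session")
def row0_rates():
    """Control-time (t=0) cohort-mean rate constants (f1, g1, g2)."""
    return 314.0, 199.0, 753.0


@pytest.fixture(scope="session")
def fixture_thermo_report(reference_anoxia):
    """Full thermodynamic analysis of the reference anoxia means."""
    df = reference_anoxia
    return mt.analyze_thermodynamics(
        times=df["time_min"].to_numpy(float),
        v0=df["v0_mean"].to_numpy(float),
        myosin_content=df["myosin_content_mean"].to_numpy(float),
        po=df["cb_force_mean"].to_numpy(float))


def make_hyperbola_dataset(a, b, to, n_points=9, noise_sd=0.0, rng=None,
                           **kwargs):
    """T–V dataset on an exact Hill hyperbola, optionally tension-noised."""
    ds = mt.sample_hyperbola(a, b, to, n_points=n_points)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        pts = []
        for p in ds.points:
            t = max(p.tension + rng.normal(0, noise_sd), 0.0)
            pts.append(mt.TVPoint(t, p.velocity))
        ds = mt.TVDataset(muscle_id=ds.muscle_id, phase=ds.phase,
                          time_min=ds.time_min, points=pts,
                          vmax_measured=ds.vmax_measured, **kwargs)
    return ds
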