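import numpy as np
import pandas as pd
import pytest

from skiptrack.io import ARGOS_DOPPLER, GPS, Deployment, Track


def build_track(times, lons, lats, sources=None, classes=None, bird_id="b1",
                deployment=None):
    """Assemble a Track from parallel sequences; times are hours or timestamps."""
    n = len(lons)
    if not isinstance(times[0], pd.Timestamp):
        t0 = pd.Timestamp("2022-01-01", tz="UTC")
        times = [t0 + pd.Timedelta(hours=float(h)) for h in times]
    sources = sources or [GPS] * n
    classes = classes or ["NONE" if s == GPS else "1" for s in sources]
    df = pd.DataFrame({
        "timestamp": times, "lon": lons, "lat": lats,
        "source": sources, "argos_class": classes,
        "quality_sd_km": np.nan,
    })
    return Track(bird_id, df, deployment or Deployment())


@pytest.fixture
def make_track():
    return build_track


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """20-bird hourly-GPS cohort with no measurement noise (session-cached)."""
    from skiptrack.simulate import DeviceModel, make_cohort
    return make_cohort(20, seed=7, device=DeviceModel("GPS_UHF").zero_noise())


@pytest.fixture(scope="session")
def argos_cohort():
    """Same cohort geometry sampled through a duty-cycled noisy Argos PTT."""
    from skiptrack.simulate import DeviceModel, make_cohort
    return make_cohort(20, seed=7, device=DeviceModel("ARGOS_PTT"))
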