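import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eprshape.lineshape_models import (
    LineshapeSpec,
    evaluate_lineshape,
    simulate_stretched_lorentzian,
)
from eprshape.preprocessing import ClassicalParams, extract_classical_params
from eprshape.spectra_io import Spectrum

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_model_spectrum(family, *, App=1.0, DeltaBpp=1.0, Bres=0.0, u_max=3.2,
                        n=4097):
    """Analytic Gaussian/Lorentzian derivative line on a uniform grid.

    The default grid is odd so the exact center (u = 0, F = 0) is a sample,
    and the step (6.4/4096) divides 1/2 so the extrema at u = -+1/2 are
    samples too: the grid-measured parameters are exact and stable under
    intensity rescaling.  u_max = 3.2 still pushes the Benc abscissa past 10.
    """
    spec = LineshapeSpec(family=family, App=App, DeltaBpp=DeltaBpp, Bres=Bres)
    u = np.linspace(-u_max, u_max, n)
    field = Bres + u * DeltaBpp
    return Spectrum(field=field, intensity=evaluate_lineshape(field, spec),
                    baseline_corrected=True), spec


@pytest.fixture(scope="session")
def lorentzian_line():
    """Dense noiseless Lorentzian derivative plus its exact parameters."""
    spectrum, spec = make_model_spectrum("lorentzian", App=2.0, DeltaBpp=4.0,
                                         Bres=3480.0)
    return spectrum, ClassicalParams(App=2.0, DeltaBpp=4.0, Bres=3480.0)


@pytest.fixture(scope="session")
def gaussian_line():
    spectrum, spec = make_model_spectrum("gaussian", App=2.0, DeltaBpp=4.0,
                                         Bres=3480.0)
    return spectrum, ClassicalParams(App=2.0, DeltaBpp=4.0, Bres=3480.0)


@pytest.fixture(scope="session")
def stretched_lines():
    """Simulated stretched-Lorentzian lines keyed by dimensionality."""
    out = {}
    for d in (1, 2, 3):
        s = simulate_stretched_lorentzian(
            LineshapeSpec(family="stretched", d=d), n_points=4096, x_max=12.0
        )
        out[d] = (s, extract_classical_params(s))
    return out
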