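import numpy as np
import pytest

from tvkl import AcquisitionSpec, DegradationModel, degrade, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def small_problem():
    """A 32x32 low-count blurred acquisition shared by solver tests."""
    x_true = make_phantom("piecewise_constant", (32, 32))
    spec = AcquisitionSpec(kappa=5, band=5, sigma=1.0, background=2e-3, seed=7)
    y, lambda_bar = degrade(x_true, spec)
    return {
        "x_true": x_true,
        "spec": spec,
        "y": y.astype(float),
        "lambda_bar": lambda_bar,
        "model": spec.model(x_true.shape),
    }


@pytest.fixture(scope="session")
def mid_problem():
    """A 64x64 low-count problem for discrepancy-equation contract tests."""
    x_true = make_phantom("piecewise_constant", (64, 64))
    spec = AcquisitionSpec(kappa=5, band=5, sigma=1.0, background=2e-3, seed=11)
    y, lambda_bar = degrade(x_true, spec)
    return {
        "x_true": x_true,
        "spec": spec,
        "y": y.astype(float),
        "lambda_bar": lambda_bar,
        "model": spec.model(x_true.shape),
    }
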