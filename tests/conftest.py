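import numpy as np
import pytest

from dialflux import AssayParams, DialyzerParams, FlowSetting


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def mid_flows():
    """The mid-grid flow setting used for the single-setting bench figures."""
    return FlowSetting(qb=150.0, qd_ml_h=2000.0, label="QB2QD2")


@pytest.fixture
def default_params():
    return DialyzerParams(k0a=80.0)


@pytest.fixture
def unit_assay():
    return AssayParams(extinction_coefficient=1.0)


def random_flows(rng) -> FlowSetting:
    return FlowSetting(
        qb=float(rng.uniform(20.0, 500.0)),
        qd_ml_h=float(rng.uniform(200.0, 10000.0)),
    )


def random_params(rng, symmetric=False) -> DialyzerParams:
    return DialyzerParams(
        k0a=float(rng.uniform(0.0, 1000.0)),
        sieving_membrane=float(rng.uniform(0.3, 1.0)),
        alpha_backfiltration=1.0 if symmetric else float(rng.uniform(0.2, 3.0)),
        permeability_reduction=float(rng.uniform(0.0, 0.5)),
    )
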