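"""Shared fixtures: reference parameters, assay conditions, random cycles."""
from __future__ import annotations

import numpy as np
import pytest

from vsglt.io import reference_parameters
from vsglt.transport_cycle import (
    FORWARD_TRANSITIONS, TRANSITIONS, Conditions, TransportParameters,
)


@pytest.fixture(scope="session")
def ref_params():
    """The packaged reference rate set (cycle-charge report must be clean)."""
    params, report = reference_parameters()
    assert report.ok
    return params


@pytest.fixture(scope="session")
def assay_conditions():
    """Uptake-assay bath: 73 mM Na+, 28 uM galactose outside, empty lumen."""
    return Conditions(voltage_V=0.0, na_out=0.073, na_in=0.0, gal_out=28e-6, gal_in=0.0)


def random_cycle_params(rng: np.random.Generator, with_charges: bool = True) -> TransportParameters:
    """A random irreducible five-state cycle with valid charge bookkeeping."""
    rates = {t: float(rng.uniform(0.1, 10.0)) for t in TRANSITIONS}
    if with_charges:
        eta_net = {t: float(rng.uniform(-0.4, 0.4)) for t in FORWARD_TRANSITIONS}
        # close the protein-charge cycle exactly
        eta_net["51"] = -sum(eta_net[t] for t in ("12", "23", "34", "45"))
        eps_net = {t: 0.0 for t in FORWARD_TRANSITIONS}
        eps_net["34"] = 1.0
    else:
        eta_net = {t: 0.0 for t in FORWARD_TRANSITIONS}
        eps_net = {t: 0.0 for t in FORWARD_TRANSITIONS}
        eps_net["34"] = 1.0
    return TransportParameters.from_net_charges(rates, eta_net, eps_net)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230901)
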