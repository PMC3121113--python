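"""Shared fixtures: default parameter sets and reusable reference runs."""

import pytest

from caspulse import (
    FateParameters,
    IntegratorOptions,
    KineticParameters,
    run_figure3,
)


@pytest.fixture(scope="session")
def params() -> KineticParameters:
    return KineticParameters()


@pytest.fixture(scope="session")
def fate() -> FateParameters:
    return FateParameters()


@pytest.fixture(scope="session")
def fig3(params):
    """Reference 2.0 nM / 10 h pulse run (trajectory, summary), shared read-only."""
    return run_figure3(params)


@pytest.fixture(scope="session")
def loose_options() -> IntegratorOptions:
    """Relaxed tolerances for tests that only need qualitative shape."""
    return IntegratorOptions(rtol=1e-6, atol=1e-9)
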