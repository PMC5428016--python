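"""Shared fixtures: typical parameter sets and the (expensive) fitted
replenishment law, computed once per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

from mstdesign.diffusion_reaction import sweep_and_fit_replenishment
from mstdesign.params import (
    MediumProperties,
    TissueSample,
    default_parameters,
)

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def medium() -> MediumProperties:
    return MediumProperties()


@pytest.fixture(scope="session")
def glucose():
    return default_parameters("typical", "glucose")


@pytest.fixture(scope="session")
def oxygen():
    return default_parameters("typical", "oxygen")


@pytest.fixture(scope="session")
def tissue_250() -> TissueSample:
    """250 um spheroid at the typical 1.02 g/cm^3 density."""
    return TissueSample(d=250e-6)


@pytest.fixture(scope="session")
def tissue_375() -> TissueSample:
    """The reference tissue used for depletion sweeps."""
    return TissueSample(d=375e-6)


@pytest.fixture(scope="session")
def replenishment_fit(tissue_375, glucose):
    """Linear replenishment law fitted to the default depletion sweep."""
    return sweep_and_fit_replenishment(tissue_375, glucose)
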