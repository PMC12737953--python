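"""Shared fixtures: small genomes for unit tests, full study runs for the
end-to-end checks (session-scoped so the cohort is simulated once)."""

from __future__ import annotations

import pytest

from homeoscan.config import RunConfig
from homeoscan.genome import GenomeLayout, build_marker_map
from homeoscan.pedigree import generate_pedigree
from homeoscan.scenario import run_study
from homeoscan.simulate import default_sites


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    return GenomeLayout(n_sets=2, set_length=1_000_000, markers_per_set=20)


@pytest.fixture(scope="session")
def small_marker_map(small_layout):
    return build_marker_map(small_layout, b_high_frac=0.4, seed=11)


@pytest.fixture(scope="session")
def small_pedigree():
    """18 plants: 6 founder seeds advanced three generations of SSD."""
    return generate_pedigree(n_founder_seeds=6, generations=3, seed=5)


@pytest.fixture(scope="session")
def sites(small_layout):
    """100 diagnostic sites per 1-Mb chromosome set."""
    return default_sites(small_layout, spacing=10_000, seed=0)


@pytest.fixture(scope="session")
def zero_noise_study():
    """The full study design with all stochastic array noise off."""
    return run_study(RunConfig.zero_noise(seed=1))


@pytest.fixture(scope="session")
def default_noise_study():
    """The full study design under the default noise model."""
    return run_study(RunConfig(seed=1))
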