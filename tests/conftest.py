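"""Shared fixtures: small deterministic windows and simulated replicate sets.

Simulation-backed fixtures are session-scoped and kept at modest replicate
counts so the whole suite stays quick; statistical assertions on them use
Monte Carlo standard errors at the fixture's own size.
"""

from __future__ import annotations

import numpy as np
import pytest

from hacsweep.core import HaplotypeWindow
from hacsweep.simulate import (
    ScenarioConfig,
    Selection,
    simulate_neutral,
    simulate_sweep,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20231207)


@pytest.fixture
def toy_window() -> HaplotypeWindow:
    """6 haplotypes x 5 sites, hand-checkable frequencies.

    Derived counts per site: 2, 4, 1, 3, 5 -> derived freqs
    1/3, 2/3, 1/6, 1/2, 5/6; site 3 is an exact tie.
    """
    alleles = np.array(
        [
            [1, 1, 0, 1, 1],
            [1, 1, 0, 1, 1],
            [0, 1, 0, 1, 1],
            [0, 1, 1, 0, 1],
            [0, 0, 0, 0, 1],
            [0, 0, 0, 0, 0],
        ],
        dtype=np.uint8,
    )
    return HaplotypeWindow(
        alleles=alleles,
        positions=np.arange(5, dtype=float),
        site_ids=[f"s{i}" for i in range(5)],
    )


def _random_window(rng, n=12, S=20) -> HaplotypeWindow:
    while True:
        alleles = (rng.random((n, S)) < rng.uniform(0.1, 0.9, size=S)).astype(np.uint8)
        counts = alleles.sum(axis=0)
        if np.all((counts > 0) & (counts < n)):
            return HaplotypeWindow(alleles=alleles, positions=np.arange(S, dtype=float))


@pytest.fixture
def random_window_factory(rng):
    return lambda n=12, S=20: _random_window(rng, n, S)


@pytest.fixture(scope="session")
def neutral_reps():
    """150 neutral standard-scenario replicates (n=50, Θ=223, ρ=0), wide
    enough flanks for S up to 201."""
    return simulate_neutral(ScenarioConfig(seed=424242), 150, min_flank=101)


@pytest.fixture(scope="session")
def sweep_reps():
    """150 default-selection replicates (s=0.15, f=0.75)."""
    cfg = ScenarioConfig(seed=424243, selection=Selection(s=0.15, f=0.75))
    return simulate_sweep(cfg, 150, min_flank=101)


@pytest.fixture(scope="session")
def conditioned_null_reps():
    """150 matched-null replicates: s=0 but the central allele conditioned at
    frequency 0.75 (the calibration null of the sweep test)."""
    cfg = ScenarioConfig(seed=424244, selection=Selection(s=0.0, f=0.75))
    return simulate_sweep(cfg, 150, min_flank=101)
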