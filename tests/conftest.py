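"""Shared fixtures: synthetic populations generated once per session."""

import numpy as np
import pytest

from cytocycle import synthcyto as sc
from cytocycle import preprocess as pp

MULTI_GAINS = {"dna": 100.0, "cyca2": 3.0, "cycb1": 0.2}
SINGLE_GAINS = {"dna": 80.0, "cyca2": 1.0, "cycb1": 1.0}
SPILL = [("phh3", "cyca2", 0.08)]


@pytest.fixture(scope="session")
def truth():
    return sc.TruthProfiles()


@pytest.fixture(scope="session")
def multi_noise():
    return sc.NoiseModel(n=20000, seed=3, gain=dict(MULTI_GAINS),
                         spillover=list(SPILL),
                         doublet_frac=0.03, debris_frac=0.02)


@pytest.fixture(scope="session")
def population(truth, multi_noise):
    """One multi-color stained population with contamination."""
    return sc.generate_population(truth, multi_noise)


@pytest.fixture(scope="session")
def clean_population(truth):
    """Contamination-free population, unit epitope gains, no spillover."""
    noise = sc.NoiseModel(n=20000, seed=11, gain={"dna": 100.0}, spillover=[])
    return sc.generate_population(truth, noise)


@pytest.fixture(scope="session")
def preprocessed(population):
    """Compensated, cleaned, background-subtracted multi-color table."""
    table = pp.compensate(population, SPILL)
    table = pp.exclude_debris_aggregates(table)
    table, anchor = pp.subtract_background(table)
    return table, anchor


@pytest.fixture(scope="session")
def assay_triple(truth):
    multi_noise = sc.NoiseModel(n=20000, seed=21, gain=dict(MULTI_GAINS),
                                spillover=list(SPILL),
                                doublet_frac=0.03, debris_frac=0.02)
    sa = sc.NoiseModel(n=10000, seed=22, gain=dict(SINGLE_GAINS))
    sb = sc.NoiseModel(n=10000, seed=23, gain=dict(SINGLE_GAINS))
    return sc.generate_assay_pair(truth, multi_noise, sa, sb)
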