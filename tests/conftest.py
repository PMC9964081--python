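"""Shared fixtures: tiny genotype matrices, simulated bundles, published reference rows."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clonalpop as cp
from clonalpop.genotype_io import MISSING

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


# --- published twelve-population assessment (rangewide ddRAD survey of a
#     threatened clonal mint), used as printed-value oracles -----------------
# (population, sites, N, H_E, H_O, F_IS, divergence, unique_ancestry, value)
REFERENCE_DIVERSITY = [
    ("LB1", 1, 23, 0.142, 0.125, 0.113, "Moderate", "Yes", "Moderate"),
    ("ANF1", 1, 19, 0.125, 0.106, 0.137, "Moderate", "Yes", "Moderate"),
    ("ANF2", 1, 14, 0.128, 0.127, 0.024, "Very High", "Yes", "High"),
    ("BRWMA1", 1, 10, 0.139, 0.040, 0.555, "Moderate", "No", "Low"),
    ("BRWMA2", 1, 11, 0.136, 0.139, -0.010, "Very High", "Yes", "High"),
    ("THSF1", 1, 14, 0.131, 0.081, 0.297, "Moderate", "No", "Low"),
    ("THSF2", 2, 18, 0.131, 0.130, 0.025, "High", "Yes", "High"),
    ("SJSBP1", 2, 7, 0.145, 0.090, 0.268, "Moderate", "No", "Low"),
    ("SJSBP2", 1, 12, 0.145, 0.136, 0.060, "Moderate", "Yes", "Moderate"),
    ("ANF3", 1, 18, 0.126, 0.132, -0.020, "Very High", "Yes", "High"),
    ("ANF4", 3, 34, 0.138, 0.116, 0.154, "Low", "Yes", "Moderate"),
    ("ANF5", 2, 11, 0.124, 0.044, 0.504, "Moderate", "No", "Low"),
]

# (unit, N, G, printed CR); threshold "n/a" rows had no histogram gap
REFERENCE_CLONES = [
    ("ANF1", 19, 16, 0.83),
    ("ANF2", 14, 14, 1.00),
    ("ANF3", 18, 15, 0.82),
    ("ANF4.1", 7, 5, 0.67),
    ("ANF4.2", 15, 11, 0.71),
    ("ANF4.3", 11, 11, 1.00),
    ("ANF5", 11, 1, 0.00),
    ("BRWMA1", 10, 3, 0.22),
    ("BRWMA2", 11, 8, 0.70),
    ("LB1", 23, 3, 0.09),
    ("SJSBP1", 7, 4, 0.50),
    ("SJSBP2", 12, 10, 0.82),
    ("THSF1", 14, 2, 0.08),
    ("THSF2", 18, 14, 0.76),
]

# 5 m circular plots: (N analysed, G, printed CR)
REFERENCE_PLOTS = [(28, 2, 0.04), (21, 3, 0.10)]


@pytest.fixture
def tiny_gm() -> cp.GenotypeMatrix:
    """4 samples x 3 loci with one missing call."""
    calls = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 1, 0],
            [MISSING, 1, 0],
        ]
    )
    return cp.GenotypeMatrix(["s1", "s2", "s3", "s4"], ["1:100", "1:200", "2:50"], calls)


@pytest.fixture(scope="session")
def two_pop_bundle():
    """Two diverged populations, no clonality, for structure/divergence tests."""
    cfg = cp.SimulationConfig(
        n_pops=2,
        loci=1000,
        fst_target=0.25,
        fis=0.0,
        genets_per_pop=15,
        mean_ramets=1.0,
        error_rate=0.0,
        missing_rate=0.1,
        seed=2,
    )
    return cp.simulate(cfg)


@pytest.fixture(scope="session")
def clonal_bundle():
    """One population of 8 genets with noisy, gappy ramet genotypes."""
    cfg = cp.SimulationConfig(
        n_pops=1,
        loci=2000,
        fst_target=0.0,
        fis=0.2,
        genets_per_pop=8,
        ramet_counts=[[5, 3, 2, 4, 1, 6, 2, 2]],
        error_rate=0.005,
        missing_rate=0.2,
        seed=8,
    )
    return cp.simulate(cfg)
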