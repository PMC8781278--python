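"""Shared fixtures: the 31-run study design and its transcribed run table."""

import numpy as np
import pandas as pd
import pytest

import modrsm as m

# The published 31-run experimental plan in physical units
# (S g/L, N mg/L, T degC, I CFU/mL); rows 1, 5, 14, 19, 20, 28, 30 are the
# seven center replicates.
STUDY_RUNS_PHYSICAL = [
    (225, 300, 20, 5e5),
    (150, 100, 30, 0),
    (150, 500, 10, 0),
    (150, 100, 10, 0),
    (225, 300, 20, 5e5),
    (225, 300, 30, 5e5),
    (300, 500, 10, 1e6),
    (300, 100, 10, 1e6),
    (150, 100, 30, 1e6),
    (300, 500, 30, 0),
    (300, 300, 20, 5e5),
    (225, 300, 20, 0),
    (225, 300, 10, 5e5),
    (225, 300, 20, 5e5),
    (225, 300, 20, 1e6),
    (150, 500, 30, 0),
    (150, 500, 30, 1e6),
    (150, 500, 10, 1e6),
    (225, 300, 20, 5e5),
    (225, 300, 20, 5e5),
    (300, 500, 30, 1e6),
    (150, 300, 20, 5e5),
    (300, 100, 10, 0),
    (300, 100, 30, 1e6),
    (225, 100, 20, 5e5),
    (150, 100, 10, 1e6),
    (300, 500, 10, 0),
    (225, 300, 20, 5e5),
    (300, 100, 30, 0),
    (225, 300, 20, 5e5),
    (225, 500, 20, 5e5),
]


@pytest.fixture(scope="session")
def factors():
    return m.wine_fermentation_factors()


@pytest.fixture(scope="session")
def design31():
    """Generated 31-run face-centered CCD (fixed run-order seed)."""
    return m.generate_ccd(k=4, alpha=1, n_center=7, seed=1)


@pytest.fixture(scope="session")
def study_design(factors):
    """The published run table re-encoded to coded levels."""
    coded = np.array(
        [
            [round(f.encode(v)) for f, v in zip(factors, row)]
            for row in STUDY_RUNS_PHYSICAL
        ],
        dtype=int,
    )
    return m.DesignTable(factors=factors, runs=coded)


@pytest.fixture(scope="session")
def dataset42(design31):
    """Default 5-module synthetic dataset at sigma = 0.05, seed 42."""
    return m.simulate_responses(design31, m.default_truth(0.05), seed=42)


@pytest.fixture(scope="session")
def scaled42(dataset42):
    return m.autoscale(dataset42.responses)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def make_response_matrix(arr, names, run_prefix="r"):
    arr = np.asarray(arr, dtype=float)
    idx = [f"{run_prefix}{i}" for i in range(arr.shape[0])]
    return m.ResponseMatrix(pd.DataFrame(arr, index=idx, columns=names))
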