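"""Shared fixtures: reference parameters and small simulated datasets."""

import numpy as np
import pytest

from mabpk import (
    CohortSpec,
    SAEMConfig,
    StructuralParams,
    fit_saem,
    generate_cohort,
    reference_poppk,
    simulate_trial,
)


@pytest.fixture(scope="session")
def ref_params() -> StructuralParams:
    """Published base-model population estimates (used as generative truth)."""
    return StructuralParams(CL=0.12, Vc=3.88, Q=0.30, Vp=3.60, F=0.47, ka=0.34)


@pytest.fixture(scope="session")
def ref_pop():
    return reference_poppk()


@pytest.fixture(scope="session")
def small_dataset():
    """A 26-subject simulated trial shared by estimation tests."""
    cohort = generate_cohort(CohortSpec(n_single=16, n_combination=10), seed=11)
    return simulate_trial(cohort, seed=11)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A reduced-iteration SAEM fit of the small dataset (shared, ~2 s)."""
    return fit_saem(small_dataset,
                    config=SAEMConfig(seed=21, n_explore=150, n_smooth=80,
                                      compute_rse=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
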