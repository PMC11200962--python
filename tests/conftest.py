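"""Shared fixtures: small synthetic cohorts and their encoded form."""

from __future__ import annotations

import numpy as np
import pytest

from gatedtab import (CohortSpec, PreprocessConfig, Preprocessor,
                      generate_cohort)

TINY_GROUPS = dict(basic=2, history=3, lab=3, followup=2, echo=2, angio=2)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 600-record, 14-column cohort with a single outcome."""
    spec = CohortSpec(n_records=600, group_sizes=dict(TINY_GROUPS),
                      events=["mace"])
    return generate_cohort(spec, seed=0)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    """The tiny cohort, preprocessed with default settings."""
    pre = Preprocessor(tiny_cohort.schema, PreprocessConfig())
    return pre.fit_transform(tiny_cohort.frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
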