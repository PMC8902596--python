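import numpy as np
import pandas as pd
import pytest

from mucoswab import (
    AbundanceTable,
    CohortDesign,
    SampleMetadata,
    mucosity_measured,
    pair_samples,
    simulate_cohort,
    to_relative,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default two-study cohort (28 + 16 paired animals)."""
    design = CohortDesign(seed=0)
    table, meta, truth = simulate_cohort(design)
    return design, table, meta, truth


@pytest.fixture(scope="session")
def single_study_design():
    return CohortDesign(studies=("exp1",), n_animals_per_arm=(14,), seed=0)


@pytest.fixture()
def tiny_table():
    counts = np.array([[10, 0, 5], [2, 8, 0], [4, 4, 4], [1, 1, 18]])
    return AbundanceTable(("s1", "s2", "s3", "s4"), ("gA", "gB", "gC"), counts)


@pytest.fixture()
def paired_meta():
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "animal_id": ["A", "A", "B", "B"],
                "sample_type": ["swab", "colon", "swab", "colon"],
                "treatment": ["EF", "EF", "CON", "CON"],
                "study": ["exp1"] * 4,
            }
        )
    )


def cohort_mucosity(table, meta, squared=True):
    """Measured mucosity and pairing for a simulated cohort."""
    rel = to_relative(table)
    pairs = pair_samples(meta)
    measured = mucosity_measured(rel, pairs, squared=squared)
    return rel, pairs, measured
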