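import numpy as np
import pandas as pd
import pytest

from bcproteodyn.io import OmicsMatrix, SampleAnnotation
from bcproteodyn.simulate import (CohortSimSpec, TimeCourseSimSpec,
                                  generate_cohort, generate_timecourse)

SMALL_COHORT = CohortSimSpec(
    n_cell_lines=24, n_tnbc=12, n_proteins=250, n_transcripts=300,
    n_mutations=40, n_drugs=2, n_complexes=25, n_tnbc_de=30, seed=11,
)

SMALL_TIMECOURSE = TimeCourseSimSpec(n_proteins=450, seed=11)


@pytest.fixture(scope="session")
def cohort():
    """A small simulated cohort shared across tests (read-only)."""
    return generate_cohort(SMALL_COHORT)


@pytest.fixture(scope="session")
def timecourse():
    """A small simulated perturbation time course (read-only)."""
    return generate_timecourse(SMALL_TIMECOURSE)


@pytest.fixture
def toy_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]],
        index=["F1", "F2", "F3"], columns=["S1", "S2"],
    )
    return OmicsMatrix("protein", values)


def make_annotation(sample_ids, cell_lines, groups, tnbc=None, batches=None):
    """Helper to build a valid SampleAnnotation for toy matrices."""
    n = len(sample_ids)
    tnbc = tnbc if tnbc is not None else [True] * n
    batches = batches if batches is not None else ["B1"] * n
    return SampleAnnotation(pd.DataFrame(
        {
            "cell_line": cell_lines,
            "subtype": ["basal_a" if t else "luminal" for t in tnbc],
            "tnbc": tnbc,
            "replicate_group": groups,
            "replicate_type": ["technical" if g == 4 else "biological"
                               for g in groups],
            "batch": batches,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    ))
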