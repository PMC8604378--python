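import math

import numpy as np
import pytest

from combimeta import StudyEffect, plhiv_comorbidity_studies


@pytest.fixture(scope="session")
def reference():
    """The five embedded PLHIV comorbidity datasets."""
    return plhiv_comorbidity_studies()


@pytest.fixture(scope="session")
def diabetes(reference):
    return reference["diabetes"]


@pytest.fixture
def make_studies():
    """Factory wrapping (y, variance) arrays as StudyEffect lists."""

    def factory(y, v):
        return [
            StudyEffect(study_label=f"s{i}", y=float(yi), sigma=float(math.sqrt(vi)))
            for i, (yi, vi) in enumerate(zip(np.atleast_1d(y), np.atleast_1d(v)))
        ]

    return factory
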