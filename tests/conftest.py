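import numpy as np
import pytest

from cephalarc.synthetic import (CohortSpec, TemplateConfig, generate_cohort,
                                 make_ideal_template, study_template_config,
                                 write_cohort)


@pytest.fixture(scope="session")
def ideal_template():
    """Ideal template (pogonion exactly on the mandibular plane) + ground truth."""
    return make_ideal_template(TemplateConfig())


@pytest.fixture(scope="session")
def study_template():
    """Study-like template: pogonion elevated above the mandibular plane."""
    return make_ideal_template(study_template_config())


@pytest.fixture(scope="session")
def study_cohort_dir(tmp_path_factory):
    """A 30-subject pixel-space cohort on disk (study-like template, seed 7)."""
    d = tmp_path_factory.mktemp("cohort")
    cohort = generate_cohort(CohortSpec(n=30, seed=7))
    write_cohort(cohort, d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
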