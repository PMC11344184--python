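"""Shared fixtures: the HZ study universe and small synthetic datasets."""

import numpy as np
import pytest

import vaxdce as vd
from vaxdce.design import AttributeSpec, ChoiceDesign, ChoiceTask, Profile, StudyDesignSpec


@pytest.fixture(scope="session")
def hz_spec():
    return vd.hz_study_spec()


@pytest.fixture(scope="session")
def hz_design(hz_spec):
    d = vd.build_choice_design(hz_spec, "auto", seed=12345)
    return vd.block_design(d, hz_spec.n_blocks, seed=12345, spec=hz_spec)


@pytest.fixture(scope="session")
def fixed_truth():
    """Homogeneous truth (all sds zero): data are conditional-logit distributed."""
    return vd.hz_true_parameters(heterogeneity=0.0)


@pytest.fixture(scope="session")
def cl_study(hz_spec, fixed_truth):
    """400 respondents answering under the fixed truth."""
    return vd.simulate_study(vd.SyntheticStudyConfig(
        spec=hz_spec, params=fixed_truth, n_respondents=400, seed=2024))


@pytest.fixture(scope="session")
def cl_result(cl_study):
    return vd.fit_mixed_logit(cl_study.table, vd.CONDITIONAL_LOGIT)


@pytest.fixture(scope="session")
def mini_spec():
    """One 2-level attribute: the smallest estimable universe."""
    return StudyDesignSpec((AttributeSpec("x", ("a", "b")),), n_tasks=2, n_blocks=1)


@pytest.fixture(scope="session")
def mini_design():
    tasks = (
        ChoiceTask(1, 1, (Profile((("x", "a"),)), Profile((("x", "b"),)))),
        ChoiceTask(2, 1, (Profile((("x", "b"),)), Profile((("x", "a"),)))),
    )
    return ChoiceDesign(tasks)
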