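import numpy as np
import pytest

from vfvar.noise import anchor_noise_model
from vfvar.normative import HillOfVision
from vfvar.series import VFExam, VFSeries
from vfvar.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def normative():
    return HillOfVision()


@pytest.fixture(scope="session")
def anchor_noise():
    return anchor_noise_model()


def make_series(sens_matrix, times=None, eye_id="eye", age=65.0, fp=0.05, fn=0.05):
    """Build a VFSeries from an (n_exams, 54) sensitivity matrix."""
    sens_matrix = np.asarray(sens_matrix, dtype=float)
    if times is None:
        times = np.arange(sens_matrix.shape[0], dtype=float)
    exams = [
        VFExam(time_years=float(t), sensitivities=row, fp_rate=fp, fn_rate=fn)
        for t, row in zip(times, sens_matrix)
    ]
    return VFSeries(eye_id=eye_id, baseline_age_years=age, exams=exams)


@pytest.fixture
def flat_series():
    """Six yearly exams, all locations flat at 25 dB."""
    return make_series(np.full((6, 54), 25.0))


@pytest.fixture(scope="session")
def stable_uniform_cohort(normative):
    """Stable eyes with uniform true sensitivities and anchor noise: the
    simulate-then-estimate loop's test bed (300 eyes x 15 exams over ~10 y)."""
    spec = CohortSpec(
        n_eyes=300, seed=1, truth="uniform",
        min_exams=15, extra_exams_poisson=0.0,
        min_gap_years=0.55, gap_shape=1.5, gap_scale=0.1,
        min_followup_years=3.0,
    )
    return generate_cohort(spec, normative)


@pytest.fixture(scope="session")
def progressing_cohort(normative):
    """Modeling-preset cohort with exponential-truth progression in every eye."""
    spec = CohortSpec.modeling_preset(40, seed=11, fraction_progressing=1.0)
    return generate_cohort(spec, normative)
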