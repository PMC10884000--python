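import numpy as np
import pytest

import fetalmorph as fm
from fetalmorph.atlas import estimate_atlas, filter_control_points, init_control_points
from fetalmorph.kernel import KernelConfig


@pytest.fixture(scope="session")
def template_face():
    return fm.make_template_face()


@pytest.fixture(scope="session")
def small_population():
    """Coarse synthetic population reused by atlas/score tests."""
    spec = fm.SyntheticPopulationSpec(
        n_subjects=6,
        seed=2,
        template_resolution=(16, 18),
        control_spacing_mm=20.0,
        vertex_noise_sd=0.2,
    )
    return spec, fm.sample_population(spec)


@pytest.fixture(scope="session")
def fitted_atlas(small_population):
    """A small fitted atlas (coarse meshes, few outer iterations)."""
    _, sample = small_population
    config = KernelConfig(lambda_V=10.0, lambda_W=7.0)
    cps = init_control_points(sample.meshes, 15.0)
    template, _ = fm.make_template_face(16, 18)
    model = estimate_atlas(
        sample.meshes, cps, config, template, n_outer_iters=3,
        register_opts={"maxiter": 80},
    )
    return sample, model


@pytest.fixture(scope="session")
def score_atlas():
    """A larger, registration-free atlas for score-model statistics.

    Momenta are the generator's ground truth, so the control cohort is big
    enough for stable covariance estimates without running registrations.
    """
    spec = fm.SyntheticPopulationSpec(
        n_subjects=40, seed=21, template_resolution=(16, 18), vertex_noise_sd=0.0
    )
    sample = fm.sample_population(spec)
    truth = sample.truth
    momenta = [fm.Momenta(row.reshape(-1, 3)) for row in truth.momenta]
    model = fm.AtlasModel(
        template=truth.template,
        cps=truth.cps,
        config=truth.config,
        momenta=momenta,
        subject_ids=sample.metadata["id"].tolist(),
    )
    return sample, model
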