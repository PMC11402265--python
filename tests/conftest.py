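import numpy as np
import pytest

import neckssm as ns
from neckssm.parametrization import ParametrizedNeck


@pytest.fixture(scope="session")
def straight_params():
    """A noiseless straight neck: both angles zero, default +10% taper."""
    return ns.NeckParams(
        neck_length=26.0, proximal_diameter=24.3, suprarenal_angle=0.0,
        infrarenal_angle=0.0, surface_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def bent_params():
    """A noiseless neck with the case-group median bends."""
    return ns.NeckParams(
        neck_length=20.0, proximal_diameter=24.0, suprarenal_angle=36.0,
        infrarenal_angle=52.0, bend_plane_azimuth=135.0, surface_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def straight_subject(straight_params):
    return ns.generate_neck_geometry(straight_params, seed=0)


@pytest.fixture(scope="session")
def bent_subject(bent_params):
    return ns.generate_neck_geometry(bent_params, seed=0)


def make_analytic_cohort(n_case=10, n_control=10, seed=0, n_levels=10, n_angles=60):
    """Small aligned cohort via the closed-form landmark route."""
    case = ns.default_case_spec(n_case)
    control = ns.default_control_spec(n_control)
    subjects = ns.sample_cohort(case, control, seed=seed, geometry="centerline")
    seqs = np.random.SeedSequence(seed + 1).spawn(len(subjects))
    necks = []
    for s, seq in zip(subjects, seqs):
        grid = ns.analytic_landmarks(
            s.true_params, n_levels=n_levels, n_angles=n_angles,
            seed=np.random.default_rng(seq),
        )
        necks.append(
            ParametrizedNeck(
                landmarks=grid,
                level_arclengths=np.linspace(0, s.true_params.neck_length, n_levels),
                subject_id=s.subject_id,
                group=s.group,
            )
        )
    return ns.align_necks(necks), subjects


@pytest.fixture(scope="session")
def small_cohort():
    return make_analytic_cohort()
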