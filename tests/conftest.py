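import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import arcqa

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Coarse lattice used by unit tests that exercise the full pipeline;
#: resolution only changes constants, not any property under test.
COARSE_SPACING = 0.1


@pytest.fixture(scope="session")
def coarse_grid():
    return arcqa.GridSpec(COARSE_SPACING, 13.5)


@pytest.fixture(scope="session")
def seeded_plan():
    """One deterministic modulated full-arc plan."""
    return arcqa.generate_arc_plan(arcqa.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def seeded_pair(seeded_plan):
    """Error-free plan and its 1 mm bank-A error variant."""
    perturbed = arcqa.inject_bank_error(
        seeded_plan, arcqa.PerturbationSpec(bank="A", offset_cm=0.1))
    return seeded_plan, perturbed


@pytest.fixture(scope="session")
def default_report():
    """The full default experiment (8 seeded plans, fine lattice).

    Session-scoped: several acceptance checks read different columns of
    the same cohort.
    """
    return arcqa.run_experiment(arcqa.ExperimentConfig())


def asymmetric_control_point(index=0, angle=0.0, mu=1.0, n_pairs=40):
    """A deliberately left/right-asymmetric aperture for mirror tests."""
    a = np.zeros(n_pairs)
    b = np.zeros(n_pairs)
    a[18:22] = [-4.0, -3.5, -3.0, -2.5]
    b[18:22] = [1.0, 2.0, 1.5, 0.5]
    return arcqa.ControlPoint(index=index, gantry_angle_deg=angle,
                              mu_weight=mu, bankA_edges=a, bankB_edges=b)
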