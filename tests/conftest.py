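import numpy as np
import pytest

from ceusnine import phantom


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 12-per-class phantom cohort shared by read-only tests."""
    return phantom.sample_cohort(12, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def case_factory():
    """Factory building a case from explicit kinetics (no prior sampling)."""
    return make_case


def make_case(params: phantom.KineticParams, *, label: str = "HCC",
              speckle_scale: float = 0.0, image_side: int = 96,
              seed: int = 0) -> phantom.CaseRecord:
    """Build a case from explicit kinetics (no prior sampling), rendering all
    eleven phases — a controlled oracle for scoring tests."""
    geometry = phantom.PhantomGeometry(
        image_side=image_side,
        lesion_center=(image_side / 2, image_side / 2),
        lesion_diameter=round(0.28 * image_side),
    )
    noise = phantom.NoiseParams(speckle_scale=speckle_scale, rng_seed=seed)
    schedule = phantom.PhaseSchedule()
    rng = np.random.default_rng(seed)
    images = {}
    for phase, t in schedule.times().items():
        lesion_i, paren_i = phantom.time_intensity(params, t)
        images[phase] = phantom.render_phase(geometry, noise, lesion_i, paren_i, rng)
    return phantom.CaseRecord(case_id=f"case{seed}", label=label, params=params,
                              geometry=geometry, noise=noise, schedule=schedule,
                              images=images, rng_seed=seed)
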