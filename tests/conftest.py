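import pytest

from fasciclebayes import (
    FascicleClass,
    GeneratorSpec,
    MaterialParams,
    PriorSpec,
    TmcmcConfig,
    generate_dataset,
)


@pytest.fixture
def truth_params() -> MaterialParams:
    """The canonical ground truth used throughout the recovery tests:
    E_f = 1400 MPa, eta_f = 42 GPa.s (tau = 50 s), E_m = 0.4 MPa,
    r_inf = 0.4, sigma_n = 0.05."""
    return MaterialParams(
        fiber_modulus=1400.0,
        fiber_viscosity=42_000.0,
        matrix_modulus=0.4,
        retained_fraction=0.4,
        error_scale=0.05,
    )


@pytest.fixture
def base_class() -> FascicleClass:
    return FascicleClass(fiber_content=0.35, helix_angle_deg=70.0)


@pytest.fixture
def prior() -> PriorSpec:
    return PriorSpec()


@pytest.fixture
def fast_config() -> TmcmcConfig:
    """Small but adequate sampler settings for unit tests."""
    return TmcmcConfig(samples_per_stage=400, mh_steps_per_sample=3, seed=7)


@pytest.fixture
def noisefree_dataset(truth_params, base_class):
    return generate_dataset(
        GeneratorSpec(truth=truth_params, cls=base_class,
                      dataset_id="noisefree", noise_scale=0.0, seed=0)
    )


@pytest.fixture
def noisy_dataset(truth_params, base_class):
    return generate_dataset(
        GeneratorSpec(truth=truth_params, cls=base_class,
                      dataset_id="noisy", noise_scale=0.05, seed=11)
    )
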