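import numpy as np
import pytest

from pentagen import SimulationConfig, build_ssmodel, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20230817)


@pytest.fixture(scope="session")
def desk_study():
    """Small single-step study reused by model-level tests."""
    return simulate_study(
        SimulationConfig(
            n_founders=16,
            n_generations=3,
            n_snps=40,
            missing_rate=0.05,
            genotyped_fraction=0.5,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def desk_model(desk_study):
    model, ainv = build_ssmodel(
        desk_study.pedigree,
        desk_study.genotypes,
        desk_study.y,
        desk_study.record_animal,
        desk_study.fixed_codes,
        w=desk_study.config.w,
        sigma2_u=desk_study.config.sigma2_u,
        sigma2_e=desk_study.config.sigma2_e,
    )
    return desk_study, model, ainv
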