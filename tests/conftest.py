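import copy

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gabamorph as gm
from gabamorph.models import MLPConfig
from gabamorph.preprocessing import FeatureEncoding, encode_records, split_data
from gabamorph.surrogate import fit_surrogate

settings.register_profile(
    "gabamorph",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("gabamorph")


def noise_from_range(params, design, frac):
    """Per-trait noise sd as a fraction of the noise-free trait range."""
    clean = copy.deepcopy(params)
    clean.noise_sd = {t: 0.0 for t in gm.TRAITS}
    df = gm.generate_morphology(design, clean)
    return {t: frac * (df[t].max() - df[t].min()) for t in gm.TRAITS}


@pytest.fixture(scope="session")
def range_noise():
    return noise_from_range


@pytest.fixture(scope="session")
def recovery_data():
    """The surrogate parameter-recovery conditions: the full 512-row
    factorial with noise sd = 2% of each trait's range, split 80/20."""
    design = gm.pomegranate_design()
    params = gm.default_generator_params(1)
    params.noise_sd = noise_from_range(params, design, 0.02)
    params.seed = 7
    frame = gm.generate_morphology(design, params)
    enc = FeatureEncoding()
    X, Y = encode_records(frame, enc)
    split = split_data(len(frame), 0.8, seed=3)
    return frame, X, Y, split, enc


@pytest.fixture(scope="session")
def trained_mlp(recovery_data):
    _, X, Y, split, enc = recovery_data
    return fit_surrogate(
        X, Y, split.train_idx, "mlp", mlp_config=MLPConfig(seed=5), encoding=enc
    )


@pytest.fixture(scope="session")
def trained_rbf(recovery_data):
    _, X, Y, split, enc = recovery_data
    return fit_surrogate(
        X, Y, split.train_idx, "rbf", rbf_params={"k": 25, "seed": 5}, encoding=enc
    )
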