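import numpy as np
import pytest

from dagae import CohortSpec, DAGAE, ModelConfig, TrainConfig, generate_cohort

# Small-but-nontrivial study used across the suite: 20 regions, 36 time
# points, 4 modules, moderate class effect.  Session-scoped so the expensive
# pieces (cohort simulation, a short adversarial fit) run once.

TINY = dict(n_rois=20, n_timepoints=36, n_per_class=8, n_modules=4,
            within_corr=0.5, between_corr=0.1, effect_edges=0.25,
            effect_size=0.4, subject_noise_sd=0.05)


def tiny_model_config(**over):
    base = dict(n_rois=20, n_timepoints=36, latent_dim=8, enc_hidden=16,
                cla_hidden=(64, 32, 16, 8), ct_heads=(4, 4, 6),
                du_dims=(16, 36))
    base.update(over)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def tiny_spec():
    return CohortSpec(seed=7, **TINY)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_model_config()


@pytest.fixture(scope="session")
def tiny_results(tiny_cohort, tiny_config):
    """A short adversarial fit shared by training/evaluation tests."""
    model = DAGAE(tiny_cohort, config=tiny_config)
    return model.fit(TrainConfig(epochs=60, seed=11))
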