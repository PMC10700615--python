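import warnings

import pytest
from hypothesis import settings

import marshcascade as mc

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

# the Hill-table shift and standardization warnings are expected on
# generated data; tests assert on them explicitly where relevant
warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*shifted.*non-negative.*")


@pytest.fixture(scope="session")
def default_dataset() -> mc.SyntheticDataset:
    """One default synthetic experiment (paper-style treatment effects)."""
    return mc.generate_experiment(mc.ExperimentConfig(seed=42))


@pytest.fixture(scope="session")
def function_matrix(default_dataset):
    return mc.build_function_matrix(default_dataset.raw)
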