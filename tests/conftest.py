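import numpy as np
import pytest
import yaml

from bindscape import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_complex():
    return sd.make_toy_complex()


@pytest.fixture(scope="session")
def default_poses(toy_complex):
    return sd.make_default_poses(toy_complex)


@pytest.fixture(scope="session")
def mixture(toy_complex):
    """Study-condition mixture at a desk-scale frame count, fixed seed."""
    spec = sd.default_mixture_spec(toy_complex, n_frames=6000, seed=42)
    traj, labels = sd.sample_mixture(spec, toy_complex)
    return spec, traj, labels


@pytest.fixture(scope="session")
def regions_yaml(tmp_path_factory):
    path = tmp_path_factory.mktemp("regions") / "toy_regions.yaml"
    path.write_text(yaml.safe_dump(sd.region_schema()))
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
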