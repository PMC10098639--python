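import numpy as np
import pytest

from microexpr.datasets_io import DOMAIN_MACRO
from microexpr.fixtures import SynthConfig, synth_catalog


@pytest.fixture(scope="session")
def small_synth_config():
    """Three subjects, one clip per class, short clips: enough to exercise
    every pipeline stage quickly."""
    return SynthConfig(n_subjects=3, clips_per_subject=3, frames_per_clip=24,
                       seed=7)


@pytest.fixture(scope="session")
def small_catalog(small_synth_config):
    return synth_catalog(small_synth_config)


@pytest.fixture(scope="session")
def small_macro_catalog(small_synth_config):
    cfg = SynthConfig(**{**vars(small_synth_config), "n_subjects": 2})
    catalog = synth_catalog(cfg, domain=DOMAIN_MACRO)
    for s in catalog.samples:  # macro corpora have their own subject pool
        s.subject_id = "m" + s.subject_id
        s.clip_id = "m" + s.clip_id
    return catalog


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory, small_synth_config):
    """A samm-like on-disk tree written once for the I/O tests."""
    root = tmp_path_factory.mktemp("samm_tree")
    synth_catalog(small_synth_config, out_dir=root)
    return root


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
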