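import numpy as np
import pytest

from orthoface import synthetic as syn


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 6-subject synthetic cohort shared across tests (seed 7)."""
    outdir = tmp_path_factory.mktemp("ds_tiny")
    cfg = syn.GeneratorConfig(n_subjects=6, seed=7, test_fraction=1 / 3)
    manifest_path = syn.generate_dataset(cfg, outdir)
    return {"config": cfg, "manifest_path": manifest_path, "dir": outdir}


@pytest.fixture(scope="session")
def sample_face():
    """One deterministic rendered subject with exact ground truth."""
    cfg = syn.GeneratorConfig(n_subjects=1, seed=3)
    rng = np.random.default_rng(3)
    geom = syn.sample_geometry(rng, cfg)
    image, landmarks, pad = syn.render_face(geom, noise_sigma=0.0)
    return {"geometry": geom, "image": image, "landmarks": landmarks, "pad": pad}
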