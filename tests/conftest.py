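import numpy as np
import pytest

from nbx import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A tiny 4-class synthetic smear set (12 images/class at 32 px)."""
    out = tmp_path_factory.mktemp("smears")
    spec = synthetic.all_style_spec(image_side=32, seed=7,
                                    counts={c: 12 for c in
                                            synthetic.ALL_STYLE_MORPHOLOGY})
    manifest = synthetic.generate_dataset(spec, out)
    return spec, manifest
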