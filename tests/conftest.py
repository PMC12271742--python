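import numpy as np
import pandas as pd
import pytest

from mmsim import fixtures as fx
from mmsim.image import Image


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_image(rng):
    return Image(rng.random((32, 32)), image_id="rand32")


@pytest.fixture()
def structured_image():
    return fx.generate_structure(structure="filaments", size=(96, 96), seed=7)


@pytest.fixture(scope="session")
def fov_series():
    """5 FOVs x 6 averaging levels noise series, reference flagged."""
    images, manifest = fx.make_fov_series(n_fovs=5, base_seed=0)
    return images, manifest


@pytest.fixture(scope="session")
def defocus_series():
    """11 FOVs x 7 focal offsets defocus grid, reference flagged."""
    images, manifest = fx.make_defocus_series(n_fovs=11, base_seed=0)
    return images, manifest


@pytest.fixture(scope="session")
def defocus_scored(defocus_series):
    """Full-marker MMSim scores joined onto the defocus manifest."""
    from mmsim import score_dataset

    images, manifest = defocus_series
    ref_id = manifest.index[manifest.is_reference][0]
    reports = score_dataset(images, ref_id)
    df = manifest.copy()
    df["mmsim"] = pd.Series({r.image_id: r.mmsim for r in reports})
    return df, ref_id
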