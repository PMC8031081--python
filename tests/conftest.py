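import warnings

import numpy as np
import pytest

import cdpa
from cdpa.exceptions import SmallGroupWarning


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_dataset():
    """The documented 9-group separated preset at a fixed seed."""
    return cdpa.make_preset_dataset("default", seed=1)


@pytest.fixture(scope="session")
def fitted_default(default_dataset):
    """Vectors, models and profiles for the default preset (shared, read-only)."""
    vecs = cdpa.encode_sites(default_dataset.sites)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallGroupWarning)
        models = cdpa.fit_group_models(vecs, default_dataset.labels)
    profiles = [cdpa.mahalanobis_profile(v, models) for v in vecs]
    return vecs, models, profiles


def random_site(rng, n=30, scales=(3.0, 2.0, 1.0), site_id="rand"):
    """A generic anisotropic cloud in a random frame (test helper)."""
    from scipy.stats import special_ortho_group

    X = rng.normal(size=(n, 3)) * np.asarray(scales)
    R = special_ortho_group.rvs(3, random_state=rng)
    return cdpa.BindingSite(
        site_id=site_id, coords=X @ R.T + rng.normal(0, 10, 3), ligand_label="X"
    )
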