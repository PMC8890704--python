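import numpy as np
import pytest

from mitolens.synthetic_geometry import (ellipsoid_taper, make_cone_envelope,
                                         make_mito_bundle, bundle_preset)


@pytest.fixture(scope="session")
def mini_envelope():
    """Reference-style envelope (8 um long, 4.5 um max diameter, blunt bulge)."""
    return make_cone_envelope(8.0, 4.5, taper_profile=ellipsoid_taper(bulge=0.5))


@pytest.fixture(scope="session")
def active_bundle(mini_envelope):
    spec = bundle_preset("active", mini_envelope, seed=1, fill_fraction=0.17)
    meshes, skels = make_mito_bundle(spec, mini_envelope)
    return spec, meshes, skels


@pytest.fixture(scope="session")
def hibernating_bundle(mini_envelope):
    spec = bundle_preset("hibernating", mini_envelope, seed=1, fill_fraction=0.17)
    meshes, skels = make_mito_bundle(spec, mini_envelope)
    return spec, meshes, skels
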