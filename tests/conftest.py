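import numpy as np
import pytest

import cryptmorph as cm


@pytest.fixture(scope="session")
def small_params():
    """A small noise-free field that renders in milliseconds."""
    return cm.preset(
        "normal",
        seed=11,
        field_size_px=128,
        crypt_count=6,
        lumen_radius_um=(9.0, 1.0),
        min_edge_spacing_um=5.0,
        noise_sigma=0.0,
    )


@pytest.fixture(scope="session")
def small_scene(small_params):
    return cm.generate_scene(small_params)


@pytest.fixture(scope="session")
def default_scene():
    """Full-size noise-free scene with the default normal preset."""
    return cm.generate_scene(cm.preset("normal", seed=3, noise_sigma=0.0))


def single_crypt_scene(radius_um, aspect=1.0, serration=(0.0, 0), field=160, seed=2):
    """One centered crypt on a noise-free field (helper for shape oracles)."""
    params = cm.SceneParams(
        field_size_px=field,
        pixel_pitch_um=1.0,
        crypt_count=1,
        lumen_radius_um=(radius_um, 0.0),
        aspect_ratio=(aspect, 0.0),
        serration=serration,
        min_edge_spacing_um=0.0,
        noise_sigma=0.0,
        seed=seed,
    )
    center = field / 2.0
    geom = cm.CryptGeometry(
        center_um=(center, center),
        a_um=radius_um * np.sqrt(aspect),
        b_um=radius_um / np.sqrt(aspect),
        orientation_rad=0.0,
        serration_amplitude_um=serration[0],
        serration_lobes=serration[1],
    )
    return cm.render_scene([geom], params), geom
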