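import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def annulus_mask():
    """Segmented concentric annulus, outer 15 mm / inner 10 mm at 0.2 mm."""
    from femora import annulus_section, derive_threshold, pool_histogram, segment_cortex

    sec = annulus_section(15.0, 10.0, spacing=0.2)
    thr = derive_threshold(pool_histogram([sec]))
    return segment_cortex(sec, thr)


@pytest.fixture(scope="session")
def eccentric_mask():
    """Annulus with the cavity shifted 2 mm laterally."""
    from femora import annulus_section, segment_cortex

    sec = annulus_section(15.0, 10.0, spacing=0.2, inner_offset_mm=(2.0, 0.0))
    return segment_cortex(sec, 100.0)


@pytest.fixture(scope="session")
def small_tube_volume():
    """Small noise-free straight tube phantom for IO-level tests."""
    from femora.phantom import PhantomSpec, render_phantom

    spec = PhantomSpec(
        n_slices=37,
        outer_rx=8.0,
        outer_ry=8.0,
        thickness=3.0,
        bow_mm=0.0,
        lateral_mode="none",
        noise_sd=0.0,
        in_plane_spacing=0.25,
    )
    vol, truth = render_phantom(spec)
    return spec, vol, truth


def random_blob(rng, shape=(150, 150), smooth=6.0, quantile=0.75):
    """A random smooth blob mask (largest connected component)."""
    from scipy import ndimage as ndi

    field = ndi.gaussian_filter(rng.normal(size=shape), smooth)
    mask = field > np.quantile(field, quantile)
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    assert n >= 1
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)
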