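import numpy as np
import pytest

from kinetoforge import (KinetochoreProteinParams, NoiseParams, Nuf2Params,
                         OpticsParams, Spc29Params, SpindleParams,
                         add_noise, build_model, process_stack, render_stack)


@pytest.fixture(scope="session")
def optics():
    return OpticsParams()


@pytest.fixture(scope="session")
def default_spindle():
    return SpindleParams()


def make_spot_image(centers_green, centers_red, sigma=1.5, amp=40000.0,
                    noise_sd=0.0, size=50, seed=0):
    """Synthetic 50x50x3 image with Gaussian spots at known subpixel centers."""
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    img = np.zeros((size, size, 3), dtype=float)
    for chan, centers in ((1, centers_green), (0, centers_red)):
        for (r0, c0) in centers:
            img[..., chan] += amp * np.exp(
                -((rr - r0)**2 + (cc - c0)**2) / (2 * sigma**2))
    if noise_sd > 0:
        img += rng.normal(0, noise_sd, img.shape)
    return np.clip(img, 0, 65535).astype(np.uint16)


@pytest.fixture(scope="session")
def spot_image():
    """Two kinetochore (green) and two SPB (red) foci at known positions."""
    return make_spot_image(
        centers_green=[(25.0, 20.0), (25.0, 30.0)],
        centers_red=[(25.0, 10.0), (25.0, 40.0)],
        sigma=1.5, amp=40000.0, noise_sd=2000.0, seed=7)


@pytest.fixture(scope="session")
def rendered_processed_images(optics):
    """Eight processed images from one rendered default-model stack."""
    fl = build_model(SpindleParams(), 42, nuf2=Nuf2Params(),
                     spc29=Spc29Params(),
                     kinetochore=KinetochoreProteinParams())
    stack = add_noise(render_stack(fl.restrict_channels(optics.channel_names),
                                   optics), NoiseParams(), 5)
    return process_stack(stack, source_id="fixture")
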