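"""Shared fixtures: scaled-down phantoms and a once-trained UNet.

The heavyweight fixture (`trained_unet`) trains the segmentation network a
single time per session on 200 phantom slices at 64x64 and is reused by
every test that needs a working model.
"""

from __future__ import annotations

import numpy as np
import pytest

from spikect import phantom as ph
from spikect.segmentation import TrainConfig, train_unet
from spikect.volume_io import CircularROI, remove_holder


def small_grain_spec(seed: int, **overrides) -> ph.PhantomSpec:
    """A 64x64-slice phantom whose grains fit inside the small holder."""
    kw = dict(
        grain_count=16,
        semi_axes_range=((8.0, 10.0), (5.5, 7.0), (4.5, 5.5)),
        axial_spacing=11.0,
        rachis_radius=2.0,
        volume_dims=(200, 64, 64),
        seed=seed,
    )
    kw.update(overrides)
    return ph.PhantomSpec(**kw)


def holder_free_slices(vol) -> list[np.ndarray]:
    """Slices with the holder ring masked out (fixed concentric ROI)."""
    ny, nx = vol.shape[1:]
    radius = 0.92 * (min(ny, nx) / 2.0) - 2.0
    roi = CircularROI(((nx - 1) / 2.0, (ny - 1) / 2.0), radius)
    return [remove_holder(s, roi) for s in vol.voxels]


@pytest.fixture(scope="session")
def unet_train_phantom():
    spec = small_grain_spec(seed=11)
    vol, truth = ph.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def unet_heldout_phantom():
    spec = small_grain_spec(seed=12)
    vol, truth = ph.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def trained_unet(unet_train_phantom):
    """UNet (depth 4, base 16) trained 10 epochs on 200 phantom slices."""
    _, vol, truth = unet_train_phantom
    images = holder_free_slices(vol)
    masks = [(sl > 0).astype(np.uint8) for sl in truth.label_volume]
    cfg = TrainConfig(epochs=10, batch_size=4, input_size=64, depth=4,
                      base_channels=16, seed=0)
    model, history = train_unet(images, masks, cfg)
    return {"model": model, "history": history, "cfg": cfg}
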