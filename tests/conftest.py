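import numpy as np
import pytest

from nerupture.simgen import NoiseParams, SceneGeometry, SimulationParams


@pytest.fixture
def geometry():
    """A compact field that keeps simulations fast."""
    return SceneGeometry(
        image_shape=(160, 160),
        nucleus_radii=(42.0, 36.0),
        cell_radii=(66.0, 60.0),
    )


@pytest.fixture
def clean_params():
    """Noiseless LC-like rupture parameters with no background offset."""
    return SimulationParams(background=0.0)


def snr_noise(level: float, snr: float) -> NoiseParams:
    """Shot-noise settings giving the requested SNR at the given intensity:
    SNR = sqrt(level * gain)."""
    return NoiseParams(photon_gain=snr**2 / level, read_sigma=0.0)


def brute_erosion(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Reference erosion by explicit shifting: a pixel survives iff every
    footprint offset lands inside the mask. Independent of skimage."""
    assert footprint.shape[0] % 2 == 1 and footprint.shape[1] % 2 == 1
    cy, cx = footprint.shape[0] // 2, footprint.shape[1] // 2
    padded = np.pad(mask, ((cy, cy), (cx, cx)), constant_values=False)
    out = np.ones_like(mask, dtype=bool)
    for dy in range(footprint.shape[0]):
        for dx in range(footprint.shape[1]):
            if footprint[dy, dx]:
                out &= padded[dy : dy + mask.shape[0], dx : dx + mask.shape[1]]
    return out


def random_blob(rng: np.random.Generator, shape=(96, 96), n_seeds=4) -> np.ndarray:
    """A random connected blob large enough to survive a 10-px erosion."""
    from scipy import ndimage as ndi

    img = np.zeros(shape)
    for _ in range(n_seeds):
        cy, cx = rng.uniform(30, shape[0] - 30), rng.uniform(30, shape[1] - 30)
        ry, rx = rng.uniform(14, 24), rng.uniform(14, 24)
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        img += np.exp(-(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2))
    mask = img > 0.5
    labels, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask
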