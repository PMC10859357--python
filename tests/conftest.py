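import numpy as np
import pytest

from vesselquant.phantoms import PhantomSpec, VesselSpec, WrapSpec, make_wrap_phantom


@pytest.fixture
def single_vessel_phantom():
    """Factory: straight-cylinder phantom with one wrapped vessel."""

    def build(theta, *, shape=96, spacing=0.5, radius_mm=5.0, start_deg=None,
              extent_slices=None, jitter_prob=0.0, seed=None, vessel="SMA"):
        if extent_slices is None:
            extent_slices = max(1, int(round(20 * 0.5 / spacing)))
        spec = PhantomSpec(
            shape=(shape,) * 3,
            spacing=(spacing,) * 3,
            vessels=(VesselSpec(name=vessel, radius_mm=radius_mm,
                                center=(shape / 2, shape / 2)),),
            wraps={vessel: WrapSpec(theta_deg=theta, start_deg=start_deg,
                                    extent_slices=extent_slices)},
            jitter_prob=jitter_prob,
            seed=seed,
        )
        return make_wrap_phantom(spec)

    return build


@pytest.fixture
def random_blob_plane():
    """Factory: random single-component mask (<=32x32) plus nearby tumor."""

    from scipy import ndimage
    from skimage import measure

    from oracles import has_saddle

    def build(rng, n_max=32):
        while True:
            n = int(rng.integers(8, n_max))
            yy, xx = np.mgrid[:n, :n]
            mask = np.zeros((n, n), bool)
            for _ in range(3):
                cy, cx = rng.random(2) * (n - 8) + 4
                r = rng.random() * 4 + 2
                mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            lab = measure.label(mask, connectivity=2)
            if lab.max() < 1:
                continue
            sizes = [(lab == i).sum() for i in range(1, lab.max() + 1)]
            mask = lab == (1 + int(np.argmax(sizes)))
            if has_saddle(mask):
                continue
            ring = ndimage.binary_dilation(mask, iterations=3) & ~mask
            tumor = ring & (rng.random((n, n)) < 0.5)
            return mask, tumor

    return build
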