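import numpy as np
import pytest

from vasomap import phantom
from vasomap.phantom import RadiusLaw, VesselTreeSpec


def cylinder_mask(radius, length=40, pad=6, axis=0):
    """Digital cylinder along `axis`: voxels with cross-section distance
    <= radius from the center line."""
    side = int(2 * radius + 2 * pad + 1)
    shape = [side, side, side]
    shape[axis] = length
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    coords = [zz, yy, xx]
    c = (side - 1) / 2.0
    others = [coords[i] for i in range(3) if i != axis]
    return (others[0] - c) ** 2 + (others[1] - c) ** 2 <= radius**2


def sphere_mask(radius, pad=4):
    side = int(2 * radius + 2 * pad)
    ax = np.arange(side)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    c = (side - 1) / 2.0
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def straight_tree(radius=4.0, shape=(64, 64, 64), seed=0):
    """Single straight axis-aligned branch of constant radius."""
    spec = VesselTreeSpec(
        n_root_branches=1,
        branch_levels=1,
        radius_law=RadiusLaw(root_mean=radius, root_sigma=0.0),
        tortuosity_amplitude=0.0,
        volume_shape=shape,
        rng_seed=seed,
    )
    return phantom.generate_vessel_tree(spec)


@pytest.fixture(scope="session")
def standard_tree():
    """Mid-size branching tree reused by several segmentation tests."""
    spec = VesselTreeSpec(
        n_root_branches=2,
        branch_levels=3,
        radius_law=RadiusLaw(3.5, 0.0, 0.75),
        tortuosity_amplitude=1.5,
        volume_shape=(64, 64, 64),
        rng_seed=7,
    )
    return phantom.generate_vessel_tree(spec)


@pytest.fixture(scope="session")
def noisy_phantom(standard_tree):
    return phantom.rasterize(standard_tree, noise_sd=10.0, bias_amplitude=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(standard_tree):
    return phantom.rasterize(standard_tree, noise_sd=0.0, bias_amplitude=0.0)
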