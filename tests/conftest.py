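import numpy as np
import pytest

from needlepipe import (NeedleLocalization, PhantomSpec, SpecRanges,
                        generate_phantom, sample_spec, small_grid)


def truth_localization(truth) -> NeedleLocalization:
    return NeedleLocalization(tip=truth.tip, entry=truth.entry,
                              axis_direction=truth.axis_direction,
                              provenance="reference")


def flood_fill_components(mask: np.ndarray) -> int:
    """Independent BFS connected-component count (26-connectivity)."""
    visited = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    n = 0
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        n += 1
        stack = [start]
        visited[start] = True
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]
                        and 0 <= p[2] < shape[2] and mask[p] and not visited[p]):
                    visited[p] = True
                    stack.append(p)
    return n


@pytest.fixture(scope="session")
def small_specs():
    """A handful of phantom specs on the fast quarter-volume preset."""
    return sample_spec(SpecRanges(depth_mm=(19.4, 70.0)), n=6, seed=42,
                       grid=small_grid())


@pytest.fixture(scope="session")
def small_phantom(small_specs):
    """One generated phantom (volume, truth) on the small preset."""
    return generate_phantom(small_specs[0])


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(grid=small_grid(), entry_point=(20.0, 30.0, 80.0),
                       insertion_depth=55.0, angle_to_axial_deg=-35.0,
                       azimuth_deg=40.0, noise_sd=0.0, seed=7)
    return generate_phantom(spec)
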