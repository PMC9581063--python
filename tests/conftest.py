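import numpy as np
import pytest

from cryosse.volio import DensityMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_map(rng):
    return DensityMap(rng.random((12, 10, 14)).astype(np.float32),
                      origin=(-3.0, 2.5, 7.0), voxel_size=(1.0, 1.0, 1.0))


def brute_force_sphere_labels(shape, origin, annotations, radius=3.0):
    """Triple-loop oracle for Cα-sphere voxel labelling (helix wins overlaps)."""
    labels = np.zeros(shape, dtype=np.int8)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                center = np.array(origin) + np.array([i, j, k], dtype=float)
                is_helix = is_sheet = False
                for a in annotations:
                    d = np.linalg.norm(center - np.asarray(a.ca_coord))
                    if d <= radius:
                        if a.ss_class == "helix":
                            is_helix = True
                        elif a.ss_class == "sheet":
                            is_sheet = True
                labels[i, j, k] = 1 if is_helix else (2 if is_sheet else 0)
    return labels
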