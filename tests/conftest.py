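import numpy as np
import pytest

from osteorad import morphometry as morph
from osteorad import synthetic_data as synth


@pytest.fixture(scope="session")
def plate_stack_20um():
    """Plate stack: 100 um plates on 500 um pitch at 20 um voxels."""
    spec = synth.PhantomSpec(
        "plate_stack", 20.0,
        {"thickness_um": 100.0, "pitch_um": 500.0, "extent_um": 1500.0},
    )
    return synth.make_phantom(spec)


@pytest.fixture(scope="session")
def ball_10um():
    return synth.make_phantom(synth.PhantomSpec("ball", 10.0, {"radius_um": 200.0}))


@pytest.fixture(scope="session")
def rod_10um():
    return synth.make_phantom(
        synth.PhantomSpec("rod", 10.0, {"radius_um": 80.0, "length_um": 3000.0})
    )


@pytest.fixture(scope="session")
def plate_10um():
    return synth.make_phantom(
        synth.PhantomSpec("plate", 10.0, {"thickness_um": 40.0, "extent_um": 3000.0})
    )


@pytest.fixture(scope="session")
def torus_10um():
    return synth.make_phantom(synth.PhantomSpec("solid_torus", 10.0))


@pytest.fixture(scope="session")
def annulus_10um():
    """Hollow cylinder r_o=0.8 mm, r_i=0.5 mm, 50 slices at 10 um."""
    return synth.make_phantom(synth.PhantomSpec("hollow_cylinder", 10.0))


@pytest.fixture(scope="session")
def annulus_metrics_10um(annulus_10um):
    vol, truth = annulus_10um
    return morph.cortical_metrics(vol), truth


@pytest.fixture(scope="session")
def femur_like_20um():
    return synth.make_phantom(synth.PhantomSpec("femur_like", 20.0))


def euler_characteristic_oracle(mask: np.ndarray) -> int:
    """Euler characteristic of the union of closed voxel cubes, by direct
    inclusion-exclusion counting of distinct vertices, edges, faces and
    cells.  Matches the 26-connected foreground convention."""
    idx = np.argwhere(mask).astype(np.int64)
    if idx.size == 0:
        return 0
    dims = np.array(mask.shape) + 2  # corner lattice strides

    def encode(pts):
        return (pts[:, 0] * dims[1] + pts[:, 1]) * dims[2] + pts[:, 2]

    corners = []
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                corners.append(idx + [dz, dy, dx])
    n_v = np.unique(encode(np.concatenate(corners))).size

    n_e = 0
    for axis in range(3):
        edges = []
        for d in np.ndindex(2, 2, 2):
            if d[axis] == 1:
                continue
            edges.append(idx + list(d))
        # tag by axis via offset blocks
        n_e += np.unique(encode(np.concatenate(edges))).size

    n_f = 0
    for axis in range(3):
        faces = []
        for d in (0, 1):
            off = [0, 0, 0]
            off[axis] = d
            faces.append(idx + off)
        n_f += np.unique(encode(np.concatenate(faces))).size

    n_c = idx.shape[0]
    return int(n_v - n_e + n_f - n_c)


def betti_numbers_oracle(mask: np.ndarray) -> tuple[int, int, int]:
    """(b0, b1, b2) via union-find components, enclosed-cavity counting and
    the Euler-Poincare formula b1 = b0 + b2 - chi."""
    from scipy import ndimage as ndi

    b0 = ndi.label(mask, structure=np.ones((3, 3, 3)))[0].max() if mask.any() else 0
    bg, n_bg = ndi.label(~mask)  # 6-connected background
    border_labels = set()
    for axis in range(3):
        for side in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = side
            border_labels |= set(np.unique(bg[tuple(sl)]))
    border_labels.discard(0)
    b2 = n_bg - len(border_labels)
    chi = euler_characteristic_oracle(mask)
    b1 = b0 + b2 - chi
    return int(b0), int(b1), int(b2)
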