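import numpy as np
import pytest

from adipo3d import LabelStack, TissuePreset, measure_regions, pack_in_situ, pack_ex_situ

SPACING = (1.15, 1.15, 1.15)


def digitized_sphere(radius_vox: float, pad: int = 4) -> np.ndarray:
    """Binary ball of the given radius (in voxels) centred in a cube."""
    n = int(2 * radius_vox) + 2 * pad + 1
    c = n // 2
    zz, yy, xx = np.indices((n, n, n))
    return ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2).astype(
        np.int32
    )


@pytest.fixture(scope="session")
def sphere_r25_table():
    """Morphometry of a digitized sphere of radius 25 voxels at 1.15 µm."""
    return measure_regions(LabelStack(digitized_sphere(25), SPACING))


@pytest.fixture(scope="session")
def packed_pair():
    """Matched in situ / ex situ packs of the same 40 diameters (2.3 µm
    pitch for speed), with their morphometry tables."""
    spacing = (2.3, 2.3, 2.3)
    preset = TissuePreset("fixture", 60.0, 0.25)
    rng = np.random.default_rng(42)
    diameters = 60.0 * np.exp(rng.normal(-0.5 * np.log(1.0625), np.sqrt(np.log(1.0625)), 40))
    in_situ = pack_in_situ(diameters, (120, 120, 120), spacing, seed=1)
    ex_situ = pack_ex_situ(diameters, (170, 170, 170), spacing, seed=2)
    return {
        "diameters": diameters,
        "preset": preset,
        "in_situ": in_situ,
        "ex_situ": ex_situ,
        "in_situ_table": measure_regions(in_situ),
        "ex_situ_table": measure_regions(ex_situ),
    }
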