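import numpy as np
import pytest

from bmigap.imaging_io import GMVImage, VoxelMask
from bmigap.synthetic_cohort import PhantomSpec, clinical_fields, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(
        grid_shape=(10, 10, 10),
        n_per_group={"HC": 48, "SCZ": 16, "CHR": 16, "ROD": 16},
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    cohort = generate_cohort(tiny_spec)
    cohort.table = clinical_fields(cohort.table, seed=6,
                                   gap_true=cohort.truth.gap_true)
    return cohort


@pytest.fixture()
def small_mask():
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1:3, 1:3, 1:3] = True  # 8 voxels
    return VoxelMask(mask, np.eye(4))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_image(data, affine=None):
    return GMVImage(np.asarray(data, float),
                    np.eye(4) if affine is None else affine)
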