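import numpy as np
import pytest

from anisokernel import VolumeGrid, neighbor_offsets
from anisokernel.demo import demo_dataset
from anisokernel.template import CorrelationTemplate


def make_uniform_template(shape=(7, 7, 7), rho=0.8, voxel_mm=2.0,
                          tissue=1.0) -> CorrelationTemplate:
    """Template with one correlation value everywhere (edges in-bounds)."""
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    offsets = neighbor_offsets()
    rho_arr = np.full((len(offsets.unique_half),) + shape, float(rho))
    return CorrelationTemplate(
        rho=rho_arr,
        tissue_prob=VolumeGrid(np.full(shape, float(tissue)), affine),
        offsets=offsets,
    )


def make_random_template(shape, rng, lo=0.05, hi=0.999, voxel_mm=2.0,
                         tissue=None) -> CorrelationTemplate:
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    offsets = neighbor_offsets()
    rho = rng.uniform(lo, hi, size=(len(offsets.unique_half),) + shape)
    t = np.ones(shape) if tissue is None else tissue
    return CorrelationTemplate(
        rho=rho, tissue_prob=VolumeGrid(t, affine), offsets=offsets
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_template():
    return make_uniform_template()


@pytest.fixture(scope="session")
def demo_ds():
    return demo_dataset(seed=0)


@pytest.fixture(scope="session")
def demo_grid(demo_ds):
    from anisokernel.validation import evaluate_grid

    return evaluate_grid(
        demo_ds.subject_volumes,
        demo_ds.template,
        alphas=[0.0, 1.0],
        fwhms=[10.0, 20.0, 100.0],
        split_plan=demo_ds.split_plan,
    )
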