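import numpy as np
import pytest

from octbrain.core import TissueClass
from octbrain.synthetic import (
    AcquisitionSpec,
    DatasetSpec,
    PhantomSpec,
    build_phantom,
    generate_dataset,
    render_volume,
)


@pytest.fixture(scope="session")
def tiny_acq() -> AcquisitionSpec:
    """Desk-scale acquisition grid for fast unit tests (64 x 128 px)."""
    return AcquisitionSpec(n_depth_pixels=64, n_lateral_pixels=128)


@pytest.fixture(scope="session")
def nor_phantom(tiny_acq):
    spec = PhantomSpec(TissueClass.NOR, mu_base=2.0, seed=11)
    return build_phantom(spec, (tiny_acq.n_depth_pixels, tiny_acq.n_lateral_pixels))


@pytest.fixture(scope="session")
def gbm_phantom(tiny_acq):
    spec = PhantomSpec(TissueClass.GBM, mu_base=2.0, mu_lateral_variation=0.4,
                       n_inclusions=4, seed=12)
    return build_phantom(spec, (tiny_acq.n_depth_pixels, tiny_acq.n_lateral_pixels))


@pytest.fixture(scope="session")
def small_volume(gbm_phantom, tiny_acq):
    return render_volume(gbm_phantom, tiny_acq, n_frames=12, seed=21)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 9-volume synthetic dataset (2/2/2 train + 1/1/1 test, 12 frames each)."""
    out = tmp_path_factory.mktemp("dataset")
    spec = DatasetSpec(
        train_volumes={"NOR": 2, "GBM": 2, "PCNSL": 2},
        test_volumes={"NOR": 1, "GBM": 1, "PCNSL": 1},
        frames_per_volume=12,
        acq=AcquisitionSpec(n_depth_pixels=64, n_lateral_pixels=128),
    )
    manifest = generate_dataset(spec, out, seed=7)
    return out, manifest, spec


def make_records(n_per_class: int, shape=(128, 256), seed: int = 0,
                 vol_prefix: str = "V", frames_per_volume: int = 1):
    """Random standardized FrameRecords, one volume per ``frames_per_volume``."""
    from octbrain.core import BScanFrame, FrameRecord

    rng = np.random.default_rng(seed)
    records = []
    for ci, label in enumerate(TissueClass):
        for i in range(n_per_class):
            vid = f"{vol_prefix}{label.value}{i // frames_per_volume}"
            px = rng.random(shape)
            records.append(FrameRecord(BScanFrame(px, 2.5, 5.0), label, vid, i))
    return records
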