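import numpy as np
import pytest

from annostream import LabelVolume, PhantomSpec, ScanVolume, generate_phantom


def label_volume(array, spacing=(1.0, 1.0, 1.0), scan_id="t") -> LabelVolume:
    return LabelVolume(np.asarray(array, dtype=np.uint8), spacing, scan_id)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic synthetic scan with 8 lesions on a 24x64x64 grid."""
    spec = PhantomSpec(shape=(24, 64, 64), n_lesions=8, seed=3)
    scan, gt, manifest = generate_phantom(spec, scan_id="phantom_small")
    return scan, gt, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
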