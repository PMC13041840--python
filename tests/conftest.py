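import nibabel as nib
import numpy as np
import pytest

DISCOVERY_TES = [13.9, 31.7, 49.5]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_nifti(path, array, affine=None):
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))
    return str(path)


@pytest.fixture
def echo_files(tmp_path, rng):
    """Three 4x4x4x10 echo volumes with positive intensities, plus TEs."""
    paths = []
    for e in range(3):
        vol = 100.0 + rng.normal(0, 5.0, size=(4, 4, 4, 10))
        paths.append(write_nifti(tmp_path / f"echo{e + 1}.nii", vol))
    return paths, DISCOVERY_TES


@pytest.fixture
def atlas_file(tmp_path):
    """A 4x4x4 atlas with labels 1, 2, 3 filling the grid."""
    atlas = np.zeros((4, 4, 4), dtype=np.int16)
    atlas[:2] = 1
    atlas[2] = 2
    atlas[3] = 3
    return write_nifti(tmp_path / "atlas.nii", atlas)
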