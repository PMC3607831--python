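import numpy as np
import pandas as pd
import pytest

from scnmap.volume_io import Cohort, GMImage


def identity_affine(voxel_mm: float = 1.0, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = origin
    return aff


def make_cohort(
    data4d,
    affine=None,
    groups=None,
    genders=None,
    ages=None,
):
    """Cohort from an (n_subjects, nx, ny, nz) array with simple covariates."""
    data4d = np.asarray(data4d, dtype=float)
    n = data4d.shape[0]
    affine = identity_affine() if affine is None else affine
    groups = ["Y"] * n if groups is None else list(groups)
    genders = (["F", "M"] * n)[:n] if genders is None else list(genders)
    ages = [30] * n if ages is None else list(ages)
    ids = [f"s{i:03d}" for i in range(n)]
    images = [
        GMImage(data=data4d[i], affine=affine, subject_id=ids[i]) for i in range(n)
    ]
    cov = pd.DataFrame(
        {"subject_id": ids, "group": groups, "gender": genders, "age": ages}
    )
    return Cohort(images=images, covariates=cov)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
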