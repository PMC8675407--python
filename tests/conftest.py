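import numpy as np
import pandas as pd
import pytest

import megasite as ms


@pytest.fixture(scope="session")
def three_site_cohort():
    """60 subjects across 3 sites with site-varying age and a group effect."""
    spec = ms.SimulationSpec(
        n_sites=3,
        subjects_per_site=20,
        covariate_specs=[
            ms.CovariateSpec(
                "age", "truncated_normal",
                [{"mean": 25, "sd": 3, "low": 20, "high": 30},
                 {"mean": 45, "sd": 5, "low": 35, "high": 55},
                 {"mean": 70, "sd": 5, "low": 60, "high": 80}],
            )
        ],
        effect_sizes={"group": 0.8, "age": 0.01},
        n_elements=6,
        seed=42,
    )
    subjects = ms.generate_cohort(spec)
    measures = ms.generate_measures(subjects, spec)
    return spec, subjects, measures


def make_nifti_fixture(path, descrip=b"PatientName Smith", intent=b"secret",
                       ext_payload=None, compressed=False):
    """Construct a small NIfTI-1 file with identifying text via nibabel."""
    import nibabel as nib

    data = np.arange(24, dtype=np.float32).reshape(2, 3, 4)
    img = nib.Nifti1Image(data, np.eye(4))
    img.header["descrip"] = descrip
    img.header["intent_name"] = intent
    if ext_payload is not None:
        img.header.extensions.append(nib.nifti1.Nifti1Extension(6, ext_payload))
    nib.save(img, str(path))
    return data
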