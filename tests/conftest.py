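import numpy as np
import pytest

from lnmts import AnnotatedVolume, make_phantom, random_phantom_spec


def build_volume(
    placements,
    shape=(5, 20, 20),
    spacing=(1.0, 1.0),
    thickness=4.0,
    gap=1.0,
    patient_id="test",
):
    """Handcrafted label volume from {label: [(slice, row, col), ...]}."""
    vox = np.zeros(shape, dtype=np.int32)
    for label, coords in placements.items():
        for s, r, c in coords:
            vox[s, r, c] = label
    return AnnotatedVolume(
        voxels=vox,
        pixel_spacing_row=spacing[0],
        pixel_spacing_col=spacing[1],
        slice_thickness_T=thickness,
        slice_gap_G=gap,
        patient_id=patient_id,
    )


@pytest.fixture(scope="session")
def random_phantoms():
    """20 random phantoms with their independently computed ground truth."""
    rng = np.random.default_rng(2024)
    return [make_phantom(random_phantom_spec(rng, patient_id=f"ph-{i}")) for i in range(20)]
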