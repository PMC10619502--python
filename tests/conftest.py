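import numpy as np
import pytest

from lcsleep import (
    HypnogramSpec,
    LCVolumeSpec,
    ReferenceRegionSpec,
    StageSpectrumSpec,
    Volume3D,
    generate_hypnogram,
    generate_lc_volume,
    generate_sleep_eeg,
)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless LC phantom: volume, masks, analytic contrast, reference spec."""
    spec = LCVolumeSpec(lc_intensity=120.0, background_intensity=100.0, noise_sd=0.0)
    vol, masks, truth = generate_lc_volume(spec, seed=0)
    ref = ReferenceRegionSpec(center_per_slice=spec.ref_center_per_slice)
    return spec, vol, masks, truth, ref


@pytest.fixture(scope="session")
def short_night():
    """A 2-hour synthetic night: hypnogram, annotations, EEG at 200 Hz."""
    hspec = HypnogramSpec(
        time_in_bed_minutes=120.0,
        sleep_onset_epoch=10,
        arousal_rate_per_hour=4.0,
        artifact_fraction=0.02,
    )
    sspec = StageSpectrumSpec()
    hyp, ann = generate_hypnogram(hspec, seed=11)
    signal, truth = generate_sleep_eeg(hyp, sspec, seed=12, annotations=ann)
    return hyp, ann, signal, sspec, truth


def toy_volume(data, axial_axis=0):
    return Volume3D(data=np.asarray(data, dtype=float), axial_axis=axial_axis)
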