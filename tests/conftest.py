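import numpy as np
import pytest

from eegaug import (CohortSpec, Diagnosis, EpochSet, PreprocessConfig,
                    epochs_from_cohort, generate_cohort)


def make_epochset(labels, fs_hz=128.0, duration_s=2.0, n_channels=3, seed=0,
                  subject_ids=None, scale=1.0):
    """Small white-noise EpochSet for protocol-level tests."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    t = int(round(fs_hz * duration_s))
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(n)]
    return EpochSet(
        epochs=scale * rng.standard_normal((n, n_channels, t)),
        fs_hz=fs_hz, duration_s=duration_s,
        labels=np.asarray([Diagnosis.coerce(l) for l in labels], dtype=object),
        subject_ids=np.asarray(subject_ids, dtype=object),
        channel_names=tuple(f"CH{i+1}" for i in range(n_channels)))


@pytest.fixture(scope="session")
def small_cohort():
    """6 HC / 3 MCI / 4 AD synthetic subjects, 30 s each."""
    return generate_cohort(CohortSpec(n_hc=6, n_mci=3, n_ad=4,
                                      duration_s=30.0, seed=1234))


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    """10-s epochs of the small cohort at 128 Hz."""
    return epochs_from_cohort(small_cohort,
                              PreprocessConfig(epoch_duration_s=10.0))
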