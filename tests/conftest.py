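import numpy as np
import pytest

import eegmdd as m
from eegmdd.montage import make_montage

DESK_LABELS = ("F3", "F4", "C3", "C4", "P3", "P4")
DESK_REGIONS = {
    "F3": "frontal", "F4": "frontal",
    "C3": "central", "C4": "central",
    "P3": "parietal", "P4": "parietal",
}


@pytest.fixture(scope="session")
def desk_montage():
    """Reduced six-electrode montage used for fast simulation tests."""
    return make_montage(DESK_LABELS, DESK_REGIONS, "Cz")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, fs=100.0, labels=None, subject_id="t01",
                class_label="unknown"):
    """Wrap an epochs x channels x samples array into an EpochSet."""
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return m.EpochSet(subject_id=subject_id, site_id="lab",
                      class_label=class_label, fs=fs,
                      channel_labels=tuple(labels), data=data)


@pytest.fixture(scope="session")
def tiny_cohort(desk_montage):
    """Small zero-effect cohort (3 MDD + 3 HC, one site) and its features."""
    spec = m.CohortSpec(n_mdd=3, n_hc=3, sites=(m.SiteProfile("s1"),),
                        seed=99, fs=250.0, duration=12.0,
                        montage=desk_montage)
    recs = m.simulate_cohort(spec)
    table = m.extract_cohort(recs, montage=desk_montage)
    return recs, table
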