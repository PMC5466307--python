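"""Shared fixtures: synthetic subjects are expensive, so build them once."""

import numpy as np
import pytest

from pacmri import simulate
from pacmri.config import AcquisitionConfig, SubjectConfig


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free, jitter-free, artifact-free subject with ground truth."""
    cfg = SubjectConfig(
        seed=11, noise_sd=0.0, ectopic_rate=0.0, r_jitter_sd=0.0, mhd_amplitude=0.0
    )
    return simulate.simulate_subject(cfg, keep_scene=True)


@pytest.fixture(scope="session")
def noisefree_subject():
    """Noise-free imaging but realistic ECG jitter and ectopics."""
    cfg = SubjectConfig(seed=12, noise_sd=0.0)
    return simulate.simulate_subject(cfg, keep_scene=True)


@pytest.fixture(scope="session")
def default_subject():
    """Defaults: the study conditions (128 beats, noise, jitter, MHD)."""
    return simulate.simulate_subject(SubjectConfig(seed=7), keep_scene=True)


@pytest.fixture(scope="session")
def clean_vmap(clean_subject):
    from pacmri import recon

    return recon.reconstruct(clean_subject.echoes)


@pytest.fixture(scope="session")
def clean_cycles(clean_subject):
    from pacmri import ecg

    return ecg.refine_and_screen(clean_subject.ecg)


@pytest.fixture(scope="session")
def clean_course(clean_subject, clean_vmap, clean_cycles):
    """Segmented aortic velocity course of the clean subject."""
    from pacmri import segment

    mean_hr = float(np.mean(clean_cycles.hr[clean_cycles.accepted]))
    seg = segment.segment_aorta(clean_vmap, mean_hr)
    return seg.chosen.course
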