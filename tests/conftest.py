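import numpy as np
import pytest

from perioperf.config import AcquisitionConfig, AIFParams
from perioperf.kinetics import sample_aif


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def aif_params(acq):
    return AIFParams(onset_delay=acq.bolus_onset)


@pytest.fixture(scope="session")
def aif_samples(acq, aif_params):
    return sample_aif(aif_params, acq.frame_times)


@pytest.fixture(scope="session")
def noiseless_subject(acq, aif_params):
    """One noiseless default-design phantom subject with its rendered
    dataset (shared: building it exercises the AUC-matching solver)."""
    from perioperf.phantom import CohortDesign, build_subject, render_acquisition

    design = CohortDesign()
    truth = build_subject(design, acq, seed=2024, aif=aif_params)
    dataset = render_acquisition(truth, acq, aif_params, noise_sd=0.0, seed=7)
    return design, truth, dataset
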