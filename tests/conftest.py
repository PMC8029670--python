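import numpy as np
import pytest

import waggledance as wd

# printed colony-level fits, reused across tests as known truths
WAGGLE_VFK = {"a": 0.1993, "b": 2.0018, "c": 0.6717}
WAGGLE_SEGMENTED = {"intercept1": 0.2917, "slope1": 1.4282,
                    "psi": 1.0328, "slope2": 0.6683}
WAGGLE_LINEAR = {"alpha": 0.4475, "beta": 1.1152}
RETURN_LINEAR = {"alpha": 1.3712, "beta": 0.5238}


@pytest.fixture(scope="session")
def study_summaries():
    """One synthetic feeder-training dataset at the study conditions."""
    obs = wd.generate_dances(wd.SimulationConfig(seed=7))
    return wd.summarize_dances(obs)


@pytest.fixture(scope="session")
def study_arrays(study_summaries):
    d = np.array([s.d for s in study_summaries])
    tw = np.array([s.tw for s in study_summaries])
    tr = np.array([s.tr for s in study_summaries])
    tc = np.array([s.tc for s in study_summaries])
    return d, tw, tr, tc


@pytest.fixture(scope="session")
def study_fits(study_arrays):
    d, tw, _, _ = study_arrays
    return {
        "linear": wd.fit_linear(d, tw, response="tw"),
        "vfk": wd.fit_vfk(d, tw, response="tw"),
        "segmented": wd.fit_segmented(d, tw, response="tw"),
    }
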