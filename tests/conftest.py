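import numpy as np
import pytest

import valuebind as vb


@pytest.fixture(scope="session")
def grid_population():
    """A semi-orthogonal population (rho = 0.5) with balanced grid labels."""
    spec = vb.syndata.PopulationCodeSpec.create(
        n_neurons=50, d_lv=1.0, d_la=1.0, d_n=1.0, sigma=0.4, seed=42)
    labels = vb.syndata.grid_labels(150)
    data = vb.syndata.simulate_population(spec, labels, seed=43)
    value01 = (labels[:, 0] - 1).astype(float)
    side = np.where(labels[:, 1] == 1, 1.0, -1.0)
    return spec, labels, data, value01, side


@pytest.fixture(scope="session")
def behavioral_session():
    """A filtered session with softmax choices under the default model."""
    sess = vb.syndata.generate_task_session(4000, seed=7)
    params = vb.behavior.SubjectiveValueParams(
        alpha=0.7, gamma=0.5, beta=1.0, tau=0.03, model_id="pow-prelec")
    sess = vb.syndata.simulate_choices(sess, params, seed=8)
    filtered, _ = vb.behavior.filter_trials(sess)
    return filtered, params


@pytest.fixture(scope="session")
def neural_session(behavioral_session):
    sess, _ = behavioral_session
    spec = vb.syndata.PopulationCodeSpec.create(
        n_neurons=40, d_lv=1.0, d_la=1.0, d_n=1.0, sigma=0.5, seed=9)
    return vb.syndata.simulate_session_rates(spec, sess, seed=10), spec
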