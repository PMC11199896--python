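import numpy as np
import pytest
from hypothesis import settings

from errpnet.synth import SynthConfig, generate_epochset

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_set():
    """Two subjects, one session, 60 epochs each, moderate noise."""
    return generate_epochset(SynthConfig(
        n_subjects=2, epochs_per_subject=60, sessions_per_subject=1,
        noise_sd=2.0, seed=11))


@pytest.fixture(scope="session")
def two_session_set():
    """Two subjects x two sessions, 80 epochs each subject."""
    return generate_epochset(SynthConfig(
        n_subjects=2, epochs_per_subject=80, sessions_per_subject=2,
        noise_sd=2.0, seed=12))


@pytest.fixture(scope="session")
def noiseless_set():
    """Separable: error epochs are the pure template, correct epochs zero."""
    return generate_epochset(SynthConfig(
        n_subjects=1, epochs_per_subject=100, sessions_per_subject=1,
        noise_sd=0.0, seed=13))


def brute_force_auc(scores, labels):
    """All-pairs concordance AUC (percent), ties credited one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return 100.0 * (gt + 0.5 * eq) / (len(pos) * len(neg))
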