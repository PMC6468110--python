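import numpy as np
import pytest

from ictalpipe.features import build_feature_matrix
from ictalpipe.signal_io import epoch_recording, labels_from_annotations
from ictalpipe.synthetic import EcogSimConfig, SeizureEventSpec, generate_ecog


@pytest.fixture(scope="session")
def annotated_recording():
    """A 30 min synthetic ECoG with five seizures at fixed, spread-out times.

    Event times are aligned away from epoch boundaries on purpose; total
    ictal time ~500 s out of 1800 s.
    """
    cfg = EcogSimConfig(duration=1800.0, seizure_amplitude_ratio=10.0, seed=42)
    events = [
        SeizureEventSpec(100.0, 80.0),
        SeizureEventSpec(400.0, 120.0),
        SeizureEventSpec(700.0, 60.0),
        SeizureEventSpec(1000.0, 150.0),
        SeizureEventSpec(1400.0, 90.0),
    ]
    return generate_ecog(cfg, events)


@pytest.fixture(scope="session")
def epoch_setup(annotated_recording):
    rec, track = annotated_recording
    index = epoch_recording(rec, 5.0)
    labels = labels_from_annotations(track, index)
    return rec, track, index, labels


@pytest.fixture(scope="session")
def feature_matrix(epoch_setup):
    rec, _, index, _ = epoch_setup
    return build_feature_matrix(rec, index)


def brute_force_posteriors(obs, params):
    """Enumeration oracle: sum over all S^T hidden state sequences."""
    import itertools

    obs = np.asarray(obs, dtype=int)
    n_states = params.transition.shape[0]
    T = obs.size
    joint = {}
    total = 0.0
    for seq in itertools.product(range(n_states), repeat=T):
        p = params.initial[seq[0]] * params.emission[seq[0], obs[0]]
        for t in range(1, T):
            p *= params.transition[seq[t - 1], seq[t]] * params.emission[seq[t], obs[t]]
        joint[seq] = p
        total += p
    post = np.zeros((T, n_states))
    for seq, p in joint.items():
        for t, s in enumerate(seq):
            post[t, s] += p
    return post / total, float(np.log(total))
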