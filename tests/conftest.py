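import numpy as np
import pytest

from synquant import synthetic as syn


@pytest.fixture
def default_params():
    return syn.SimParams()


@pytest.fixture
def noisy_fov():
    """Standard test field: ~50 boutons, SNR 10 (amplitude 100, noise 10)."""
    return syn.generate_fov(syn.SimParams(), (256, 256), seed=7, noise_sd=10.0)


@pytest.fixture
def noiseless_fov():
    return syn.generate_fov(syn.SimParams(), (256, 256), seed=7, noise_sd=0.0)


def match_detections(truth: np.ndarray, detected: np.ndarray, tol: float = 2.0):
    """Greedy one-to-one matching of detected centroids to true centers.

    Returns (n_true_positive, n_false_positive)."""
    from scipy.spatial import cKDTree

    if len(detected) == 0:
        return 0, 0
    d, i = cKDTree(detected).query(truth)
    used, tp = set(), 0
    for dd, ii in sorted(zip(d, i)):
        if dd <= tol and ii not in used:
            tp += 1
            used.add(ii)
    return tp, len(detected) - tp
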