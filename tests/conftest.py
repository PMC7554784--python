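import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sersclass as sc

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture()
def tiny_set():
    """Four handcrafted spectra on a 5-point grid (2 control, 2 trc)."""
    grid = np.array([100.0, 101.0, 102.0, 103.0, 104.0])
    intensities = np.array(
        [
            [0.0, 2.0, 1.0, 3.0, 1.0],
            [1.0, 0.0, 2.0, 1.0, 0.0],
            [0.5, 2.5, 1.5, 3.5, 1.5],
            [1.5, 0.5, 2.5, 1.5, 0.5],
        ]
    )
    labels = np.array(["control", "control", "trc", "trc"], dtype=object)
    ids = np.array([f"S01/L{i + 1:02d}" for i in range(4)], dtype=object)
    return sc.SpectrumSet(grid, intensities, labels, ids)


@pytest.fixture(scope="session")
def default_set():
    """One default-condition synthetic dataset (51 spectra), shared per session."""
    sset, truth = sc.generate(sc.GeneratorConfig(seed=1))
    return sset, truth


@pytest.fixture(scope="session")
def corrected_set(default_set):
    sset, truth = default_set
    return sc.correct_baseline(sset), truth


# ---------------------------------------------------------------------------
# Independent brute-force oracles for the univariate scorers (naive loops,
# no shared code with the implementation).

def brute_t(X, labels):
    scores = []
    for j in range(X.shape[1]):
        a = [X[i, j] for i in range(X.shape[0]) if labels[i] == "control"]
        b = [X[i, j] for i in range(X.shape[0]) if labels[i] == "trc"]
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        va = sum((v - ma) ** 2 for v in a) / (len(a) - 1)
        vb = sum((v - mb) ** 2 for v in b) / (len(b) - 1)
        denom = (vb / len(b) + va / len(a)) ** 0.5
        if denom == 0:
            scores.append(0.0 if ma == mb else None)
        else:
            scores.append(abs(ma - mb) / denom)
    return _fill_flagged(scores)


def brute_w(X, labels):
    scores = []
    for j in range(X.shape[1]):
        a = [X[i, j] for i in range(X.shape[0]) if labels[i] == "control"]
        b = [X[i, j] for i in range(X.shape[0]) if labels[i] == "trc"]
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        sa = (sum((v - ma) ** 2 for v in a) / (len(a) - 1)) ** 0.5
        sb = (sum((v - mb) ** 2 for v in b) / (len(b) - 1)) ** 0.5
        if sa + sb == 0:
            scores.append(0.0 if ma == mb else None)
        else:
            scores.append(abs(ma - mb) / (sa + sb))
    return _fill_flagged(scores)


def _fill_flagged(scores):
    finite = [s for s in scores if s is not None]
    top = max(finite) if finite else 0.0
    return np.array([top + 1.0 if s is None else s for s in scores])


def brute_relief(X, labels):
    n, p = X.shape
    scores = []
    for j in range(p):
        total = 0.0
        for i in range(n):
            hit = min(
                abs(X[i, j] - X[m, j])
                for m in range(n)
                if m != i and labels[m] == labels[i]
            )
            miss = min(
                abs(X[i, j] - X[m, j]) for m in range(n) if labels[m] != labels[i]
            )
            total += miss - hit
        scores.append(total / n)
    return np.array(scores)
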