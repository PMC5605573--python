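import numpy as np
import pytest
import scipy.sparse as sp

from wfage import (
    ModelSpec,
    TransientSystem,
    build_transition_matrix,
    extract_transient_system,
)


def make_system(Ne, s=0.0, h=0.5, u=0.0, v=0.0, cutoff=0.0):
    """Transient system for a small Wright-Fisher model (dense-friendly)."""
    spec = ModelSpec(Ne=Ne, s=s, h=h, u=u, v=v)
    return extract_transient_system(build_transition_matrix(spec, cutoff=cutoff))


def scalar_system(q=0.5):
    """One-transient-state chain: Q = [[q]], symmetric absorption."""
    r = (1.0 - q) / 2.0
    return TransientSystem(
        Q=sp.csc_matrix(np.array([[q]])),
        R=np.array([[r, r]]),
        state_labels=np.array([1]),
        spec=None,
    )


def dense_fundamental(ts):
    """Dense fundamental matrix N = (I - Q)^-1 (oracle path)."""
    Q = np.asarray(ts.Q.todense())
    return np.linalg.inv(np.eye(Q.shape[0]) - Q)


def brute_force_age_pmf(ts, p, x, t_max):
    """Unnormalized f(t) = [Q^t]_{p,x} by repeated dense matrix powers."""
    Q = np.asarray(ts.Q.todense())
    ip, ix = ts.index_of(p), ts.index_of(x)
    out = np.empty(t_max + 1)
    M = np.eye(Q.shape[0])
    for t in range(t_max + 1):
        out[t] = M[ip, ix]
        M = M @ Q
    return out


@pytest.fixture(scope="session")
def ne5_neutral():
    return make_system(5)


@pytest.fixture(scope="session")
def ne5_selected():
    return make_system(5, s=-0.02, h=0.0, u=1e-4, v=1e-4)
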