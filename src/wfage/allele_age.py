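"""Exact allele-age distribution and moments for absorbing Markov chains.

An allele founded at copy count ``p`` and observed, still segregating, at
copy count ``x`` has age ``t`` with probability proportional to the
``(p, x)`` entry of ``Q^t``.  Because the chain is absorbing, the
normalizer ``sum_t Q^t = (I-Q)^{-1} = N`` is finite, so

    f(t) = [Q^t]_{p,x} / N_{p,x},     t = 0, 1, 2, ...

is a proper distribution (t = 0 contributes only when p = x: observing the
allele in its founding generation has age 0).  The k-th raw moment is a
rational matrix expression in Q whose numerator factors through the
polylogarithm of negative integer order,

    mu_k = [Li_{-k}(Q)]_{p,x} / N_{p,x},
    Li_{-k}(z) = z * A_k(z) / (1 - z)^{k+1},

with ``A_k`` the k-th Eulerian polynomial (A_1 = 1, A_2 = 1 + z,
A_3 = 1 + 4z + z^2, ...).  Every moment is therefore computable with
``k + 1`` triangular solves against one LU factorization of ``(I - Q)^T``
plus a handful of sparse matrix-vector products that assemble the x-th
column of ``Q * A_k(Q)`` — never a matrix-matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .markov_core import ResolventFactorization, _start_vector, factorize
from .wf_model import TransientSystem

__all__ = [
    "AgeMoments",
    "AgePMF",
    "StartPrior",
    "age_moments",
    "age_pmf",
    "starting_copy_prior",
    "polylog_numerator_coefficients",
]

MAX_MOMENT = 4

#: largest transient state space for which the full pmf may be requested
PMF_STATE_LIMIT = 2001


class UnreachableStateError(ValueError):
    """Observed state has probability 0 under the start distribution."""


def polylog_numerator_coefficients(k: int) -> list[int]:
    """Coefficients of the Eulerian polynomial ``A_k(z)``.

    ``Li_{-k}(z) = sum_{j>=1} j^k z^j = z * A_k(z) / (1-z)^{k+1}``.  The
    coefficients satisfy the triangle recurrence
    ``E(k, j) = (j+1) E(k-1, j) + (k-j) E(k-1, j-1)``:
    [1], [1, 1], [1, 4, 1], [1, 11, 11, 1], ...
    """
    if k < 1 or int(k) != k:
        raise ValueError(f"moment order k must be a positive integer, got {k}")
    row = [1]
    for m in range(2, k + 1):
        prev = row + [0]
        row = [(j + 1) * prev[j] + (m - j) * (prev[j - 1] if j else 0) for j in range(m)]
    return row


@dataclass(frozen=True)
class AgeMoments:
    """Moments of the allele-age distribution, in generations.

    ``raw_moments[k]`` is ``E[T^k]``; ``normalizer`` is ``N_{p,x}`` (or its
    start-weighted average), the expected visits to ``x`` from the start.
    """

    mean: float
    variance: float
    std_dev: float
    raw_moments: dict[int, float]
    normalizer: float
    provenance: dict = field(default_factory=dict)


def age_moments(
    ts: TransientSystem,
    f: ResolventFactorization,
    start,
    x: int,
    k_max: int = 2,
) -> AgeMoments:
    """Exact raw moments ``mu_1 .. mu_k_max`` of allele age.

    Parameters
    ----------
    ts, f
        Transient system and the LU factorization of ``(I - Q)^T``.
    start
        Founding copy count ``p`` (int), or a probability vector over the
        transient states (e.g. from :class:`StartPrior`) to integrate over
        the founding configuration.
    x
        Observed copy count (must label a transient state).
    k_max
        Highest raw moment, between 1 and 4.

    Notes
    -----
    ``mu_k = M_{k+1} . c_k / M_1[x]`` where ``M_1, M_2, ...`` are iterated
    solves against ``(I - Q)^T`` and ``c_k = Q A_k(Q) e_x`` is assembled
    column-wise from powers ``Q^m e_x``.
    """
    if not (1 <= k_max <= MAX_MOMENT):
        raise ValueError(
            f"k_max must be in 1..{MAX_MOMENT}; higher moments follow from "
            "polylog_numerator_coefficients and iterated solves"
        )
    ix = ts.index_of(int(x))
    b = _start_vector(ts, start)
    M = f.solve(b, "T")  # M_1
    normalizer = float(M[ix])
    if normalizer <= 0.0:
        raise UnreachableStateError(
            f"state x={x} is unreachable from the given start (normalizer 0)"
        )
    # powers Q^m e_x, m = 1..k_max, by repeated sparse matvec
    e_x = np.zeros(ts.n_transient)
    e_x[ix] = 1.0
    cols = []
    c = e_x
    for _ in range(k_max):
        c = ts.Q @ c
        cols.append(c)
    raw: dict[int, float] = {}
    for k in range(1, k_max + 1):
        M = f.solve(M, "T")  # M_{k+1}
        coeffs = polylog_numerator_coefficients(k)
        num_col = sum(a * cols[j] for j, a in enumerate(coeffs))
        raw[k] = float(M @ num_col) / normalizer
    mean = raw[1]
    variance = raw[2] - mean**2 if k_max >= 2 else float("nan")
    prov = {
        "start": start if np.isscalar(start) else "vector",
        "x": int(x),
        "spec": ts.spec,
    }
    return AgeMoments(
        mean=mean,
        variance=variance,
        std_dev=float(np.sqrt(variance)) if k_max >= 2 else float("nan"),
        raw_moments=raw,
        normalizer=normalizer,
        provenance=prov,
    )


@dataclass(frozen=True)
class AgePMF:
    """Truncated allele-age pmf ``f(t), t = 0..t_max`` and its missing tail mass."""

    t: np.ndarray
    probabilities: np.ndarray
    deficit: float


def age_pmf(
    ts: TransientSystem,
    normalizer: float,
    p: int,
    x: int,
    t_max: int,
    state_limit: int = PMF_STATE_LIMIT,
) -> AgePMF:
    """Allele-age probabilities ``f(t) = [Q^t]_{p,x} / N_{p,x}``, t = 0..t_max.

    Computed by propagating the row vector ``e_p^T Q^t`` with one sparse
    vector-matrix product per generation — ``Q^t`` is never materialized.
    Intended for small state spaces; for large ``Ne`` use
    :func:`age_moments` instead.
    """
    if ts.n_transient > state_limit:
        raise ValueError(
            f"state space of {ts.n_transient} exceeds the pmf limit "
            f"({state_limit}); use age_moments for large chains"
        )
    ip, ix = ts.index_of(int(p)), ts.index_of(int(x))
    QT = ts.Q.T.tocsr()
    w = np.zeros(ts.n_transient)
    w[ip] = 1.0
    probs = np.empty(t_max + 1)
    for t in range(t_max + 1):
        probs[t] = w[ix]
        w = QT @ w
    probs /= normalizer
    return AgePMF(
        t=np.arange(t_max + 1),
        probabilities=probs,
        deficit=float(1.0 - probs.sum()),
    )


@dataclass(frozen=True)
class StartPrior:
    """Truncated, renormalized Poisson prior over the founding copy count.

    Under recurrent mutation the founding event can inject several mutant
    copies in one generation; the number of new copies is modelled as
    ``p ~ Poisson(lambda = theta/2)`` conditioned on ``p >= 1`` and
    truncated to copy counts whose raw pmf is at least ``epsilon``.
    """

    support: np.ndarray
    weights: np.ndarray
    epsilon: float
    lam: float

    def start_vector(self, ts: TransientSystem) -> np.ndarray:
        """Dense probability vector over the transient states of ``ts``."""
        v = np.zeros(ts.n_transient)
        for p, w in zip(self.support, self.weights):
            v[ts.index_of(int(p))] = w
        return v


def starting_copy_prior(theta: float, epsilon: float = 1e-5) -> StartPrior:
    """Poisson(theta/2) prior over the founding copy count ``p >= 1``.

    Copy counts with raw Poisson probability below ``epsilon`` are dropped,
    then the retained weights are renormalized.  As ``epsilon`` grows toward
    the p = 1 probability the prior degenerates to a point mass at p = 1,
    recovering the single-founder convention.
    """
    if theta <= 0.0:
        raise ValueError("theta must be positive")
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must be in (0, 1)")
    lam = theta / 2.0
    # pmf is eventually decreasing; scan until it falls below epsilon past the mode
    support = []
    p = 1
    while True:
        pm = poisson.pmf(p, lam)
        if pm >= epsilon:
            support.append(p)
        elif p > lam:
            break
        p += 1
    if not support:
        raise ValueError(
            f"no copy count p >= 1 has Poisson(lambda={lam:g}) probability >= {epsilon:g}"
        )
    support = np.asarray(support)
    w = poisson.pmf(support, lam)
    return StartPrior(support=support, weights=w / w.sum(), epsilon=epsilon, lam=lam)
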