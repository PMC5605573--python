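"""Biallelic diploid Wright-Fisher model with selection, dominance and mutation.

The state space is the number of copies of the mutant allele in a diploid
population of ``Ne`` individuals, i.e. the integers ``0 .. 2*Ne``.  Copy
counts 0 (extinction) and ``2*Ne`` (fixation) are absorbing.  One step of
the chain is one generation: deterministic selection on genotype fitnesses
(1, 1+s*h, 1+s), then bidirectional mutation, then binomial resampling of
``2*Ne`` gametes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.special import gammaln

__all__ = [
    "ModelSpec",
    "TransitionMatrix",
    "TransientSystem",
    "post_selection_mutation_frequency",
    "build_transition_matrix",
    "extract_transient_system",
    "save_transient_system",
    "load_transient_system",
]


@dataclass(frozen=True)
class ModelSpec:
    """Parameters of the Wright-Fisher chain.

    Parameters
    ----------
    Ne : int
        Effective diploid population size (>= 2).  The chain has
        ``2*Ne + 1`` copy-number states.
    s : float
        Selection coefficient; homozygous mutant fitness is ``1 + s``.
    h : float
        Dominance coefficient; heterozygote fitness is ``1 + s*h``.
    u : float
        Per-generation wild-type -> mutant mutation probability.
    v : float
        Per-generation mutant -> wild-type mutation probability.
    """

    Ne: int
    s: float = 0.0
    h: float = 0.5
    u: float = 0.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.Ne < 2 or int(self.Ne) != self.Ne:
            raise ValueError(f"Ne must be an integer >= 2, got {self.Ne}")
        if not (1.0 + self.s > 0.0 and 1.0 + self.s * self.h > 0.0):
            raise ValueError(
                f"all genotype fitnesses must be positive: s={self.s}, h={self.h}"
            )
        for name, rate in (("u", self.u), ("v", self.v)):
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"mutation rate {name}={rate} outside [0, 1)")

    @property
    def n_states(self) -> int:
        return 2 * self.Ne + 1

    @property
    def theta(self) -> float:
        """Population-scaled mutation rate theta = 4*Ne*u."""
        return 4.0 * self.Ne * self.u

    @classmethod
    def from_theta(
        cls, Ne: int, theta: float, s: float = 0.0, h: float = 0.5
    ) -> "ModelSpec":
        """Symmetric-mutation constructor: u = v = theta / (4*Ne)."""
        mu = theta / (4.0 * Ne)
        return cls(Ne=Ne, s=s, h=h, u=mu, v=mu)

    @classmethod
    def from_scaled_selection(
        cls,
        Ne: int,
        two_nes: float,
        h: float = 0.5,
        theta: float | None = None,
        u: float = 0.0,
        v: float = 0.0,
    ) -> "ModelSpec":
        """Construct from population-scaled selection 2*Ne*s."""
        s = two_nes / (2.0 * Ne)
        if theta is not None:
            mu = theta / (4.0 * Ne)
            u, v = mu, mu
        return cls(Ne=Ne, s=s, h=h, u=u, v=v)


def post_selection_mutation_frequency(q, spec: ModelSpec):
    """Expected mutant gamete frequency after selection and mutation.

    Selection acts first through the genotype fitnesses (1, 1+s*h, 1+s)
    assuming Hardy-Weinberg proportions at frequency ``q``; mutation then
    flips gametes in both directions::

        psi* = [(1+s) q^2 + (1+sh) q (1-q)] / wbar
        wbar = (1+s) q^2 + 2 (1+sh) q (1-q) + (1-q)^2
        psi  = psi* (1 - v) + (1 - psi*) u

    Accepts scalars or arrays; returns the same shape.
    """
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)) or np.any(q < 0.0) or np.any(q > 1.0):
        raise ValueError("allele frequency q must be finite and in [0, 1]")
    s, h, u, v = spec.s, spec.h, spec.u, spec.v
    w_mut = (1.0 + s) * q * q
    w_het = (1.0 + s * h) * q * (1.0 - q)
    wbar = w_mut + 2.0 * w_het + (1.0 - q) ** 2
    q_sel = (w_mut + w_het) / wbar
    psi = q_sel * (1.0 - v) + (1.0 - q_sel) * u
    return psi if psi.ndim else float(psi)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix over copy-number states 0..2Ne."""

    entries: sp.csr_matrix
    absorbing_states: tuple[int, int]
    cutoff: float
    spec: ModelSpec | None = None

    @property
    def n_states(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class TransientSystem:
    """Transient block Q and transient-to-absorbing block R of an absorbing chain.

    ``Q[i, j]`` is the one-step probability of moving between transient
    states ``state_labels[i] -> state_labels[j]``; ``R[:, 0]`` and
    ``R[:, 1]`` are the one-step probabilities of extinction and fixation.
    """

    Q: sp.csc_matrix
    R: np.ndarray
    state_labels: np.ndarray = field(repr=False)
    spec: ModelSpec | None = None

    @property
    def n_transient(self) -> int:
        return self.Q.shape[0]

    def index_of(self, copies: int) -> int:
        """Row/column index of the transient state with this copy count."""
        idx = np.searchsorted(self.state_labels, copies)
        if idx >= len(self.state_labels) or self.state_labels[idx] != copies:
            raise ValueError(f"copy count {copies} is not a transient state")
        return int(idx)


def _binomial_row(n: int, p: float, log_cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of Binomial(n, p) with pmf >= exp(log_cutoff).

    The pmf is unimodal, so the retained support is a contiguous window
    around the mean.  Evaluated in log space via gammaln to avoid underflow.
    """
    if p <= 0.0:
        return np.array([0]), np.array([1.0])
    if p >= 1.0:
        return np.array([n]), np.array([1.0])
    mean = n * p
    sd = np.sqrt(n * p * (1.0 - p))
    pad = 12.0 * sd + 35.0
    lo, hi = max(0, int(mean - pad)), min(n, int(mean + pad) + 1)
    logp, log1mp = np.log(p), np.log1p(-p)
    lg_n1 = gammaln(n + 1)

    def logpmf(j: np.ndarray) -> np.ndarray:
        return lg_n1 - gammaln(j + 1) - gammaln(n - j + 1) + j * logp + (n - j) * log1mp

    j = np.arange(lo, hi + 1)
    lp = logpmf(j)
    # widen until the window edges are genuinely below the cutoff
    while lo > 0 and lp[0] >= log_cutoff:
        lo = max(0, lo - 200)
        j = np.arange(lo, hi + 1)
        lp = logpmf(j)
    while hi < n and lp[-1] >= log_cutoff:
        hi = min(n, hi + 200)
        j = np.arange(lo, hi + 1)
        lp = logpmf(j)
    keep = lp >= log_cutoff
    return j[keep], np.exp(lp[keep])


def build_transition_matrix(
    spec: ModelSpec, cutoff: float = 1e-12
) -> TransitionMatrix:
    """Assemble the sparse Wright-Fisher transition matrix.

    Row ``i`` (for transient ``1 <= i <= 2Ne-1``) is the
    ``Binomial(2Ne, psi(i/2Ne))`` pmf over ``j = 0..2Ne`` with entries below
    ``cutoff`` dropped; rows 0 and 2Ne are absorbing identity rows.  Dropped
    mass is *not* renormalized: the row-sum deficit is bounded by
    ``(2Ne+1) * cutoff``, mirroring a "zero at machine precision" treatment.
    """
    if not (0.0 <= cutoff < 1e-8):
        raise ValueError(f"cutoff must be in [0, 1e-8), got {cutoff}")
    n = 2 * spec.Ne
    log_cutoff = np.log(cutoff) if cutoff > 0.0 else -np.inf
    rows, cols, vals = [], [], []
    # absorbing identity rows
    rows.append(np.array([0, n]))
    cols.append(np.array([0, n]))
    vals.append(np.array([1.0, 1.0]))
    for i in range(1, n):
        psi = post_selection_mutation_frequency(i / n, spec)
        j, pv = _binomial_row(n, psi, log_cutoff)
        rows.append(np.full(j.size, i))
        cols.append(j)
        vals.append(pv)
    P = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 1, n + 1),
    )
    return TransitionMatrix(entries=P, absorbing_states=(0, n), cutoff=cutoff, spec=spec)


def extract_transient_system(P: TransitionMatrix) -> TransientSystem:
    """Split the chain into its transient block Q and absorbing block R."""
    n = P.n_states - 1
    ext, fix = P.absorbing_states
    M = P.entries
    for a in (ext, fix):
        row = M.getrow(a)
        if row.nnz != 1 or row.indices[0] != a or row.data[0] != 1.0:
            raise ValueError(f"state {a} is not an absorbing identity row")
    Q = M[1:n, 1:n].tocsc()
    R = np.column_stack(
        [np.asarray(M[1:n, ext].todense()).ravel(), np.asarray(M[1:n, fix].todense()).ravel()]
    )
    return TransientSystem(Q=Q, R=R, state_labels=np.arange(1, n), spec=P.spec)


def save_transient_system(ts: TransientSystem, q_path, r_path) -> None:
    """Write Q and R in MatrixMarket coordinate format."""
    mmwrite(q_path, ts.Q)
    mmwrite(r_path, sp.csc_matrix(ts.R))


def load_transient_system(q_path, r_path=None) -> TransientSystem:
    """Read a transient system from MatrixMarket files.

    This is the generic entry point for analysing any user-supplied finite
    absorbing Markov chain: only Q is required for age computations; R is
    needed for absorption and sojourn analyses.  If R is omitted it is
    reconstructed as a single absorbing column holding each row's deficit
    ``1 - rowsum(Q)``.
    """
    Q = sp.csc_matrix(mmread(q_path))
    if Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    if r_path is not None:
        R = np.asarray(sp.csc_matrix(mmread(r_path)).todense())
    else:
        R = np.asarray(1.0 - Q.sum(axis=1)).reshape(-1, 1)
    labels = np.arange(1, Q.shape[0] + 1)
    return TransientSystem(Q=Q, R=R, state_labels=labels, spec=None)
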