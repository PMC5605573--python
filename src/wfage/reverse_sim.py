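"""Monte-Carlo validation of the exact allele-age moments.

The age distribution can be sampled without conditioning-by-rejection by
running the *time-reversed* absorbing chain: a walker starts at the observed
copy count ``x`` and steps backward in time under

    Q'[j, k] = Q[k, j] * N[p, k] / N[p, j]

until, while at the founding count ``p``, it takes the absorbing "stop"
transition (probability ``1 / N[p, p]``) marking the founding mutation.
The number of reversed steps taken is an exact draw of the allele age;
extinction and fixation are not reachable in the reversed chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .markov_core import ResolventFactorization, factorize, resolvent_row
from .wf_model import TransientSystem

__all__ = ["ReversedChain", "SimulationSummary", "build_reversed_chain", "simulate_ages"]

#: visit counts below this are treated as "unreachable backward" and pruned
_PRUNE_TOL = 1e-300


@dataclass(frozen=True)
class ReversedChain:
    """Time-reversed transient chain anchored at founding copy count ``p``."""

    Qprime: sp.csr_matrix
    stop_prob: np.ndarray
    p_anchor: int
    state_labels: np.ndarray = field(repr=False)

    @property
    def n_states(self) -> int:
        return self.Qprime.shape[0]

    def index_of(self, copies: int) -> int:
        idx = np.searchsorted(self.state_labels, copies)
        if idx >= len(self.state_labels) or self.state_labels[idx] != copies:
            raise ValueError(f"copy count {copies} not in the reversed state space")
        return int(idx)


def build_reversed_chain(
    ts: TransientSystem, f: ResolventFactorization | None, p: int
) -> ReversedChain:
    """Construct the reversed chain from one row of the fundamental matrix.

    Only ``N[p, .]`` is needed — a single solve of ``(I - Q)^T M = e_p``.
    States with ``N[p, j] = 0`` (unreachable from ``p`` going forward, hence
    unreachable backward from any observable state) are pruned before the
    similarity transform so no 0/0 arises.
    """
    if f is None:
        f = factorize(ts)
    Np = resolvent_row(f, ts, int(p))
    keep = Np > _PRUNE_TOL
    ip_full = ts.index_of(int(p))
    if not keep[ip_full]:
        raise ValueError(f"N[p,p] vanished for p={p}; chain is numerically degenerate")
    Np_k = Np[keep]
    labels = ts.state_labels[keep]
    Qk = ts.Q[np.ix_(keep, keep)]
    # Q' = D^{-1} Q^T D with D = diag(N[p, .])
    D = sp.diags(Np_k)
    Dinv = sp.diags(1.0 / Np_k)
    Qprime = (Dinv @ Qk.T @ D).tocsr()
    stop = np.zeros(labels.size)
    ip = int(np.searchsorted(labels, p))
    stop[ip] = 1.0 / Np_k[ip]
    return ReversedChain(Qprime=Qprime, stop_prob=stop, p_anchor=int(p), state_labels=labels)


@dataclass(frozen=True)
class SimulationSummary:
    """Replicate ages from the reversed chain, with summary statistics."""

    replicates: int
    seed: int
    sample_mean: float
    sample_sd: float
    standard_error: float
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    max_steps_hit: int
    ages: np.ndarray | None = None


def _sampling_tables(rc: ReversedChain) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flattened per-row inverse-CDF tables for vectorized sampling.

    Row ``j`` of the reversed chain (its transitions plus, at the anchor,
    the stop transition with target -1) is stored as a cumulative
    distribution offset by ``j``, so the concatenation is globally sorted
    and a single ``searchsorted(cum, state + u)`` samples every walker at
    once, whatever row it occupies.
    """
    n = rc.n_states
    Q = rc.Qprime
    cums, targets = [], []
    for j in range(n):
        lo, hi = Q.indptr[j], Q.indptr[j + 1]
        probs = Q.data[lo:hi]
        tgts = Q.indices[lo:hi].astype(np.int64)
        if rc.stop_prob[j] > 0.0:
            probs = np.append(probs, rc.stop_prob[j])
            tgts = np.append(tgts, -1)
        c = np.cumsum(probs)
        c[-1] = 1.0  # close the row exactly; rowsum is 1 up to rounding
        cums.append(j + c)
        targets.append(tgts)
    offsets = np.zeros(n + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([t.size for t in targets])
    return np.concatenate(cums), np.concatenate(targets), offsets


def simulate_ages(
    rc: ReversedChain,
    x: int,
    replicates: int,
    seed: int,
    max_steps: int = 10**9,
    bins: int | str = "auto",
    keep_ages: bool = False,
) -> SimulationSummary:
    """Draw ``replicates`` exact allele ages by walking the reversed chain.

    Every replicate starts at ``x``; its age is the number of reversed
    transitions taken before the stop transition fires (a same-generation
    observation, x = p stopping immediately, has age 0).  All replicates
    advance in lock-step through vectorized inverse-CDF sampling, so the
    run is deterministic given ``seed`` and independent of batching.

    Replicates still walking after ``max_steps`` are counted in
    ``max_steps_hit`` and excluded from the moments — with sane inputs the
    default cap is never reached.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ix = rc.index_of(int(x))
    cum, targets, _ = _sampling_tables(rc)
    rng = np.random.default_rng(seed)

    state = np.full(replicates, ix, dtype=np.int64)
    alive = np.arange(replicates, dtype=np.int64)
    ages = np.zeros(replicates, dtype=np.int64)
    truncated = np.zeros(replicates, dtype=bool)
    step = 0
    while alive.size:
        if step >= max_steps:
            truncated[alive] = True
            break
        u = rng.random(alive.size)
        nxt = targets[np.searchsorted(cum, state[alive] + u, side="left")]
        stopped = nxt < 0
        ages[alive[stopped]] = step
        keep = ~stopped
        alive = alive[keep]
        state[alive] = nxt[keep]
        step += 1

    ok = ~truncated
    vals = ages[ok].astype(float)
    mean = float(vals.mean()) if vals.size else float("nan")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    counts, edges = np.histogram(vals, bins=bins)
    return SimulationSummary(
        replicates=replicates,
        seed=seed,
        sample_mean=mean,
        sample_sd=sd,
        standard_error=sd / np.sqrt(vals.size) if vals.size else float("nan"),
        histogram_edges=edges,
        histogram_counts=counts,
        max_steps_hit=int(truncated.sum()),
        ages=ages if keep_ages else None,
    )
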