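"""Sparse resolvent machinery for finite absorbing Markov chains.

Everything downstream (allele-age moments, absorption probabilities and
times, conditional sojourn times) reduces to repeated triangular solves
against a single sparse LU factorization of ``(I - Q)^T``.  No
matrix-matrix product is ever formed: the implementation uses only the
factorization, matrix-vector products, and sparse column extraction.

Writing ``N = (I - Q)^{-1}`` for the fundamental matrix, ``N[p, j]`` is the
expected number of generations spent at transient state ``j`` for a chain
started at ``p``; the solve ``(I - Q)^T m = e_p`` returns exactly that row.
The same factorization solves the untransposed system ``(I - Q) y = b``
(SuperLU exposes both orientations), which yields columns of ``N`` as
needed for endpoint-conditioned quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .wf_model import TransientSystem

__all__ = [
    "ResolventFactorization",
    "AbsorptionSummary",
    "factorize",
    "resolvent_row",
    "iterate_resolvent",
    "absorption_probabilities",
    "conditional_absorption_times",
    "sojourn_difference_vs_neutral",
]

#: hard bound on the residual of every solve, after at most one step of
#: iterative refinement
RESIDUAL_TOL = 1e-8


class SingularChainError(RuntimeError):
    """Raised when (I - Q) cannot be factorized or a solve fails to converge."""


@dataclass(frozen=True)
class ResolventFactorization:
    """Reusable sparse LU factorization of ``(I - Q)^T``.

    Immutable after creation; arbitrarily many right-hand sides may be
    solved against it.  Both orientations are available:

    * ``solve(b)``            solves ``(I - Q)^T m = b``  (rows of N),
    * ``solve(b, "N")``       solves ``(I - Q)   y = b``  (columns of N).
    """

    _lu: object = field(repr=False)
    _A: sp.csc_matrix = field(repr=False)  # (I - Q)^T, kept for residual checks
    n: int = 0

    def solve(self, b: np.ndarray, orientation: str = "T") -> np.ndarray:
        """Solve against the factorization with a verified residual.

        ``orientation="T"`` (default) solves ``(I - Q)^T m = b``;
        ``orientation="N"`` solves ``(I - Q) y = b``.
        """
        if orientation not in ("T", "N"):
            raise ValueError("orientation must be 'T' or 'N'")
        b = np.asarray(b, dtype=float)
        if b.shape != (self.n,):
            raise ValueError(f"right-hand side has shape {b.shape}, expected ({self.n},)")
        # self._A is (I-Q)^T; SuperLU trans='T' solves A^T x = b, i.e. (I-Q) x = b
        trans = "N" if orientation == "T" else "T"
        x = self._lu.solve(b, trans=trans)
        A = self._A if orientation == "T" else self._A.T
        # bound scales with the right-hand side: iterated solves feed back
        # vectors whose entries grow like expected visit counts
        tol = RESIDUAL_TOL * max(1.0, np.max(np.abs(b)))
        resid = A @ x - b
        err = np.max(np.abs(resid))
        if err > tol:
            x = x - self._lu.solve(resid, trans=trans)
            err = np.max(np.abs(A @ x - b))
            if err > tol:
                raise SingularChainError(
                    f"solve residual {err:.3e} exceeds {tol:.3e} "
                    "after iterative refinement"
                )
        return x


def factorize(ts: TransientSystem) -> ResolventFactorization:
    """LU-factorize ``(I - Q)^T`` once, for reuse across all analyses."""
    n = ts.n_transient
    A = (sp.identity(n, format="csc") - ts.Q).T.tocsc()
    try:
        lu = splu(A)
    except RuntimeError as exc:  # pragma: no cover - degenerate input
        detail = f" (spec: {ts.spec})" if ts.spec is not None else ""
        raise SingularChainError(f"I - Q is numerically singular{detail}") from exc
    return ResolventFactorization(_lu=lu, _A=A, n=n)


def _start_vector(ts: TransientSystem, start) -> np.ndarray:
    """Normalize a start specification to a probability vector over transients.

    ``start`` may be a copy count (int) or an explicit nonnegative vector
    over the transient states summing to 1.
    """
    if np.isscalar(start):
        e = np.zeros(ts.n_transient)
        e[ts.index_of(int(start))] = 1.0
        return e
    v = np.asarray(start, dtype=float)
    if v.shape != (ts.n_transient,):
        raise ValueError(
            f"start vector has shape {v.shape}, expected ({ts.n_transient},)"
        )
    if np.any(v < 0) or not np.isclose(v.sum(), 1.0, atol=1e-9):
        raise ValueError("start vector must be nonnegative and sum to 1")
    return v


def resolvent_row(f: ResolventFactorization, ts: TransientSystem, start) -> np.ndarray:
    """Start-weighted row of the fundamental matrix, ``M1 = N^T b``.

    For a point start at ``p`` this is the ``p``-th row of
    ``N = (I - Q)^{-1}``: entry ``j`` is the expected number of visits to
    transient state ``j``, and ``sum(M1)`` is the unconditional expected
    absorption time.
    """
    return f.solve(_start_vector(ts, start), "T")


def iterate_resolvent(f: ResolventFactorization, M_k: np.ndarray) -> np.ndarray:
    """One more resolvent power: from the start-row of ``(I-Q)^{-k}``
    to the start-row of ``(I-Q)^{-(k+1)}``."""
    return f.solve(M_k, "T")


def absorption_probabilities(
    ts: TransientSystem, f: ResolventFactorization, start
) -> tuple[float, float]:
    """Probabilities of absorbing at extinction vs fixation from ``start``.

    Classical identity ``B = N R`` evaluated as ``M1^T R`` with a single
    solve; returns ``(prob_extinction, prob_fixation)``.
    """
    if ts.R.shape[1] != 2:
        raise ValueError("absorption analysis requires a two-column R (extinction, fixation)")
    M1 = resolvent_row(f, ts, start)
    b = M1 @ ts.R
    return float(b[0]), float(b[1])


@dataclass(frozen=True)
class AbsorptionSummary:
    """Absorption probabilities and (conditional) absorption times, in generations.

    ``sojourn_given_extinction[j]`` is the expected number of generations
    spent at transient state ``j`` by chains that are eventually absorbed at
    extinction; its sum is ``expected_time_given_extinction``.  A
    conditional time whose conditioning event has probability 0 is reported
    as ``None`` rather than NaN.
    """

    prob_extinction: float
    prob_fixation: float
    expected_time_unconditional: float
    expected_time_given_extinction: float | None
    expected_time_given_fixation: float | None
    sojourn_given_extinction: np.ndarray | None
    sojourn_given_fixation: np.ndarray | None
    state_labels: np.ndarray


def conditional_absorption_times(
    ts: TransientSystem, f: ResolventFactorization, start
) -> AbsorptionSummary:
    """Expected absorption times, unconditional and by absorbing endpoint.

    Uses the endpoint-conditioned visit counts
    ``N[p, j] * B[j, end] / B[p, end]`` where ``B = N R``; the column
    ``B[:, end]`` comes from one untransposed solve ``(I - Q) y = R[:, end]``.
    """
    M1 = resolvent_row(f, ts, start)
    b_ext_all = f.solve(ts.R[:, 0], "N")
    b_fix_all = f.solve(ts.R[:, 1], "N")
    p_ext = float(M1 @ ts.R[:, 0])
    p_fix = float(M1 @ ts.R[:, 1])
    t_uncond = float(M1.sum())

    def conditional(b_all: np.ndarray, p_end: float):
        if p_end <= 0.0:
            return None, None
        soj = M1 * b_all / p_end
        return soj, float(soj.sum())

    soj_ext, t_ext = conditional(b_ext_all, p_ext)
    soj_fix, t_fix = conditional(b_fix_all, p_fix)
    return AbsorptionSummary(
        prob_extinction=p_ext,
        prob_fixation=p_fix,
        expected_time_unconditional=t_uncond,
        expected_time_given_extinction=t_ext,
        expected_time_given_fixation=t_fix,
        sojourn_given_extinction=soj_ext,
        sojourn_given_fixation=soj_fix,
        state_labels=ts.state_labels,
    )


def sojourn_difference_vs_neutral(
    ts_selected: TransientSystem,
    ts_neutral: TransientSystem,
    start,
    f_selected: ResolventFactorization | None = None,
    f_neutral: ResolventFactorization | None = None,
) -> np.ndarray:
    """Per-state difference in extinction-conditioned sojourn times.

    ``selected - neutral``, in generations, state by state.  Positive
    entries at low copy numbers are the signature of the stochastic
    slowdown: selection against the allele prolonging its residency in low
    frequency classes.
    """
    if ts_selected.n_transient != ts_neutral.n_transient:
        raise ValueError("systems must share the same transient state space")
    f_selected = f_selected or factorize(ts_selected)
    f_neutral = f_neutral or factorize(ts_neutral)
    a = conditional_absorption_times(ts_selected, f_selected, start)
    b = conditional_absorption_times(ts_neutral, f_neutral, start)
    if a.sojourn_given_extinction is None or b.sojourn_given_extinction is None:
        raise ValueError("extinction has probability 0 in one of the systems")
    return a.sojourn_given_extinction - b.sojourn_given_extinction
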