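"""Parameter sweeps over (2*Ne*s, h, theta) grids and result serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .allele_age import age_moments, starting_copy_prior
from .markov_core import conditional_absorption_times, factorize
from .wf_model import ModelSpec, build_transition_matrix, extract_transient_system

__all__ = ["SweepSpec", "run_sweep", "emit_report", "extinction_time_argmax"]

RESULT_COLUMNS = [
    "Ne", "two_nes", "s", "h", "theta", "p", "x",
    "mean_age", "var_age", "sd_age", "normalizer",
    "prob_extinction", "prob_fixation",
    "t_unconditional", "t_extinction", "t_fixation",
    "error",
]


@dataclass(frozen=True)
class SweepSpec:
    """Grid of scaled-selection, dominance and mutation values at fixed Ne.

    ``two_nes_values`` are population-scaled coefficients (2*Ne*s); ``x`` is
    the observed copy count; the start is a point mass at ``p`` unless
    ``integrate_p`` requests the Poisson prior (threshold ``epsilon``).
    ``absorption`` additionally computes absorption probabilities and
    conditional absorption times from ``x``.
    """

    Ne: int
    two_nes_values: tuple = (0.0,)
    h_values: tuple = (0.5,)
    theta_values: tuple = (0.0,)
    x: int = 10
    p: int = 1
    integrate_p: bool = False
    epsilon: float = 1e-5
    k_max: int = 2
    cutoff: float = 1e-12
    absorption: bool = False

    def __post_init__(self):
        if not (self.two_nes_values and self.h_values and self.theta_values):
            raise ValueError("sweep grid must be non-empty")
        for tn in self.two_nes_values:
            for h in self.h_values:
                ModelSpec.from_scaled_selection(self.Ne, tn, h=h)  # validate


def _point(sw: SweepSpec, two_nes: float, h: float, theta: float) -> dict:
    row: dict = {
        "Ne": sw.Ne, "two_nes": two_nes, "s": two_nes / (2 * sw.Ne),
        "h": h, "theta": theta, "p": sw.p, "x": sw.x, "error": "",
    }
    spec = ModelSpec.from_scaled_selection(sw.Ne, two_nes, h=h, theta=theta or None)
    ts = extract_transient_system(build_transition_matrix(spec, cutoff=sw.cutoff))
    f = factorize(ts)
    if sw.integrate_p:
        start = starting_copy_prior(theta, sw.epsilon).start_vector(ts)
    else:
        start = sw.p
    am = age_moments(ts, f, start, sw.x, k_max=sw.k_max)
    row.update(
        mean_age=am.mean, var_age=am.variance, sd_age=am.std_dev,
        normalizer=am.normalizer,
    )
    if sw.absorption:
        summ = conditional_absorption_times(ts, f, sw.x)
        row.update(
            prob_extinction=summ.prob_extinction,
            prob_fixation=summ.prob_fixation,
            t_unconditional=summ.expected_time_unconditional,
            t_extinction=summ.expected_time_given_extinction,
            t_fixation=summ.expected_time_given_fixation,
        )
    return row


def run_sweep(sw: SweepSpec) -> pd.DataFrame:
    """Evaluate every grid point; the factorization is built once per point
    and shared by all quantities computed there.

    Per-point failures are recorded in the ``error`` column and the sweep
    continues.  Row order is deterministic: theta-major, then 2*Ne*s, then h.
    """
    rows = []
    for theta in sw.theta_values:
        for two_nes in sw.two_nes_values:
            for h in sw.h_values:
                try:
                    rows.append(_point(sw, two_nes, h, theta))
                except Exception as exc:  # noqa: BLE001 - sweep must continue
                    rows.append({
                        "Ne": sw.Ne, "two_nes": two_nes, "s": two_nes / (2 * sw.Ne),
                        "h": h, "theta": theta, "p": sw.p, "x": sw.x,
                        "error": f"{type(exc).__name__}: {exc}",
                    })
    return pd.DataFrame(rows).reindex(columns=RESULT_COLUMNS)


def extinction_time_argmax(
    Ne: int,
    theta: float,
    h: float,
    grid,
    start: int = 1,
    cutoff: float = 1e-12,
) -> float:
    """Scaled selection coefficient (2*Ne*s) maximizing the expected
    extinction time.

    Evaluates the extinction-conditioned absorption time from ``start`` at
    every grid value and refines the discrete argmax by parabolic
    interpolation through its two neighbours.  Under strong bidirectional
    mutation the maximum falls at weakly *deleterious* selection — the
    stochastic-slowdown critical point — but the curve is very flat there,
    so a modest grid suffices.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size < 3:
        raise ValueError("grid must contain at least 3 points")
    vals = []
    for two_nes in grid:
        spec = ModelSpec.from_scaled_selection(Ne, two_nes, h=h, theta=theta)
        ts = extract_transient_system(build_transition_matrix(spec, cutoff=cutoff))
        summ = conditional_absorption_times(ts, factorize(ts), start)
        vals.append(summ.expected_time_given_extinction)
    vals = np.asarray(vals)
    i = int(np.argmax(vals))
    if i in (0, grid.size - 1):
        return float(grid[i])
    v0, v1, v2 = vals[i - 1], vals[i], vals[i + 1]
    step = grid[i + 1] - grid[i]
    return float(grid[i] - 0.5 * step * (v2 - v0) / (v2 - 2.0 * v1 + v0))


def emit_report(results: pd.DataFrame, tsv_path=None, json_path=None, meta: dict | None = None):
    """Write a sweep table as TSV and/or JSON with provenance."""
    if tsv_path is not None:
        results.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        payload = {
            "software": {"name": "wfage", "version": __version__},
            "meta": meta or {},
            "results": json.loads(results.to_json(orient="records")),
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
    return results
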