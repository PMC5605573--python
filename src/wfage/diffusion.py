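"""Neutral diffusion baseline for allele age (Kimura-Ohta).

Under the neutral diffusion with no mutation, the expected age of an allele
observed at population frequency ``q`` is

    E[T | q] = -4 * Ne * (q / (1 - q)) * ln(q)    generations.

This closed form slightly overestimates the exact Markov-chain value (by a
few generations at the parameter ranges of interest) and serves as an
independent sanity check on the exact solver.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kimura_ohta_neutral_age"]


def kimura_ohta_neutral_age(q, Ne: int):
    """Expected neutral allele age, in generations, at observed frequency q.

    ``q`` may be a scalar or array in the open interval (0, 1); ``Ne`` is
    the effective diploid population size.  The value is exactly linear in
    ``Ne`` at fixed frequency.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0.0) or np.any(q >= 1.0):
        raise ValueError("observed frequency q must lie strictly in (0, 1)")
    age = -4.0 * Ne * (q / (1.0 - q)) * np.log(q)
    return age if age.ndim else float(age)
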