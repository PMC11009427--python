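"""Fitted demographic model constants and derived conversions.

The two-population piecewise model (ancestral split, a long linear decline,
then two short recent epochs) is shipped as constants — it is an input to
this package, not something it re-fits.  The functions here provide the
derived arithmetic: generation-to-year conversion and the harmonic-mean
effective size of a linear-decline epoch, which governs drift over that
epoch.
"""

from __future__ import annotations

import json
import math
from importlib import resources

import numpy as np


def load_model() -> dict:
    """The fitted piecewise demography, as a plain dict of constants."""
    with resources.files("rhinoload.data").joinpath("demography.json").open() as fh:
        return json.load(fh)


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


def years_from_generations(generations: float, generation_time: float) -> int:
    """Convert generations to calendar years, rounded half-up to an integer."""
    if generations < 0 or generation_time <= 0:
        raise ValueError("generations must be >= 0 and generation_time > 0")
    return round_half_up(generations * generation_time)


def harmonic_mean_linear(n_start: float, n_end: float, duration: float | None = None) -> float:
    """Harmonic-mean Ne over an epoch of linear size change.

    For N(t) moving linearly from ``n_start`` to ``n_end`` the time average
    of 1/N(t) has the closed form ln(n_start/n_end)/(n_start - n_end), so
    the harmonic mean is (n_start - n_end)/ln(n_start/n_end); it reduces to
    N when the size is constant.  ``duration`` does not enter the mean and
    is accepted only for interface symmetry with the epoch table.
    """
    if n_start <= 0 or n_end <= 0:
        raise ValueError("population sizes must be positive")
    if n_start == n_end:
        return float(n_start)
    return (n_start - n_end) / math.log(n_start / n_end)


def harmonic_mean_numeric(n_start: float, n_end: float, n_steps: int = 100_000) -> float:
    """Trapezoid-integrated harmonic mean of a linear decline (cross-check)."""
    t = np.linspace(0.0, 1.0, n_steps)
    n_t = n_start + (n_end - n_start) * t
    return 1.0 / np.trapezoid(1.0 / n_t, t)
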