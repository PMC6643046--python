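"""Small shared statistics helpers (Student-t summaries)."""

from __future__ import annotations

import math
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import ArgumentError


def mean_t_ci(values: Sequence[float]) -> Tuple[float, float, int]:
    """Arithmetic mean and two-sided 95% Student-t confidence half-width.

    Returns ``(mean, half_width, n)`` where
    ``half_width = t(0.975, n-1) * sd / sqrt(n)`` with the sample standard
    deviation (ddof=1).  For ``n == 1`` the half-width is NaN (undefined);
    an empty input is an error.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ArgumentError("cannot summarize an empty sequence")
    mean = float(arr.mean())
    n = int(arr.size)
    if n == 1:
        return mean, math.nan, n
    sd = float(arr.std(ddof=1))
    half = float(sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return mean, half, n
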