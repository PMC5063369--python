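"""Measurement grid: every analysed value lives on a fixed resolution.

Diameters are reported by electronic calipers to 0.1 mm; SUVmean to 0.01.
All thresholds, observed values and candidate cutoffs are snapped through
the same function so that ``>=`` comparisons between a snapped value and a
snapped cutoff are exact, with no float drift between code paths.
"""

from __future__ import annotations

import math

import numpy as np

#: resolution of the three MRI diameters, in millimetres
DIAMETER_RES = 0.1
#: resolution of the PET SUVmean channel (dimensionless)
SUV_RES = 0.01


def _decimals(res: float) -> int:
    return max(0, -int(math.floor(math.log10(res) + 1e-9)))


def snap(x, res: float):
    """Round ``x`` half-up onto the grid of step ``res``.

    Accepts scalars or arrays; +/-inf sentinels pass through unchanged.
    """
    d = _decimals(res)
    arr = np.asarray(x, dtype=float)
    out = np.where(np.isfinite(arr), np.round(np.floor(arr / res + 0.5) * res, d), arr)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def grid_step_up(x: float, res: float) -> float:
    """The next grid point above ``x`` (identity for +inf)."""
    if not math.isfinite(x):
        return x
    return snap(x + res, res)
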